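"""Access to packaged YAML configuration files."""

from __future__ import annotations

from importlib import resources

import yaml


def load_packaged_yaml(name: str) -> dict:
    ref = resources.files("mesycea").joinpath("data", name)
    with ref.open("r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)
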