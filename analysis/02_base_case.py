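#!/usr/bin/env python
"""Intention-to-treat base case on the synthetic cohort.

Completes the cohort by last observation carried forward, runs the four
scenario simulations (with-study vs reference × intervention vs control)
over the 3-year and lifelong horizons in exact cohort-expectation mode,
and reports DD costs (societal and health-care perspectives) and DD QALYs
with 1,000-sample bootstrap CIs plus the ICER classification.
"""

import argparse
from pathlib import Path

from mesycea.cohort import read_cohort_csv
from mesycea.ddcea import run_base_case


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort.csv"))
    ap.add_argument("--bootstrap", type=int, default=1000)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cohort = read_cohort_csv(args.cohort)
    res = run_base_case(cohort, bootstrap_B=args.bootstrap, seed=args.seed)
    table = res["table"]
    table.to_csv(args.out / "base_case.csv", index=False)

    print("base case (synthetic cohort, synthetic model parameters):")
    print(table.to_string(index=False, float_format=lambda v: f"{v:,.3f}"))
    print(
        "\nNote: with synthetic cost/utility/risk parameters these magnitudes"
        " are illustrative; the pipeline (DD arithmetic, bootstrap, ICER"
        " classification) is the reproducible object."
    )
    print(f"wrote {args.out/'base_case.csv'}")


if __name__ == "__main__":
    main()
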