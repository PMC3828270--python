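#!/usr/bin/env python
"""Generate the synthetic analysis cohort.

Draws 145 synthetic participants (71 intervention, 74 control) whose
group-wise risk-factor marginals at baseline, year 1 and year 3 match the
published participant table, with monotone 17% attrition, and writes the
cohort plus a summary comparing realised marginals against their targets.
"""

import argparse
from pathlib import Path

from mesycea.cohort import (
    CONTINUOUS_FIELDS,
    default_cohort_spec,
    generate_cohort,
    write_cohort_csv,
)

def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    spec = default_cohort_spec(seed=args.seed)
    cohort = generate_cohort(spec)
    write_cohort_csv(cohort, args.out / "cohort.csv")

    n_base = (cohort["wave"] == "baseline").sum()
    n_y3 = cohort[cohort["wave"] == "year3"]["sbp"].notna().sum()
    print(f"cohort: {n_base} participants at baseline, {n_y3} observed at year 3 "
          f"({1 - n_y3 / n_base:.0%} attrition)")

    rows = []
    for gname, g in spec.groups.items():
        for wname, w in g.waves.items():
            sub = cohort[(cohort["group"] == gname) & (cohort["wave"] == wname)]
            for f in CONTINUOUS_FIELDS:
                rows.append(
                    {"group": gname, "wave": wname, "field": f,
                     "target_mean": w.means[f], "realised_mean": sub[f].mean()}
                )
    import pandas as pd

    summary = pd.DataFrame(rows)
    summary.to_csv(args.out / "cohort_marginals.csv", index=False)
    worst = (summary["realised_mean"] - summary["target_mean"]).abs().max()
    print(f"largest |realised − target| group-wave mean: {worst:.2f} "
          f"(finite-sample noise at n≈60–74 per cell)")
    print(f"wrote {args.out/'cohort.csv'} and {args.out/'cohort_marginals.csv'}")


if __name__ == "__main__":
    main()
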