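"""Pooled cohort demographics from the published subgroup summaries.

Combines the male (n=15) and female (n=9) subgroup statistics into the
whole-cohort mean +/- SD for body mass, age and relative bench-press
1-RM, using the exact pooling identity.
"""

from pathlib import Path

import pandas as pd

from strendo.demographics import SubgroupStats, pool_subgroups

RESULTS = Path(__file__).resolve().parents[1] / "results"

SUBGROUPS = {
    "body_mass_kg": [SubgroupStats(15, 85.4, 7.9), SubgroupStats(9, 63.6, 3.3)],
    "age_y": [SubgroupStats(15, 27.2, 3.3), SubgroupStats(9, 27.7, 5.2)],
    "relative_one_rm": [SubgroupStats(15, 1.33, 0.11), SubgroupStats(9, 0.96, 0.17)],
}


def main():
    rows = {}
    for name, groups in SUBGROUPS.items():
        pooled = pool_subgroups(groups)
        rows[name] = {"n": pooled.n, "mean": round(pooled.mean, 2), "sd": round(pooled.sd, 2)}
        print(f"{name:16s} n={pooled.n}  {pooled.mean:6.2f} +/- {pooled.sd:5.2f}")
    RESULTS.mkdir(exist_ok=True)
    pd.DataFrame(rows).T.to_csv(RESULTS / "pooled_demographics.csv")
    print(f"-> {RESULTS/'pooled_demographics.csv'}")


if __name__ == "__main__":
    main()
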