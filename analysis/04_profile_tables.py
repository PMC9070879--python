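"""Individual strength-endurance profiles and repetition-maximum tables.

The profile calculator applied to the cohort's group-mean repetition
pattern: least-squares fit, adjusted R-squared, and an RM table giving
the predicted relative (and absolute) load for 1..15 repetitions.
"""

import argparse
from pathlib import Path

from strendo.profile_builder import fit_individual_profile, rm_table

RESULTS = Path(__file__).resolve().parents[1] / "results"

# group-mean (relative load, RTF) points, including the 1-RM as (100 %, 1)
GROUP_POINTS = [(100.0, 1.0), (90.0, 4.2), (80.0, 7.8), (70.0, 12.2)]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--one-rm", type=float, default=93.5, help="1-RM (kg) for absolute loads")
    args = ap.parse_args()

    RESULTS.mkdir(exist_ok=True)
    for model in ("lin", "ex2"):
        prof = fit_individual_profile(GROUP_POINTS, model)
        table = rm_table(prof, one_rm_kg=args.one_rm, max_reps=15)
        out = RESULTS / f"rm_table_{model}.csv"
        table.to_csv(out, index=False)
        print(f"{model}: {prof.equation()}   adjusted R2 = {prof.adj_r_squared:.4f}")
        print(table.round(2).to_string(index=False))
        print(f"-> {out}\n")


if __name__ == "__main__":
    main()
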