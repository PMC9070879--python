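"""Test-retest consistency of the 1-RM and repetitions-to-failure measures.

Fits the random-intercept model per measure on the simulated cohort and
summarizes dt (systematic T2-T1 change), ICC, SEM, WSCV and SEP as MAP
[90 % HDI].  High loads should show smaller SEM but also smaller ICC
(less between-subject spread to separate).
"""

import argparse
import warnings
from pathlib import Path

from strendo.io_data import load_dataset
from strendo.reliability import reliability_table

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--cohort", type=Path, default=RESULTS / "cohort.csv")
    args = ap.parse_args()

    ds = load_dataset(args.cohort)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = reliability_table(ds, seed=args.seed, check="warn")
    out = RESULTS / "reliability.csv"
    table.to_csv(out, index=False)
    print(table.round(3).to_string(index=False))
    print(f"-> {out}")


if __name__ == "__main__":
    main()
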