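"""Reproducibility of the four strength-endurance model families.

Fits the linear, 2- and 3-parameter exponential and critical-load
multilevel models with test-retest change effects, then summarizes the
posterior predictive change distributions (relative %, standardized,
and the probability of a small-or-trivial standardized change within
+/-0.6).  The 2-parameter families should keep their slope/curvature
changes inside the band far more often than any 3-parameter change
effect — the robustness ranking the profile calculator relies on.
"""

import argparse
import warnings
from pathlib import Path

import pandas as pd

from strendo.io_data import load_dataset
from strendo.se_models import fit_se_model, plot_change_densities, summarize_se

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--cohort", type=Path, default=RESULTS / "cohort.csv")
    args = ap.parse_args()

    ds = load_dataset(args.cohort)
    summaries, rows = {}, []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for model in ("lin", "ex2", "ex3", "crit"):
            short = model in ("ex3", "crit")
            post = fit_se_model(ds, model, seed=args.seed,
                                n_warmup=1200 if short else 2000,
                                n_keep=1500 if short else 4500, check="warn")
            summ = summarize_se(post)
            summaries[model] = summ
            print(f"\n== {model} (converged: {post.converged}) ==")
            print(summ.absolute.round(3).to_string())
            print(summ.changes.round(3).to_string())
            for df, kind in ((summ.absolute, "absolute"), (summ.changes, "changes")):
                d = df.copy()
                d.insert(0, "model", model)
                d.insert(1, "kind", kind)
                rows.append(d.reset_index(names="parameter"))

    pd.concat(rows, ignore_index=True).to_csv(RESULTS / "se_models.csv", index=False)
    plot_change_densities(summaries, RESULTS / "change_densities.png")
    ranking = sorted(
        ((m, float(s.changes["p_within"].max())) for m, s in summaries.items()),
        key=lambda kv: -kv[1],
    )
    print("\nmost reproducible change effect per family (p_within):")
    for m, p in ranking:
        print(f"  {m:5s} {p:.3f}")
    print(f"-> {RESULTS/'se_models.csv'}, {RESULTS/'change_densities.png'}")


if __name__ == "__main__":
    main()
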