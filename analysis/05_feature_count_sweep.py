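#!/usr/bin/env python
"""Accuracy as a function of the number of selected features (CN vs AD).

Sweeps the t-statistic feature count over 8..435 for each measure and
writes results/reports/feature_sweep.tsv plus an accuracy-vs-feature-count
figure.  The non-linear measures should dominate across the sweep and stay
stable once the informative edges are included; PCC should hover around
chance at every count.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from fconn.cohort import read_cohort
from fconn.evaluation import run_cv
from fconn.melm import MELMConfig

ROOT = Path(__file__).resolve().parent.parent / "results"
MEASURES = ("PCC", "MIC", "eMIC")
GRID = [8, 16, 32, 64, 128, 256, 435]
SEED = 2023


def main() -> None:
    cohort = read_cohort(ROOT / "cohort")
    rows = []
    for measure in MEASURES:
        df = pd.read_csv(ROOT / "features" / f"{measure}.features.tsv",
                         sep="\t", header=None, index_col=0,
                         float_precision="round_trip")
        labels = [cohort.labels[sid] for sid in df.index]
        reps = run_cv(df.to_numpy(float), labels, ("CN", "AD"), measure,
                      GRID, MELMConfig(seed=SEED), seed=SEED)
        for rep in reps:
            rows.append({"measure": measure, "n_features": rep.n_features,
                         "accuracy": rep.accuracy})
    out = ROOT / "reports"
    out.mkdir(parents=True, exist_ok=True)
    table = pd.DataFrame(rows)
    table.to_csv(out / "feature_sweep.tsv", sep="\t", index=False,
                 float_format="%.4g")
    fig, ax = plt.subplots(figsize=(6, 4))
    for measure in MEASURES:
        sub = table[table["measure"] == measure]
        ax.plot(sub["n_features"], sub["accuracy"], marker="o", label=measure)
    ax.set_xscale("log")
    ax.set_xlabel("number of selected features")
    ax.set_ylabel("10-fold CV accuracy (CN vs AD)")
    ax.axhline(0.5, color="grey", ls=":", lw=1)
    ax.legend()
    fig.tight_layout()
    figdir = ROOT / "figures"
    figdir.mkdir(parents=True, exist_ok=True)
    fig.savefig(figdir / "feature_sweep.png", dpi=150)
    print(table.pivot(index="n_features", columns="measure",
                      values="accuracy").to_string())
    print(f"\nwritten to {out / 'feature_sweep.tsv'} and "
          f"{figdir / 'feature_sweep.png'}")


if __name__ == "__main__":
    main()
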