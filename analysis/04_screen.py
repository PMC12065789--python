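"""Screen statistics: outlier-filtered success calls (+liposome vs
control, Welch t-test, BH correction, delta > 1 pmol), preferred
compositions over each protein's top-3 conditions, per-protein OLS
interaction p-values, and Euclidean-norm trajectories from the standard
composition to each protein's best.

Reads results/screen_records.csv (run 01 first).  Writes
results/success_calls.csv, results/preferred_compositions.csv,
results/interaction_pvalues.csv, results/trajectory_norms.csv.
"""

import pathlib
import warnings

import numpy as np
import pandas as pd

from memscreen import design
from memscreen.active_learn import scale_yields_per_protein
from memscreen.screen_stats import (
    call_screen,
    interaction_model,
    preferred_composition,
    trajectory_norm,
)

OUT = pathlib.Path("results")
STANDARD = {"Mg": 0.0, "K": 0.0, "PEG": 0.0, "SecYE": 0.0, "lipid": 0.0}


def main():
    records = pd.read_csv(OUT / "screen_records.csv")
    grid = design.default_grid()
    factor_names = grid.names

    calls = call_screen(records, condition_cols=["condition"])
    enc = records[["condition", *factor_names]].drop_duplicates("condition")
    calls = calls.merge(enc, on="condition")
    calls.to_csv(OUT / "success_calls.csv", index=False)
    by_protein = calls.groupby("protein")["passed"].mean()
    print(f"success calls: {calls['passed'].mean():.1%} of "
          f"{len(calls)} condition tests pass (delta > 1 pmol, q < 0.05)")
    print("per-protein pass fraction:",
          {k: round(v, 2) for k, v in by_protein.items()})

    prefs = {}
    for protein, grp in calls.groupby("protein"):
        prefs[protein] = preferred_composition(grp, factor_names)
    prefs = pd.DataFrame(prefs).T
    prefs.to_csv(OUT / "preferred_compositions.csv")
    print("mean preferred composition across proteins:",
          prefs.mean().round(2).to_dict())

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scaled, _ = scale_yields_per_protein(records[records["liposome"]])
    pmat = {}
    for protein, grp in scaled.groupby("protein"):
        table = interaction_model(grp[factor_names].to_numpy(),
                                  grp["yield_z"].to_numpy(),
                                  factor_names=factor_names)
        pmat[protein] = table["p"]
    pmat = pd.DataFrame(pmat).T
    pmat.to_csv(OUT / "interaction_pvalues.csv")
    inter_cols = [c for c in pmat.columns if "x" in c]
    n_sig = (pmat[inter_cols] < 0.05).any(axis=0).sum()
    print(f"interaction terms significant for >= 1 protein: "
          f"{n_sig}/{len(inter_cols)}")

    norms = {}
    std_vec = np.array([STANDARD[f] for f in factor_names])
    for protein, grp in calls.groupby("protein"):
        best = grp.sort_values("delta", ascending=False).iloc[0]
        best_vec = best[factor_names].to_numpy(float)
        dmax = grp["delta"].max()
        dstd = grp.loc[
            (grp[factor_names] == std_vec).all(axis=1), "delta"
        ]
        base = float(dstd.iloc[0]) if len(dstd) else 0.0
        scale = max(calls["delta"].abs().max(), 1e-9)
        norms[protein] = trajectory_norm(std_vec, best_vec,
                                         base / scale, dmax / scale)
    norms = pd.DataFrame(norms, index=factor_names).T
    norms.to_csv(OUT / "trajectory_norms.csv")
    print("mean trajectory norm per factor:",
          norms.mean().round(2).to_dict())


if __name__ == "__main__":
    main()
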