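"""Generate the synthetic screening campaign.

A 5-factor, 3-level reaction grid is screened by a 3-fold generalized
subset design over a 16-protein panel (quadruplicates with and without
liposomes, 7.5% outlier contamination).  Half the panel responds strongly
to its environment (clear > 1 pmol liposome gains somewhere on the grid),
half barely responds — emulating the split between synthesizable and
recalcitrant membrane proteins.  Each protein also gets an idealized
helix-bundle structure whose lipid-facing hydrophobicity tracks its
class, planting the structural signal the classifier stage should find.

Writes results/screen_records.csv, results/ground_truth_*.csv, and
results/structures/ (PDB + TM annotations).
"""

import pathlib

import numpy as np
import pandas as pd

from memscreen import design
from memscreen.synthetic_data import (
    BundleConfig,
    LandscapeConfig,
    gen_helix_bundle,
    gen_yield_landscape,
)

SEED = 2024
N_STRONG = 8
N_WEAK = 8
OUT = pathlib.Path("results")


def main():
    OUT.mkdir(exist_ok=True)
    grid = design.default_grid()
    gdes = design.gsd(grid, 3)

    strong_cfg = LandscapeConfig(n_proteins=N_STRONG, grid=grid,
                                 effect_scale=4.0, seed=SEED)
    weak_cfg = LandscapeConfig(n_proteins=N_WEAK, grid=grid,
                               effect_scale=0.6, interaction_scale=0.3,
                               seed=SEED + 1)
    rec_s, truth_s = gen_yield_landscape(strong_cfg, design=gdes)
    rec_w, truth_w = gen_yield_landscape(weak_cfg, design=gdes)
    rename = {f"P{p:02d}": f"P{p + N_STRONG:02d}" for p in range(N_WEAK)}
    rec_w = rec_w.assign(protein=rec_w["protein"].map(rename))
    records = pd.concat([rec_s, rec_w], ignore_index=True)
    records.to_csv(OUT / "screen_records.csv", index=False)

    optima = pd.concat([truth_s.optimum_encoding,
                        truth_w.optimum_encoding.rename(index=rename)])
    means = pd.concat([truth_s.true_mean,
                       truth_w.true_mean.rename(index=rename)])
    optima.to_csv(OUT / "ground_truth_optima.csv")
    means.to_csv(OUT / "ground_truth_means.csv")

    sdir = OUT / "structures"
    sdir.mkdir(exist_ok=True)
    rng = np.random.default_rng(SEED + 7)
    for p, protein in enumerate(means.index):
        strong = p < N_STRONG
        signal = float(rng.uniform(0.3, 0.8)) * (1 if strong else -1)
        bcfg = BundleConfig(
            n_helices=4, helix_length=30, ring_radius=8.0,
            hydrophobicity_signal=signal, seed=SEED * 100 + p,
        )
        gen_helix_bundle(bcfg, protein_id=protein).write(
            sdir / f"{protein}.pdb", sdir / f"{protein}.tsv"
        )

    print(f"screen: {len(means)} proteins ({N_STRONG} strong responders, "
          f"{N_WEAK} weak) x {len(gdes)} GSD conditions of "
          f"{grid.n_conditions}; {len(records)} reactions "
          f"({records['is_outlier'].mean():.1%} outliers injected)")
    print(f"structures: {len(means)} bundles under {sdir}/ with "
          f"class-tied lipid-facing hydrophobicity")


if __name__ == "__main__":
    main()
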