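"""Structural featurization: orient each bundle in the mock bilayer,
apply QC, assign membrane layers and lipid-contact shells, and aggregate
the 32-feature vector per protein.

Reads results/structures/ (run 01 first).  Writes
results/structure_features.csv and results/structure_qc.tsv.
"""

import pathlib
import warnings

import pandas as pd

from memscreen import structure_feats as sf

OUT = pathlib.Path("results")


def main():
    sdir = OUT / "structures"
    structures = {}
    qc_rows = []
    for pdb in sorted(sdir.glob("*.pdb")):
        pid = pdb.stem
        st = sf.read_structure(pdb, pdb.with_suffix(".tsv"))
        structures[pid] = st
        q = sf.qc(sf.orient(st))
        qc_rows.append({"protein": pid, "tm_within": q.tm_within_membrane,
                        "min_span": q.min_helix_span, "passed": q.passed})
    qc_table = pd.DataFrame(qc_rows)
    qc_table.to_csv(OUT / "structure_qc.tsv", sep="\t", index=False)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        feats = sf.featurize(structures)
    feats.to_csv(OUT / "structure_features.csv")
    print(f"{qc_table['passed'].sum()}/{len(qc_table)} structures pass QC "
          f"(min helix span {qc_table['min_span'].min():.1f} A)")
    print(f"feature table: {feats.shape[0]} proteins x {feats.shape[1]} "
          f"features")
    hydro = feats.filter(like="membrane_contacting__hydrophobicity")
    print("lipid-facing hydrophobicity (inner layer) range:",
          f"{hydro.iloc[:, 0].min():.2f} to {hydro.iloc[:, 0].max():.2f} "
          f"kcal/mol")


if __name__ == "__main__":
    main()
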