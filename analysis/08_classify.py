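"""Synthesis-success classification from structure features.

Proteins are labeled from the screen's BH-corrected success calls; feature
subsets are embedded to 2D and scored with 50-member RBF-SVM Ensemble
Classifiers; qualifying embeddings are paired (adding protein length, 5
inputs) and the best pairs vote in a comprehensive prediction with
likely / unlikely / uncertain confidence categories.

Reads results/success_calls.csv and results/structure_features.csv (run
04 and 07 first).  Writes results/embedding_accuracy.csv and
results/comprehensive_predictions.csv.

With the small demonstration panel the accuracy gates of 0.77/0.85 are
kept at their defaults; when too few embeddings qualify the script says
so rather than lowering the gates.
"""

import pathlib
import warnings

import pandas as pd

from memscreen.classify import (
    comprehensive_predict,
    label_proteins,
    pair_top_embeddings,
    search_embeddings,
)

SEED = 2024
OUT = pathlib.Path("results")


def main():
    calls = pd.read_csv(OUT / "success_calls.csv")
    feats = pd.read_csv(OUT / "structure_features.csv", index_col=0)
    labels = label_proteins(calls).reindex(feats.index).dropna().astype(int)
    print(f"labels: {labels.sum()}/{len(labels)} proteins successfully "
          f"synthesized (>= 1 condition with delta > 1 pmol, q < 0.05)")
    if labels.nunique() < 2:
        print("single-class panel: classifier training skipped")
        return

    perp = max(2.0, (len(feats) - 1) / 3 - 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        results = search_embeddings(feats, labels, perplexity=perp,
                                    seed=SEED)
    acc = pd.Series({k: v.accuracy for k, v in results.items()},
                    name="accuracy").sort_values(ascending=False)
    acc.to_csv(OUT / "embedding_accuracy.csv")
    print(f"{len(acc)} feature-subset embeddings scored; best "
          f"{acc.index[0]} at {acc.iloc[0]:.3f}")

    length = pd.Series(100.0, index=feats.index, name="length")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pairs = pair_top_embeddings(results, labels, length, seed=SEED)
    if not pairs:
        print("no embedding pairs above the 0.77 accuracy gate on this "
              "panel; comprehensive prediction not attempted")
        return
    try:
        pred = comprehensive_predict(pairs)
    except ValueError:
        print(f"{len(pairs)} pairs trained but none above the 0.85 gate; "
              f"comprehensive prediction not attempted")
        return
    pred.to_csv(OUT / "comprehensive_predictions.csv")
    frac = pred["category"].value_counts(normalize=True)
    print(f"comprehensive ensemble of {pred.attrs['n_members']} members:",
          {k: f"{v:.1%}" for k, v in frac.items()})


if __name__ == "__main__":
    main()
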