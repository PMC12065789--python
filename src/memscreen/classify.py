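"""Synthesis-success classification from structural features.

Proteins are labeled successful when any screened condition clears the
success call under BH correction (delta > 1 pmol, q < 0.05).  Feature
subsets of the 32-feature structural description are embedded to 2D with
t-SNE; on each embedding an Ensemble Classifier — 50 RBF-kernel SVMs
(C = 100) trained on different stratified 80:20 splits of the labeled
proteins — is scored by its mean test accuracy.  Embeddings above an
accuracy threshold are paired (the two 2D embeddings plus protein length,
5 inputs) into second-stage Ensemble Classifiers, and all members of
every pair above a second threshold vote in a comprehensive prediction
whose mean/SD are thresholded into likely / unlikely / uncertain.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC

from .embed_response import tsne_embed

__all__ = [
    "EnsembleClassifier",
    "ComprehensivePrediction",
    "label_proteins",
    "default_feature_subsets",
    "train_ensemble_classifier",
    "search_embeddings",
    "pair_top_embeddings",
    "comprehensive_predict",
]

ACCURACY_PAIR_THRESHOLD = 0.77
ACCURACY_COMPREHENSIVE_THRESHOLD = 0.85
LIKELY_MEAN, LIKELY_SD = 0.7, 0.2
UNLIKELY_MEAN, UNLIKELY_SD = 0.3, 0.15


@dataclass
class EnsembleClassifier:
    """One embedding's ensemble of RBF SVMs with its inputs retained."""

    embedding_id: object
    members: list = field(repr=False)
    X: pd.DataFrame = field(repr=False)  # per-protein inputs (all proteins)
    labels: pd.Series = field(repr=False)  # labeled subset used in training
    accuracy: float = float("nan")

    @property
    def n_members(self):
        return len(self.members)

    def predict_members(self, X=None) -> np.ndarray:
        """(n_members, n_proteins) hard 0/1 votes."""
        data = self.X.to_numpy(float) if X is None else np.asarray(X, float)
        return np.vstack([m.predict(data) for m in self.members])


@dataclass(frozen=True)
class ComprehensivePrediction:
    protein: object
    mean: float
    sd: float
    category: str


def label_proteins(calls: pd.DataFrame, min_delta: float = 1.0,
                   alpha: float = 0.05) -> pd.Series:
    """Binary success label per protein from BH-corrected success calls.

    label = 1 iff any condition has delta > min_delta and q < alpha.
    Proteins with zero tested conditions simply do not appear.
    """
    if calls.empty:
        return pd.Series(dtype=int)
    hit = (calls["delta"] > min_delta) & (calls["q"] < alpha)
    return hit.groupby(calls["protein"]).any().astype(int).rename("label")


def default_feature_subsets(columns, sizes=(2, 3, 4), cap: int = 256,
                            seed: int = 0) -> dict:
    """Enumerate feature subsets by location-bin families.

    The 32 default features group into 8 families (one per location bin,
    4 metrics each); subsets take all metrics of 2-4 bins.  The
    enumeration is capped with a seeded subsample when it exceeds ``cap``.
    """
    fams = {}
    for c in columns:
        fam = c.split("__")[0]
        fams.setdefault(fam, []).append(c)
    names = sorted(fams)
    combos = [
        combo for k in sizes for combo in itertools.combinations(names, k)
    ]
    if len(combos) > cap:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(combos), size=cap, replace=False)
        combos = [combos[i] for i in sorted(idx)]
    return {
        "+".join(combo): [c for fam in combo for c in fams[fam]]
        for combo in combos
    }


def train_ensemble_classifier(
    X: pd.DataFrame,
    labels: pd.Series,
    embedding_id=None,
    n_members: int = 50,
    test_fraction: float = 0.2,
    C: float = 100.0,
    seed: int = 0,
) -> EnsembleClassifier:
    """Train 50 RBF SVMs on stratified splits of the labeled proteins.

    ``X`` holds inputs for *all* proteins (rows indexed by protein);
    ``labels`` indexes the labeled subset.  Accuracy is the mean test-set
    accuracy across members.
    """
    labeled = labels.index
    XL = X.loc[labeled].to_numpy(float)
    y = labels.to_numpy(int)
    members, accs = [], []
    for m in range(n_members):
        Xtr, Xte, ytr, yte = train_test_split(
            XL, y, test_size=test_fraction, stratify=y,
            random_state=seed * 1009 + m,
        )
        clf = SVC(kernel="rbf", C=C)
        clf.fit(Xtr, ytr)
        members.append(clf)
        accs.append(float((clf.predict(Xte) == yte).mean()))
    return EnsembleClassifier(
        embedding_id=embedding_id, members=members, X=X, labels=labels,
        accuracy=float(np.mean(accs)),
    )


def search_embeddings(
    features: pd.DataFrame,
    labels: pd.Series,
    subsets: dict | None = None,
    perplexity: float = 30.0,
    n_members: int = 50,
    C: float = 100.0,
    seed: int = 0,
) -> dict:
    """Embed each feature subset to 2D and train an Ensemble Classifier.

    Features are z-scored before embedding (constant columns dropped);
    subsets with fewer than 2 usable features are skipped.  Returns
    subset id -> EnsembleClassifier; the 2D coordinates for every protein
    live in each classifier's ``X``.
    """
    if subsets is None:
        subsets = default_feature_subsets(features.columns, seed=seed)
    sd = features.std(ddof=0)
    usable = sd[sd > 0].index
    z = (features[usable] - features[usable].mean()) / sd[usable]
    results = {}
    for sid, cols in subsets.items():
        cols = [c for c in cols if c in usable]
        if len(cols) < 2:
            warnings.warn(f"subset {sid!r} has < 2 usable features; skipped",
                          stacklevel=2)
            continue
        coords = pd.DataFrame(
            tsne_embed(z[cols].to_numpy(float), perplexity=perplexity, seed=seed),
            index=features.index, columns=["e1", "e2"],
        )
        results[sid] = train_ensemble_classifier(
            coords, labels, embedding_id=sid, n_members=n_members, C=C,
            seed=seed,
        )
    return results


def pair_top_embeddings(
    results: dict,
    labels: pd.Series,
    protein_length: pd.Series,
    threshold: float = ACCURACY_PAIR_THRESHOLD,
    n_members: int = 50,
    C: float = 100.0,
    seed: int = 0,
) -> dict:
    """Pair qualifying embeddings into 5-input second-stage classifiers.

    Every unordered pair of embeddings whose ensemble accuracy exceeds
    ``threshold`` yields a new Ensemble Classifier on [e1, e2] of both
    embeddings plus the protein length — n(n-1)/2 pairs.
    """
    qualifying = {k: v for k, v in results.items() if v.accuracy > threshold}
    if len(qualifying) < 2:
        warnings.warn(
            f"fewer than 2 embeddings above accuracy {threshold}; no pairs",
            stacklevel=2,
        )
        return {}
    out = {}
    for (ka, ea), (kb, eb) in itertools.combinations(qualifying.items(), 2):
        X = pd.concat(
            [
                ea.X.rename(columns={"e1": "a1", "e2": "a2"}),
                eb.X.rename(columns={"e1": "b1", "e2": "b2"}),
                protein_length.rename("length"),
            ],
            axis=1,
        )
        out[(ka, kb)] = train_ensemble_classifier(
            X, labels, embedding_id=(ka, kb), n_members=n_members, C=C,
            seed=seed,
        )
    return out


def _category(mean: float, sd: float) -> str:
    if mean > LIKELY_MEAN and sd < LIKELY_SD:
        return "likely"
    if mean < UNLIKELY_MEAN and sd < UNLIKELY_SD:
        return "unlikely"
    return "uncertain"


def comprehensive_predict(
    paired: dict,
    threshold: float = ACCURACY_COMPREHENSIVE_THRESHOLD,
) -> pd.DataFrame:
    """Vote of every member of every qualifying paired ensemble.

    Returns per protein the mean and SD of the 0/1 member votes and the
    confidence category, plus ``attrs['n_members']`` (qualifying
    ensembles x members each).
    """
    qualifying = [e for e in paired.values() if e.accuracy > threshold]
    if not qualifying:
        raise ValueError(f"no paired ensembles above accuracy {threshold}")
    proteins = qualifying[0].X.index
    votes = np.vstack([e.predict_members() for e in qualifying])
    mean = votes.mean(axis=0)
    sd = votes.std(axis=0, ddof=1)
    out = pd.DataFrame(
        {
            "mean": mean,
            "sd": sd,
            "category": [_category(m, s) for m, s in zip(mean, sd)],
        },
        index=proteins,
    )
    out.attrs["n_members"] = int(votes.shape[0])
    return out
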