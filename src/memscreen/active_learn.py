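"""Ensemble neural-network regression and acquisition of new conditions.

The ensemble crosses three feed-forward architectures (4, 5, or 6 hidden
ReLU layers: 128-64-32-16, plus a leading 256, plus a leading 512 node
layer), three minibatch sizes (10, 50, 200), and five condition-grouped
80:20 train/test splits — 45 members by default.  Members train for a
fixed 100 epochs with Adam (lr 1e-3) on mean absolute error, regressing
per-protein z-scored yield on the min-max scaled reaction factors plus an
optional protein descriptor block (one-hot identity or 2D response-profile
embedding coordinates).

Acquisition ranks untested conditions by ``mean + kappa * sd`` of the
member predictions; the default ``kappa = -1`` penalizes member
disagreement so that consistently-high predictions are selected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import r2_score

from ._mlp import MLPRegressor

__all__ = [
    "EnsembleSpec",
    "Ensemble",
    "PredictionSummary",
    "ProteinScaler",
    "scale_yields_per_protein",
    "encode_inputs",
    "train_ensemble",
    "predict_grid",
    "acquire",
    "evaluate_ensemble",
]

DEFAULT_ARCHITECTURES = (
    (128, 64, 32, 16),
    (256, 128, 64, 32, 16),
    (512, 256, 128, 64, 32, 16),
)
DEFAULT_BATCH_SIZES = (10, 50, 200)


@dataclass(frozen=True)
class EnsembleSpec:
    """Hyperparameter cross defining the ensemble members."""

    architectures: tuple = DEFAULT_ARCHITECTURES
    batch_sizes: tuple = DEFAULT_BATCH_SIZES
    n_splits: int = 5
    train_fraction: float = 0.8
    epochs: int = 100
    learning_rate: float = 1e-3
    loss: str = "mae"
    seed: int = 0

    @property
    def n_members(self) -> int:
        return len(self.architectures) * len(self.batch_sizes) * self.n_splits

    def __post_init__(self):
        if self.loss != "mae":
            raise ValueError("only the mean-absolute-error loss is supported")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass(frozen=True)
class PredictionSummary:
    """Per-candidate ensemble summary (z-score units)."""

    condition: object
    mean: float
    sd: float
    score: float


@dataclass
class ProteinScaler:
    """Per-protein z-score scalers, invertible back to raw pmol."""

    means: dict
    sds: dict

    def transform(self, protein, y):
        return (np.asarray(y, float) - self.means[protein]) / self.sds[protein]

    def inverse(self, protein, z):
        return np.asarray(z, float) * self.sds[protein] + self.means[protein]


def scale_yields_per_protein(records: pd.DataFrame, col: str = "yield_pmol"):
    """Z-score yields within each protein (mean 0, SD 1 per protein).

    Zero-variance proteins are excluded with a warning.  Returns the
    scaled table (new column ``yield_z``) and the scaler registry.
    """
    means, sds, keep = {}, {}, []
    for protein, grp in records.groupby("protein"):
        y = grp[col].to_numpy(float)
        sd = y.std(ddof=0)
        if sd == 0 or np.unique(y).size < 2:
            warnings.warn(f"protein {protein!r} has zero yield variance; excluded",
                          stacklevel=2)
            continue
        means[protein] = y.mean()
        sds[protein] = sd
        keep.append(protein)
    out = records[records["protein"].isin(keep)].copy()
    scaler = ProteinScaler(means, sds)
    out["yield_z"] = [
        (y - means[p]) / sds[p] for p, y in zip(out["protein"], out[col])
    ]
    return out, scaler


def encode_inputs(
    conditions,
    proteins=None,
    mode: str = "none",
    protein_index: list | None = None,
    embedding: pd.DataFrame | None = None,
):
    """Build design rows: 5 scaled factors + optional descriptor block.

    mode 'none'    -> factors only;
    mode 'one-hot' -> + one column per protein in ``protein_index`` (a
                      held-out protein simply gets an all-zero block);
    mode 'embedding' -> + that protein's 2 embedding coordinates.
    """
    X = np.asarray(conditions, float)
    if mode == "none":
        return X
    if proteins is None:
        raise ValueError(f"mode {mode!r} requires per-row protein ids")
    proteins = list(proteins)
    if len(proteins) != X.shape[0]:
        raise ValueError("proteins must align with condition rows")
    if mode == "one-hot":
        if protein_index is None:
            protein_index = sorted(set(proteins))
        lookup = {p: i for i, p in enumerate(protein_index)}
        block = np.zeros((X.shape[0], len(protein_index)))
        for r, p in enumerate(proteins):
            if p in lookup:
                block[r, lookup[p]] = 1.0
            # unseen protein: all-zero descriptor by contract
        return np.hstack([X, block])
    if mode == "embedding":
        if embedding is None:
            raise ValueError("embedding mode requires per-protein coordinates")
        missing = sorted(set(proteins) - set(embedding.index))
        if missing:
            raise ValueError(f"no embedding coordinates for proteins: {missing}")
        block = embedding.loc[proteins].to_numpy(float)
        return np.hstack([X, block])
    raise ValueError("mode must be 'none', 'one-hot', or 'embedding'")


def _condition_splits(records, spec, rng, max_retries=20):
    """80:20 splits grouping all replicates of a condition on one side.

    Conditions are keyed by (protein, condition).  A split is re-drawn if
    some protein loses all training conditions.
    """
    keys = records[["protein", "condition"]].drop_duplicates()
    key_tuples = list(keys.itertuples(index=False, name=None))
    proteins = set(keys["protein"])
    n_train = max(1, int(round(spec.train_fraction * len(key_tuples))))
    splits = []
    for _ in range(spec.n_splits):
        for _attempt in range(max_retries):
            order = rng.permutation(len(key_tuples))
            train_keys = {key_tuples[i] for i in order[:n_train]}
            if {p for p, _ in train_keys} == proteins:
                break
        else:
            raise RuntimeError(
                "could not draw a split with >= 1 training condition per protein"
            )
        mask = np.array(
            [(p, c) in train_keys for p, c in
             zip(records["protein"], records["condition"])]
        )
        splits.append(mask)
    return splits


@dataclass
class Ensemble:
    """Trained members plus the encodings they were fitted on."""

    spec: EnsembleSpec
    members: list = field(repr=False)
    member_meta: pd.DataFrame = field(repr=False)  # architecture, batch, split
    encode_kwargs: dict = field(default_factory=dict, repr=False)
    test_predictions: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def n_members(self):
        return len(self.members)

    def predict_members(self, X):
        """(n_members, n_rows) member predictions."""
        return np.vstack([m.predict(X) for m in self.members])


def train_ensemble(
    records: pd.DataFrame,
    spec: EnsembleSpec,
    mode: str = "one-hot",
    factor_cols=None,
    embedding: pd.DataFrame | None = None,
    protein_index: list | None = None,
) -> Ensemble:
    """Train the (architecture x batch size x split) member cross.

    ``records`` must carry per-protein z-scored yields (``yield_z``), a
    ``condition`` key, and min-max scaled factor columns.
    """
    if "yield_z" not in records:
        raise ValueError("records must carry z-scored yields (run "
                         "scale_yields_per_protein first)")
    if factor_cols is None:
        factor_cols = [
            c for c in records.columns
            if c not in {"protein", "condition", "liposome", "replicate",
                         "yield_pmol", "yield_z", "is_outlier"}
        ]
    rng = np.random.default_rng(spec.seed)
    if protein_index is None and mode == "one-hot":
        protein_index = sorted(records["protein"].unique())
    X = encode_inputs(
        records[factor_cols].to_numpy(float),
        proteins=records["protein"] if mode != "none" else None,
        mode=mode, protein_index=protein_index, embedding=embedding,
    )
    y = records["yield_z"].to_numpy(float)
    splits = _condition_splits(records, spec, rng)

    members, meta, test_rows = [], [], []
    member_idx = 0
    for ai, arch in enumerate(spec.architectures):
        for bi, bs in enumerate(spec.batch_sizes):
            for si, train_mask in enumerate(splits):
                model = MLPRegressor(
                    hidden_layers=arch, lr=spec.learning_rate, batch_size=bs,
                    epochs=spec.epochs, seed=spec.seed * 100003 + member_idx,
                )
                model.fit(X[train_mask], y[train_mask])
                members.append(model)
                meta.append({"member": member_idx, "architecture": ai,
                             "batch_size": bs, "split": si})
                test_mask = ~train_mask
                pred = model.predict(X[test_mask])
                test_rows.append(pd.DataFrame({
                    "member": member_idx,
                    "row": np.flatnonzero(test_mask),
                    "observed_z": y[test_mask],
                    "predicted_z": pred,
                }))
                member_idx += 1
    return Ensemble(
        spec=spec,
        members=members,
        member_meta=pd.DataFrame(meta),
        encode_kwargs={
            "mode": mode, "factor_cols": list(factor_cols),
            "protein_index": protein_index, "embedding": embedding,
        },
        test_predictions=pd.concat(test_rows, ignore_index=True),
    )


def predict_grid(
    ensemble: Ensemble,
    candidates,
    proteins=None,
    kappa: float = -1.0,
    condition_labels=None,
):
    """Ensemble mean/SD/score per candidate condition.

    ``candidates`` are factor rows scaled like the training data; the
    descriptor block is appended with the training encoding.  SD is the
    sample standard deviation across members; score = mean + kappa * sd.
    """
    ek = ensemble.encode_kwargs
    X = encode_inputs(
        np.asarray(candidates, float),
        proteins=proteins if ek["mode"] != "none" else None,
        mode=ek["mode"], protein_index=ek["protein_index"],
        embedding=ek["embedding"],
    )
    n_expected = ensemble.members[0]._params[0][0].shape[0]
    if X.shape[1] != n_expected:
        raise ValueError(
            f"encoding mismatch: got {X.shape[1]} columns, trained on {n_expected}"
        )
    preds = ensemble.predict_members(X)
    mean = preds.mean(axis=0)
    sd = preds.std(axis=0, ddof=1) if preds.shape[0] > 1 else np.zeros(X.shape[0])
    if condition_labels is None:
        condition_labels = list(range(X.shape[0]))
    return [
        PredictionSummary(c, float(m), float(s), float(m + kappa * s))
        for c, m, s in zip(condition_labels, mean, sd)
    ]


def acquire(summaries, k: int = 12):
    """Top-k candidates by score; ties broken by higher mean, then order."""
    if k > len(summaries):
        raise ValueError("k exceeds the number of candidates")
    order = sorted(
        range(len(summaries)),
        key=lambda i: (-summaries[i].score, -summaries[i].mean, i),
    )
    return [summaries[i] for i in order[:k]]


def evaluate_ensemble(ensemble: Ensemble, X_holdout, y_holdout):
    """R^2 of the ensemble-mean prediction plus per-member R^2 values."""
    y = np.asarray(y_holdout, float)
    if y.size < 3:
        raise ValueError("need >= 3 held-out observations")
    preds = ensemble.predict_members(np.asarray(X_holdout, float))
    ens_r2 = float(r2_score(y, preds.mean(axis=0)))
    member_r2 = np.array([r2_score(y, p) for p in preds])
    return ens_r2, member_r2
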