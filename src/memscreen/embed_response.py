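"""Response-profile embedding and cross-protein transfer evaluation.

Every (ensemble member, protein) pair predicts the yield of every condition
on the full factor grid, giving a profile matrix of members x proteins rows
by grid-size columns.  t-SNE maps the column-z-scored profiles to 2D; the
per-protein centroid and member dispersion summarize where a protein's
condition response lives.  Transfer is evaluated leave-one-protein-out:
an ensemble trained without a protein predicts that protein's conditions,
with the protein described by nothing, a one-hot identity (all zero at
prediction time), or its 2D profile-embedding coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE
from sklearn.metrics import r2_score

from .active_learn import Ensemble, EnsembleSpec, train_ensemble

__all__ = [
    "ProteinEmbedding",
    "tsne_embed",
    "build_profiles",
    "embed_profiles",
    "interpolate_coords",
    "transfer_eval",
]


def tsne_embed(X, perplexity: float = 30.0, seed: int = 0) -> np.ndarray:
    """2-component t-SNE with PCA init and a fixed seed.

    Perplexity is auto-reduced (with a warning) when the row count is too
    small for the requested value; all-identical rows are rejected.
    """
    X = np.asarray(X, float)
    n = X.shape[0]
    if n < 4:
        raise ValueError("need >= 4 rows to embed")
    if np.allclose(X, X[0]):
        raise ValueError("degenerate profile matrix: all rows identical")
    max_perp = (n - 1) / 3.0
    if perplexity >= max_perp:
        new_p = max(2.0, max_perp - 1e-6)
        warnings.warn(
            f"perplexity {perplexity} too large for {n} rows; reduced to "
            f"{new_p:.1f}",
            stacklevel=2,
        )
        perplexity = new_p
    ts = TSNE(
        n_components=2, perplexity=perplexity, init="pca", random_state=seed,
        max_iter=500,
    )
    return ts.fit_transform(X)


@dataclass(frozen=True)
class ProteinEmbedding:
    """Per-protein summary of the member positions in the 2D plane."""

    coords: pd.DataFrame = field(repr=False)  # (member, protein) -> x, y
    centroids: pd.DataFrame = field(repr=False)  # protein -> x, y
    dispersion: pd.Series = field(repr=False)  # protein -> SD of positions


def build_profiles(ensemble: Ensemble, proteins, grid_encoded) -> pd.DataFrame:
    """Member x protein response-profile matrix over the full grid.

    Rows are indexed by (member, protein); columns by condition; entries
    are predicted z-scored yields, z-scored again per column so every
    condition contributes comparably to the embedding.
    """
    from .active_learn import encode_inputs

    grid_encoded = np.asarray(grid_encoded, float)
    ek = ensemble.encode_kwargs
    rows, index = [], []
    for protein in proteins:
        X = encode_inputs(
            grid_encoded,
            proteins=[protein] * len(grid_encoded) if ek["mode"] != "none" else None,
            mode=ek["mode"], protein_index=ek["protein_index"],
            embedding=ek["embedding"],
        )
        preds = ensemble.predict_members(X)  # (members, conditions)
        for m in range(preds.shape[0]):
            rows.append(preds[m])
            index.append((m, protein))
    mat = pd.DataFrame(
        np.vstack(rows), index=pd.MultiIndex.from_tuples(index,
                                                         names=["member", "protein"])
    )
    # column z-score; constant columns carry no signal and become 0
    sd = mat.std(axis=0, ddof=0).replace(0.0, 1.0)
    return (mat - mat.mean(axis=0)) / sd


def embed_profiles(
    matrix: pd.DataFrame, perplexity: float = 30.0, seed: int = 0
):
    """Embed profile rows to 2D and summarize per protein.

    Returns (coords DataFrame indexed like ``matrix``, ProteinEmbedding).
    Dispersion is the SD of a protein's member positions (2D distances
    from the centroid).
    """
    coords = pd.DataFrame(
        tsne_embed(matrix.to_numpy(), perplexity=perplexity, seed=seed),
        index=matrix.index, columns=["e1", "e2"],
    )
    centroids = coords.groupby(level="protein").mean()
    d2 = (
        (coords - centroids.reindex(coords.index.get_level_values("protein")).
         to_numpy()) ** 2
    ).sum(axis=1)
    dispersion = np.sqrt(d2.groupby(coords.index.get_level_values("protein")).mean())
    return coords, ProteinEmbedding(coords, centroids, dispersion.rename("dispersion"))


def interpolate_coords(
    target_profile: pd.Series,
    reference_profiles: pd.DataFrame,
    centroids: pd.DataFrame,
    k: int = 3,
) -> np.ndarray:
    """Coordinates for an unseen protein by nearest-neighbor interpolation.

    The target's observed mean response profile is compared to each
    reference protein's profile over the shared conditions; the embedding
    coordinates are the inverse-distance weighted mean of the ``k``
    nearest reference centroids.  This keeps the target's data out of both
    the embedding and the ensemble that produced it.
    """
    shared = reference_profiles.columns.intersection(target_profile.index)
    if len(shared) < 2:
        raise ValueError("need >= 2 shared conditions to interpolate coordinates")
    t = target_profile[shared].to_numpy(float)
    diffs = reference_profiles[shared].to_numpy(float) - t
    dist = np.sqrt((diffs**2).mean(axis=1))
    order = np.argsort(dist)[: min(k, len(dist))]
    w = 1.0 / np.maximum(dist[order], 1e-9)
    w = w / w.sum()
    ref_names = reference_profiles.index[order]
    return (centroids.loc[ref_names].to_numpy(float) * w[:, None]).sum(axis=0)


def _observed_profiles(records: pd.DataFrame) -> pd.DataFrame:
    """Per-protein mean observed z-scored yield per condition."""
    return records.pivot_table(index="protein", columns="condition",
                               values="yield_z", aggfunc="mean")


def transfer_eval(
    records: pd.DataFrame,
    spec: EnsembleSpec,
    mode: str = "one-hot",
    grid_encoded=None,
    factor_cols=None,
    perplexity: float = 30.0,
    seed: int = 0,
) -> pd.Series:
    """Leave-one-protein-out R^2 for the chosen descriptor mode.

    ``records`` must carry ``yield_z`` and scaled factor columns.  For the
    embedding mode, each held-out protein's coordinates come from an
    embedding built on an ensemble trained without its data, via
    :func:`interpolate_coords`.  Proteins with < 3 observed conditions are
    skipped with a warning.  Returns protein -> R^2.
    """
    proteins = sorted(records["protein"].unique())
    if len(proteins) < 3:
        raise ValueError("need >= 3 proteins for leave-one-out transfer")
    if factor_cols is None:
        factor_cols = [
            c for c in records.columns
            if c not in {"protein", "condition", "liposome", "replicate",
                         "yield_pmol", "yield_z", "is_outlier"}
        ]
    obs_profiles = _observed_profiles(records)
    out = {}
    for held in proteins:
        held_rows = records[records["protein"] == held]
        if held_rows["condition"].nunique() < 3:
            warnings.warn(f"protein {held!r} has < 3 conditions; skipped",
                          stacklevel=2)
            continue
        train_rows = records[records["protein"] != held]
        train_proteins = sorted(train_rows["protein"].unique())
        if mode in ("none", "one-hot"):
            ens = train_ensemble(
                train_rows, spec, mode=mode, factor_cols=factor_cols,
                protein_index=train_proteins if mode == "one-hot" else None,
            )
            embedding = None
        elif mode == "embedding":
            if grid_encoded is None:
                raise ValueError("embedding mode requires grid_encoded")
            profile_ens = train_ensemble(
                train_rows, spec, mode="one-hot", factor_cols=factor_cols,
                protein_index=train_proteins,
            )
            matrix = build_profiles(profile_ens, train_proteins, grid_encoded)
            _, emb = embed_profiles(matrix, perplexity=perplexity, seed=seed)
            held_coords = interpolate_coords(
                obs_profiles.loc[held].dropna(),
                obs_profiles.loc[train_proteins],
                emb.centroids,
            )
            embedding = pd.concat(
                [emb.centroids,
                 pd.DataFrame([held_coords], index=[held],
                              columns=emb.centroids.columns)]
            )
            # min-max scale coordinates (fit on training proteins only) so
            # the descriptor block matches the [0, 1] factor scale
            lo = emb.centroids.min()
            span = (emb.centroids.max() - lo).replace(0.0, 1.0)
            embedding = (embedding - lo) / span
            ens = train_ensemble(
                train_rows, spec, mode="embedding", factor_cols=factor_cols,
                embedding=embedding,
            )
        else:
            raise ValueError("mode must be 'none', 'one-hot', or 'embedding'")
        from .active_learn import encode_inputs

        X_held = encode_inputs(
            held_rows[factor_cols].to_numpy(float),
            proteins=list(held_rows["protein"]) if mode != "none" else None,
            mode=mode,
            protein_index=train_proteins if mode == "one-hot" else None,
            embedding=embedding,
        )
        preds = ens.predict_members(X_held).mean(axis=0)
        out[held] = float(r2_score(held_rows["yield_z"].to_numpy(float), preds))
    return pd.Series(out, name=f"r2_{mode}")
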