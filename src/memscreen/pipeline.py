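"""End-to-end orchestration of the synthetic campaign.

A single seeded configuration drives simulate -> calibrate -> design ->
screen -> learn -> embed -> featurize -> classify; each stage writes CSV
artifacts stamped with a hash of the configuration so runs are traceable
and byte-reproducible under a fixed master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import (
    active_learn,
    classify,
    design,
    embed_response,
    quantify,
    screen_stats,
    structure_feats,
    synthetic_data,
)

__all__ = ["RunConfig", "run_pipeline", "STAGES"]

STAGES = (
    "simulate", "calibrate", "design", "screen", "learn", "embed",
    "featurize", "classify",
)


@dataclass(frozen=True)
class RunConfig:
    """All knobs of a campaign; defaults are the pipeline's fixed constants.

    min_delta 1 pmol and alpha 0.05 define a success call; k = 12
    conditions are acquired per active-learning round; classifier
    accuracy gates are 0.77 (pairing) and 0.85 (comprehensive); the
    confidence categories use 0.7/0.2 (likely) and 0.3/0.15 (unlikely);
    the membrane layer boundaries pin 6 A (inner hydrophobic) and 30 A
    (water).
    """

    seed: int = 0
    outdir: str = "results/pipeline"
    n_proteins: int = 8
    gsd_reduction: int = 3
    min_delta: float = screen_stats.MIN_DELTA_PMOL
    alpha: float = screen_stats.ALPHA
    acquisition_k: int = 12
    kappa: float = -1.0
    pair_threshold: float = classify.ACCURACY_PAIR_THRESHOLD
    comprehensive_threshold: float = classify.ACCURACY_COMPREHENSIVE_THRESHOLD
    layer_boundaries: tuple = (6.0, 15.0, 20.0, 30.0)
    alpha_scale: float = 2.5
    ensemble: active_learn.EnsembleSpec = field(
        default_factory=active_learn.EnsembleSpec
    )
    landscape_noise_sd: float = 0.5
    landscape_outlier_rate: float = 0.075

    def hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            return str(o)

        fields = dataclasses.asdict(self)
        fields.pop("outdir")  # where artifacts land does not change them
        payload = json.dumps(fields, default=enc, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _write(df: pd.DataFrame, path: Path, cfg_hash: str, index=False):
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# config={cfg_hash}\n")
        df.to_csv(fh, index=index)


def run_pipeline(cfg: RunConfig, stages=STAGES) -> dict:
    """Execute the requested stages; returns the in-memory artifacts.

    Stages consume the artifacts of earlier stages; a missing upstream
    artifact raises an error naming the stage to run first.
    """
    stages = list(stages)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(cfg.outdir)
    h = cfg.hash()
    art = {"config_hash": h}
    grid = design.default_grid()

    def need(key, stage):
        if key not in art:
            raise RuntimeError(f"missing artifact {key!r}: run stage "
                               f"{stage!r} first")
        return art[key]

    if "design" in stages or "simulate" in stages:
        full = design.full_factorial(grid)
        subset = design.gsd(grid, cfg.gsd_reduction)
        art["design_full"] = full
        art["design_gsd"] = subset
        if "design" in stages:
            _write(subset.to_frame(), out / "design_gsd.csv", h)
            _write(full.to_frame(), out / "design_full.csv", h)

    if "simulate" in stages:
        lcfg = synthetic_data.LandscapeConfig(
            n_proteins=cfg.n_proteins, grid=grid,
            noise_sd=cfg.landscape_noise_sd,
            outlier_rate=cfg.landscape_outlier_rate, seed=cfg.seed,
        )
        records, truth = synthetic_data.gen_yield_landscape(
            lcfg, design=art["design_gsd"]
        )
        art["records"], art["truth"] = records, truth
        _write(records, out / "screen_records.csv", h)

    if "calibrate" in stages:
        amounts, fluo = synthetic_data.gen_calibration_points(
            L=30000.0, k=1.2, x0=4.0, b=500.0, n=12, noise_sd=300.0,
            seed=cfg.seed + 1,
        )
        fit = quantify.fit_calibration(amounts, fluo)
        art["calibration"] = fit
        _write(
            pd.DataFrame([dataclasses.asdict(fit)]),
            out / "calibration_fit.csv", h,
        )

    if "screen" in stages:
        records = need("records", "simulate")
        calls = screen_stats.call_screen(records, condition_cols=["condition"],
                                         min_delta=cfg.min_delta,
                                         alpha=cfg.alpha)
        art["calls"] = calls
        _write(calls, out / "success_calls.csv", h)

    if "learn" in stages:
        records = need("records", "simulate")
        scaled, scaler = active_learn.scale_yields_per_protein(
            records[records["liposome"]]
        )
        ens = active_learn.train_ensemble(scaled, cfg.ensemble, mode="one-hot",
                                          factor_cols=grid.names)
        art["scaled"], art["scaler"], art["ensemble"] = scaled, scaler, ens
        full = need("design_full", "design")
        proteins = sorted(scaled["protein"].unique())
        acq_rows = []
        for protein in proteins:
            tested = set(
                scaled.loc[scaled["protein"] == protein, "condition"]
            )
            cand = [i for i in range(len(full)) if i not in tested]
            summaries = active_learn.predict_grid(
                ens, full.encoded[cand], proteins=[protein] * len(cand),
                kappa=cfg.kappa, condition_labels=cand,
            )
            for s in active_learn.acquire(summaries,
                                          k=min(cfg.acquisition_k, len(cand))):
                acq_rows.append({"protein": protein, "condition": s.condition,
                                 "mean": s.mean, "sd": s.sd, "score": s.score})
        art["acquired"] = pd.DataFrame(acq_rows)
        _write(art["acquired"], out / "acquired_conditions.csv", h)

    if "embed" in stages:
        ens = need("ensemble", "learn")
        scaled = art["scaled"]
        full = need("design_full", "design")
        proteins = sorted(scaled["protein"].unique())
        matrix = embed_response.build_profiles(ens, proteins, full.encoded)
        coords, emb = embed_response.embed_profiles(matrix, seed=cfg.seed)
        art["profile_matrix"], art["embedding"] = matrix, emb
        _write(emb.centroids.join(emb.dispersion),
               out / "protein_embedding.csv", h, index=True)

    if "featurize" in stages:
        structures = {}
        rng = np.random.default_rng(cfg.seed + 7)
        for p in range(cfg.n_proteins):
            bcfg = synthetic_data.BundleConfig(
                n_helices=4, helix_length=20, ring_radius=8.0,
                hydrophobicity_signal=float(rng.uniform(-0.8, 0.8)),
                seed=cfg.seed * 1000 + p,
            )
            bundle = synthetic_data.gen_helix_bundle(bcfg, protein_id=f"P{p:02d}")
            structures[f"P{p:02d}"] = structure_feats.annotated_from_bundle(bundle)
        feats = structure_feats.featurize(
            structures, boundaries=cfg.layer_boundaries,
            alpha_scale=cfg.alpha_scale,
        )
        art["features"] = feats
        art["protein_length"] = pd.Series(
            {sid: len(st.residues) for sid, st in structures.items()},
            name="length",
        )
        _write(feats, out / "structure_features.csv", h, index=True)

    if "classify" in stages:
        calls = need("calls", "screen")
        feats = need("features", "featurize")
        labels = classify.label_proteins(calls, min_delta=cfg.min_delta,
                                         alpha=cfg.alpha)
        labels = labels.reindex(feats.index).dropna().astype(int)
        art["labels"] = labels
        counts = labels.value_counts()
        if labels.nunique() < 2 or counts.min() < 3:
            # too small / one-sided a panel to train stratified ensembles
            art["classifiers"] = {}
        else:
            perp = max(2.0, min(30.0, (len(feats) - 1) / 3 - 1))
            results = classify.search_embeddings(
                feats, labels, perplexity=perp, seed=cfg.seed,
            )
            art["classifiers"] = results
            acc = pd.Series({k: v.accuracy for k, v in results.items()},
                            name="accuracy")
            _write(acc.to_frame(), out / "embedding_accuracy.csv", h,
                   index=True)

    return art
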