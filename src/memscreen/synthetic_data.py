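"""Synthetic fixtures with the statistical structure the analysis assumes.

Three generators:

* ``gen_yield_landscape`` — per-protein factorial response surfaces for the
  liposome synthesis screen: a quadratic bowl over the min-max scaled
  factors with a protein-specific optimum plus pairwise interaction terms,
  quadruplicate replicates with and without liposomes, i.i.d. normal
  replicate noise, and symmetric outlier contamination.  Protein optima are
  driven by a latent 2D coordinate so that cross-protein structure exists
  for the response-profile embedding to discover.
* ``gen_helix_bundle`` — idealized alpha-helical TM bundles (1.5 A rise,
  100 deg twist per residue) on a ring, with alternating up/down topology,
  UniProt-style helix annotations, and a plantable hydrophobicity class
  signal on the lipid-facing residues.
* ``gen_calibration_points`` — noisy points on the four-parameter sigmoid
  used by the yield calibration.

These emulate the screen's statistics, not real CFPS biochemistry or real
predicted structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DesignMatrix, FactorGrid, full_factorial
from .quantify import sigmoid

__all__ = [
    "LandscapeConfig",
    "GroundTruth",
    "gen_yield_landscape",
    "BundleConfig",
    "HelixBundle",
    "gen_helix_bundle",
    "gen_calibration_points",
]

# ---------------------------------------------------------------------------
# yield landscapes


@dataclass(frozen=True)
class LandscapeConfig:
    """Study conditions for a synthetic screen.

    Defaults mirror the screen: quadruplicate replicates per arm, matched
    no-liposome controls, 7.5% outlier contamination, and planted effects
    of a few pmol (the scale of the reported liposome gains).
    """

    n_proteins: int
    grid: FactorGrid
    effect_scale: float = 4.0  # pmol, response-surface amplitude
    interaction_scale: float = 1.0  # pmol, pairwise-term amplitude
    noise_sd: float = 0.5  # pmol, replicate noise
    baseline_no_liposome: float = 0.5  # pmol
    outlier_rate: float = 0.075
    replicates: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.replicates < 3:
            raise ValueError("replicates must be >= 3")
        if not 0 <= self.outlier_rate < 0.5:
            raise ValueError("outlier_rate must be in [0, 0.5)")
        if min(self.effect_scale, self.interaction_scale, self.noise_sd) < 0:
            raise ValueError("scales must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """True surfaces behind a generated screen."""

    proteins: list
    conditions: pd.DataFrame  # encoded factor values, one row per condition
    true_mean: pd.DataFrame  # (protein x condition) true +liposome mean, pmol
    optimum: pd.Series  # per protein: condition index of the true maximum
    optimum_encoding: pd.DataFrame  # per protein: encoded factor optimum
    latent: pd.DataFrame  # per protein: 2D latent coordinate

    def condition_mean(self, protein, condition_idx):
        return float(self.true_mean.loc[protein, condition_idx])


def _surface(cfg: LandscapeConfig, encoded, optima, pair_w, pairs):
    """True +liposome mean yield per (protein, condition), pmol."""
    n_p = optima.shape[0]
    n_c = encoded.shape[0]
    out = np.empty((n_p, n_c))
    # curvature normalized so the bowl spans ~effect_scale over the unit
    # cell (mean squared factor distance to the optimum is at most ~0.4)
    for p in range(n_p):
        sq = ((encoded - optima[p]) ** 2).mean(axis=1)
        s = cfg.baseline_no_liposome + cfg.effect_scale * (1.0 - sq / 0.4)
        for w, (i, j) in zip(pair_w[p], pairs[p]):
            s = s + cfg.interaction_scale * w * encoded[:, i] * encoded[:, j]
        out[p] = np.maximum(s, 0.0)  # yields cannot go below zero
    return out


def gen_yield_landscape(cfg: LandscapeConfig, design: DesignMatrix | None = None):
    """Generate a tidy screen table plus its ground truth.

    Returns ``(records, truth)`` where ``records`` has columns protein,
    condition (index into the design), one encoded column per factor,
    liposome, replicate, yield_pmol, is_outlier.
    """
    if design is None:
        design = full_factorial(cfg.grid)
    if len(design) < 2:
        raise ValueError("degenerate design: need >= 2 conditions to screen")
    rng = np.random.default_rng(cfg.seed)
    # conditions are keyed by their index in the full factorial so that a
    # subset design and later whole-grid predictions share one labeling
    full = full_factorial(cfg.grid)
    encoded = full.encoded
    cond_ids = np.ravel_multi_index(design.rows.T, cfg.grid.shape)
    n_f = encoded.shape[1]
    proteins = [f"P{p:02d}" for p in range(cfg.n_proteins)]

    # protein optima vary smoothly with a latent 2D coordinate
    latent = rng.uniform(size=(cfg.n_proteins, 2))
    mix = rng.uniform(-1.0, 1.0, size=(n_f, 2))
    optima = np.clip(0.5 + latent @ mix.T * 0.8, 0.0, 1.0)

    # 1-3 pairwise interaction terms per protein, signed weights
    pairs_all = [(i, j) for i in range(n_f) for j in range(i + 1, n_f)]
    pairs, pair_w = [], []
    for _ in range(cfg.n_proteins):
        k = rng.integers(1, min(3, len(pairs_all)) + 1)
        idx = rng.choice(len(pairs_all), size=k, replace=False)
        pairs.append([pairs_all[i] for i in idx])
        pair_w.append(rng.uniform(-1.0, 1.0, size=k))

    true_mean = _surface(cfg, encoded, optima, pair_w, pairs)

    rows = []
    for p, prot in enumerate(proteins):
        for c in cond_ids:
            for lipo in (True, False):
                mu = true_mean[p, c] if lipo else cfg.baseline_no_liposome
                y = mu + rng.normal(0.0, cfg.noise_sd, size=cfg.replicates)
                out_mask = rng.random(cfg.replicates) < cfg.outlier_rate
                if cfg.noise_sd > 0:
                    # symmetric inflation to |deviation| >= 4 noise_sd
                    n_out = int(out_mask.sum())
                    if n_out:
                        mag = (4.0 + rng.exponential(1.0, n_out)) * cfg.noise_sd
                        sign = rng.choice([-1.0, 1.0], n_out)
                        y[out_mask] = mu + sign * mag
                else:
                    out_mask[:] = False
                for r in range(cfg.replicates):
                    rows.append((prot, int(c), lipo, r, y[r], bool(out_mask[r])))
    records = pd.DataFrame(
        rows,
        columns=["protein", "condition", "liposome", "replicate", "yield_pmol",
                 "is_outlier"],
    )
    factor_names = cfg.grid.names
    enc_df = pd.DataFrame(encoded, columns=factor_names)
    records = records.join(enc_df, on="condition")

    opt_idx = pd.Series(true_mean.argmax(axis=1), index=proteins, name="optimum")
    truth = GroundTruth(
        proteins=proteins,
        conditions=enc_df,
        true_mean=pd.DataFrame(true_mean, index=proteins),
        optimum=opt_idx,
        optimum_encoding=pd.DataFrame(optima, index=proteins, columns=factor_names),
        latent=pd.DataFrame(latent, index=proteins, columns=["u1", "u2"]),
    )
    return records, truth


# ---------------------------------------------------------------------------
# helix bundles

RISE_PER_RESIDUE = 1.5  # A, ideal alpha helix
TWIST_PER_RESIDUE = 100.0  # degrees
CA_RADIUS = 2.3  # A, Calpha distance from the helix axis
CB_EXTRA = 1.5  # A, sidechain pseudo-atom beyond the Calpha radius
MIN_AXIS_SPACING = 7.0  # A, clash-free helix axis separation

HYDROPHOBIC = ("LEU", "ILE", "VAL", "PHE", "MET", "ALA")
POLAR = ("SER", "THR", "ASN", "GLN", "LYS", "GLU", "ASP", "ARG")


@dataclass(frozen=True)
class BundleConfig:
    """Idealized TM helix bundle.

    ``hydrophobicity_signal`` in [-1, 1] biases the amino-acid identities
    of lipid-facing membrane residues toward hydrophobic (+1) or polar
    (-1); 0 is an even mix.  ``center_helix`` places one helix on the
    bundle axis and the remaining ``n_helices - 1`` on the ring.
    """

    n_helices: int = 4
    helix_length: int = 20  # residues
    ring_radius: float = 8.0  # A
    hydrophobicity_signal: float = 0.0
    seed: int = 0
    center_helix: bool = False

    def __post_init__(self):
        if self.n_helices < 1:
            raise ValueError("n_helices must be >= 1")
        if self.helix_length < 4:
            raise ValueError("helix_length must be >= 4")
        if not -1.0 <= self.hydrophobicity_signal <= 1.0:
            raise ValueError("hydrophobicity_signal must be in [-1, 1]")


@dataclass(frozen=True)
class HelixBundle:
    """Generated bundle: PDB text plus its TM annotation table."""

    pdb_text: str
    annotations: pd.DataFrame  # protein_id, helix_index, start, end
    residues: pd.DataFrame = field(repr=False)  # resseq, aa, per-atom coords

    def write(self, pdb_path, annotation_path=None):
        with open(pdb_path, "w") as fh:
            fh.write(self.pdb_text)
        if annotation_path is not None:
            self.annotations.to_csv(annotation_path, sep="\t", index=False)


def _pdb_atom(serial, name, resname, resseq, xyz):
    x, y, z = xyz
    return (
        f"ATOM  {serial:5d} {name:^4s}{resname:>4s} A{resseq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
    )


def gen_helix_bundle(cfg: BundleConfig, protein_id: str = "synthetic") -> HelixBundle:
    """Build an ideal alternating-topology helix bundle on a ring.

    Each residue carries a Calpha and a sidechain pseudo-atom (CB) placed
    radially outward from the helix axis, so residue centroids differ from
    the Calpha positions.  Raises if ``ring_radius`` is too small for
    clash-free placement.
    """
    rng = np.random.default_rng(cfg.seed)
    n_ring = cfg.n_helices - 1 if cfg.center_helix else cfg.n_helices
    axes = []
    if cfg.center_helix:
        axes.append((0.0, 0.0))
        if cfg.ring_radius < MIN_AXIS_SPACING:
            raise ValueError(
                f"ring_radius {cfg.ring_radius} A too small: center-to-ring "
                f"spacing must be >= {MIN_AXIS_SPACING} A"
            )
    if n_ring > 1:
        chord = 2 * cfg.ring_radius * np.sin(np.pi / n_ring)
        if chord < MIN_AXIS_SPACING:
            raise ValueError(
                f"ring_radius {cfg.ring_radius} A too small for {n_ring} "
                f"helices: axis spacing {chord:.1f} < {MIN_AXIS_SPACING} A"
            )
    for h in range(n_ring):
        th = 2 * np.pi * h / max(n_ring, 1)
        axes.append((cfg.ring_radius * np.cos(th), cfg.ring_radius * np.sin(th)))

    span = (cfg.helix_length - 1) * RISE_PER_RESIDUE
    half = span / 2.0
    membrane_half = 20.0  # used only to decide which residues carry the signal

    records, ann, resseq = [], [], 0
    p_hydro = 0.5 + 0.5 * cfg.hydrophobicity_signal
    for h, (ax, ay) in enumerate(axes):
        up = h % 2 == 0  # alternating up/down topology
        start = resseq + 1
        for i in range(cfg.helix_length):
            resseq += 1
            z = (-half + i * RISE_PER_RESIDUE) * (1 if up else -1)
            phase = np.deg2rad(TWIST_PER_RESIDUE * i) + 2 * np.pi * h / len(axes)
            dx, dy = np.cos(phase), np.sin(phase)
            # coordinates rounded to PDB precision so files round-trip exactly
            ca = np.round([ax + CA_RADIUS * dx, ay + CA_RADIUS * dy, z], 3)
            cb = np.round(
                [ax + (CA_RADIUS + CB_EXTRA) * dx, ay + (CA_RADIUS + CB_EXTRA) * dy, z],
                3,
            )
            # lipid-facing = sidechain points away from the bundle axis
            radial = np.array([ax, ay])
            outward = (
                bool(np.dot([dx, dy], radial) > 0)
                if np.linalg.norm(radial) > 1e-9
                else False
            )
            in_membrane = abs(z) < membrane_half
            if outward and in_membrane:
                aa = (
                    rng.choice(HYDROPHOBIC)
                    if rng.random() < p_hydro
                    else rng.choice(POLAR)
                )
            else:
                pool = HYDROPHOBIC + POLAR + ("GLY",)
                aa = rng.choice(pool)
            records.append((resseq, aa, h, outward, ca, cb))
        ann.append((protein_id, h, start, resseq))

    lines, serial = [], 0
    for resseq_, aa, *_rest, ca, cb in records:
        serial += 1
        lines.append(_pdb_atom(serial, "CA", aa, resseq_, ca))
        serial += 1
        lines.append(_pdb_atom(serial, "CB", aa, resseq_, cb))
    lines.append("END")
    pdb_text = "\n".join(lines) + "\n"

    res_df = pd.DataFrame(
        [
            {
                "resseq": r, "aa": aa, "helix": h, "lipid_facing": outward,
                "ca_x": ca[0], "ca_y": ca[1], "ca_z": ca[2],
                "cb_x": cb[0], "cb_y": cb[1], "cb_z": cb[2],
            }
            for r, aa, h, outward, ca, cb in records
        ]
    )
    ann_df = pd.DataFrame(
        ann, columns=["protein_id", "helix_index", "start", "end"]
    )
    return HelixBundle(pdb_text, ann_df, res_df)


# ---------------------------------------------------------------------------
# calibration points


def gen_calibration_points(L, k, x0, b, n=12, noise_sd=0.0, seed=0, amounts=None):
    """Noisy points on the calibration sigmoid.

    Amounts default to an even span of [0, 2*x0] (bracketing the
    inflection).  Returns (amount, fluorescence) arrays.
    """
    if L <= 0 or k <= 0:
        raise ValueError("need L > 0 and k > 0")
    if n < 6:
        raise ValueError("need n >= 6 calibration points")
    rng = np.random.default_rng(seed)
    if amounts is None:
        amounts = np.linspace(0.0, 2.0 * x0, n)
    amounts = np.asarray(amounts, float)
    y = sigmoid(amounts, L, k, x0, b)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=amounts.shape)
    return amounts, y
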