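"""Membrane-frame featurization of alpha-helical membrane proteins.

A structure with UniProt-style transmembrane-helix annotations is oriented
into a mock bilayer: helix termini are split into the two membrane sides by
alternating topology, the midpoint of the two side centers is translated to
the origin, and the side-to-side axis is rotated onto +z, so the membrane
midplane is z = 0.

Each residue (heavy-atom centroid) is then assigned to

* a layer by |z|: inner hydrophobic (< 6 A), outer hydrophobic, interface,
  polar, and water-exposed (> 30 A), and
* a shell: membrane-layer residues are either in contact with the
  surrounding lipid (within 4 A of the alpha-shape outer surface of the
  protein) or interior; polar/water residues are external.

That yields 8 location bins — (3 membrane layers x 2 shells) + (2 outside
layers x 1 shell).  Four per-residue metrics (charge, Wimley-White
interfacial hydrophobicity, depth = neighbor centroids within 6 A, and a
location-enrichment probability) are averaged within each bin: 32 features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np
import pandas as pd
import trimesh
from scipy.spatial import Delaunay, QhullError, cKDTree

__all__ = [
    "WIMLEY_WHITE_INTERFACE",
    "CHARGE",
    "MEMBRANE_LAYERS",
    "LOCATION_BINS",
    "METRICS",
    "AnnotatedStructure",
    "OrientedStructure",
    "QCResult",
    "ProbabilityReference",
    "read_structure",
    "annotated_from_bundle",
    "orient",
    "qc",
    "assign_layers",
    "lipid_shell",
    "residue_metrics",
    "featurize_structure",
    "featurize",
    "feature_names",
]

#: Wimley & White interfacial partitioning free energies (kcal/mol; positive
#: = unfavorable transfer into the POPC interface). Whole-residue scale.
WIMLEY_WHITE_INTERFACE = {
    "ALA": 0.17, "ARG": 0.81, "ASN": 0.42, "ASP": 1.23, "CYS": -0.24,
    "GLN": 0.58, "GLU": 2.02, "GLY": 0.01, "HIS": 0.17, "ILE": -0.31,
    "LEU": -0.56, "LYS": 0.99, "MET": -0.23, "PHE": -1.13, "PRO": 0.45,
    "SER": 0.13, "THR": 0.14, "TRP": -1.85, "TYR": -0.94, "VAL": 0.07,
}

#: Formal charge rule: Arg/Lys/His +1, Glu/Asp -1, all others 0.
CHARGE = {"ARG": 1, "LYS": 1, "HIS": 1, "GLU": -1, "ASP": -1}

LAYERS = ("inner_hydrophobic", "outer_hydrophobic", "interface", "polar", "water")
MEMBRANE_LAYERS = ("inner_hydrophobic", "outer_hydrophobic", "interface")
METRICS = ("charge", "hydrophobicity", "depth", "probability")

#: The 8 location bins: membrane layers split by lipid contact, outside
#: layers form a single external shell each.
LOCATION_BINS = tuple(
    [(layer, shell) for layer in MEMBRANE_LAYERS
     for shell in ("interior", "membrane_contacting")]
    + [("polar", "external"), ("water", "external")]
)

DEPTH_BIN_EDGES = (3, 6, 9)  # depth bins {0-2, 3-5, 6-8, >=9}


def feature_names(expanded: bool = False) -> list:
    stats = ("mean",) if not expanded else ("mean", "min", "max", "sum")
    return [
        f"{layer}_{shell}__{metric}" + ("" if not expanded else f"__{stat}")
        for layer, shell in LOCATION_BINS
        for metric in METRICS
        for stat in stats
    ]


@dataclass(frozen=True)
class AnnotatedStructure:
    """Residue table + TM helix ranges.

    ``residues`` columns: resseq, aa, x, y, z (heavy-atom centroid).
    ``atoms`` columns: resseq, x, y, z.  ``helices`` columns: helix_index,
    start, end (1-based inclusive residue numbers, ordered).
    """

    residues: pd.DataFrame = field(repr=False)
    atoms: pd.DataFrame = field(repr=False)
    helices: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        h = self.helices.sort_values("start").reset_index(drop=True)
        if (h["start"] > h["end"]).any():
            raise ValueError("helix start must be <= end")
        if (h["start"].iloc[1:].to_numpy() <= h["end"].iloc[:-1].to_numpy()).any():
            raise ValueError("helix ranges overlap")
        present = set(self.residues["resseq"])
        missing = []
        for _, row in h.iterrows():
            missing += [r for r in (row["start"], row["end"]) if r not in present]
        if missing:
            raise ValueError(f"annotated residues missing from structure: {missing}")
        object.__setattr__(self, "helices", h)

    @property
    def tm_mask(self) -> np.ndarray:
        res = self.residues["resseq"].to_numpy()
        mask = np.zeros(res.size, bool)
        for _, row in self.helices.iterrows():
            mask |= (res >= row["start"]) & (res <= row["end"])
        return mask


@dataclass(frozen=True)
class OrientedStructure:
    """Annotated structure in the membrane frame (midplane z = 0)."""

    structure: AnnotatedStructure
    rotation: np.ndarray = field(repr=False)
    translation: np.ndarray = field(repr=False)

    @property
    def residues(self):
        return self.structure.residues

    @property
    def helices(self):
        return self.structure.helices

    @property
    def z(self) -> np.ndarray:
        return self.structure.residues["z"].to_numpy(float)

    @property
    def centroids(self) -> np.ndarray:
        return self.structure.residues[["x", "y", "z"]].to_numpy(float)


def read_structure(pdb_path, annotations, chain: str | None = None) -> AnnotatedStructure:
    """Read a PDB file and a helix-annotation table.

    ``annotations`` is a path to a TSV (protein_id, helix_index, start,
    end) or an equivalent DataFrame.  Only the first chain is used unless
    ``chain`` is given.  Hydrogens are skipped; residue positions are
    heavy-atom centroids.
    """
    st = gemmi.read_structure(str(pdb_path))
    st.setup_entities()
    model = st[0]
    ch = model[chain] if chain is not None else model[0]
    res_rows, atom_rows = [], []
    for res in ch:
        coords = [
            (a.pos.x, a.pos.y, a.pos.z)
            for a in res
            if a.element.name != "H"
        ]
        if not coords:
            continue
        arr = np.array(coords)
        res_rows.append(
            (res.seqid.num, res.name.upper(), *arr.mean(axis=0))
        )
        for xyz in coords:
            atom_rows.append((res.seqid.num, *xyz))
    residues = pd.DataFrame(res_rows, columns=["resseq", "aa", "x", "y", "z"])
    atoms = pd.DataFrame(atom_rows, columns=["resseq", "x", "y", "z"])
    if isinstance(annotations, pd.DataFrame):
        ann = annotations.copy()
    else:
        ann = pd.read_csv(annotations, sep="\t")
    helices = ann[["helix_index", "start", "end"]].astype(int)
    return AnnotatedStructure(residues, atoms, helices)


def annotated_from_bundle(bundle) -> AnnotatedStructure:
    """Build an AnnotatedStructure directly from a generated helix bundle."""
    res = bundle.residues
    ca = res[["ca_x", "ca_y", "ca_z"]].to_numpy()
    cb = res[["cb_x", "cb_y", "cb_z"]].to_numpy()
    cen = (ca + cb) / 2.0
    residues = pd.DataFrame(
        {"resseq": res["resseq"], "aa": res["aa"],
         "x": cen[:, 0], "y": cen[:, 1], "z": cen[:, 2]}
    )
    atoms = pd.concat(
        [
            pd.DataFrame({"resseq": res["resseq"], "x": ca[:, 0],
                          "y": ca[:, 1], "z": ca[:, 2]}),
            pd.DataFrame({"resseq": res["resseq"], "x": cb[:, 0],
                          "y": cb[:, 1], "z": cb[:, 2]}),
        ],
        ignore_index=True,
    )
    helices = bundle.annotations[["helix_index", "start", "end"]].astype(int)
    return AnnotatedStructure(residues, atoms, helices)


def _rotation_to_z(v: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector v onto +z (Rodrigues)."""
    v = v / np.linalg.norm(v)
    ez = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(v, ez))
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])
    axis = np.cross(v, ez)
    s = np.linalg.norm(axis)
    axis = axis / s
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + s * K + (1 - c) * (K @ K)


def orient(structure: AnnotatedStructure) -> OrientedStructure:
    """Place the membrane-spanning region at the origin, midplane = z = 0.

    Helix termini are partitioned into the two membrane sides assuming
    alternating topology (the end of helix 1 shares a side with the start
    of helix 2): helix h contributes its start terminus to side A when h is
    even, to side B when odd.  The two side centers (means of the terminal
    residue centroids) define the membrane normal; their midpoint is
    translated to the origin and the A->B axis rotated onto +z.
    """
    hel = structure.helices
    if len(hel) < 2:
        raise ValueError(
            "orientation needs >= 2 TM helices (single-helix topology is "
            "underdetermined)"
        )
    res = structure.residues.set_index("resseq")
    side_a, side_b = [], []
    for h, row in hel.reset_index(drop=True).iterrows():
        start_pt = res.loc[row["start"], ["x", "y", "z"]].to_numpy(float)
        end_pt = res.loc[row["end"], ["x", "y", "z"]].to_numpy(float)
        if h % 2 == 0:
            side_a.append(start_pt)
            side_b.append(end_pt)
        else:
            side_b.append(start_pt)
            side_a.append(end_pt)
    center_a = np.mean(side_a, axis=0)
    center_b = np.mean(side_b, axis=0)
    mid = (center_a + center_b) / 2.0
    R = _rotation_to_z(center_b - center_a)

    def xform(df):
        xyz = (df[["x", "y", "z"]].to_numpy(float) - mid) @ R.T
        out = df.copy()
        out[["x", "y", "z"]] = xyz
        return out

    oriented = AnnotatedStructure(
        xform(structure.residues), xform(structure.atoms), structure.helices
    )
    return OrientedStructure(oriented, rotation=R, translation=-mid)


@dataclass(frozen=True)
class QCResult:
    """Orientation sanity metrics and the pass/fail verdict."""

    tm_within_membrane: float  # fraction of TM residues with |z| <= edge
    non_tm_within_membrane: float
    min_helix_span: float  # A
    passed: bool


def qc(
    oriented: OrientedStructure,
    membrane_edge: float = 20.0,
    min_tm_fraction: float = 0.75,
    min_span: float = 10.0,
) -> QCResult:
    """Check the oriented structure against its annotations.

    Fails when fewer than ``min_tm_fraction`` of annotated TM residues sit
    within ``membrane_edge`` of the midplane, or when any annotated helix
    spans less than ``min_span`` A in z (a physically impossible TM label).
    """
    z = oriented.z
    tm = oriented.structure.tm_mask
    tm_ok = float(np.mean(np.abs(z[tm]) <= membrane_edge)) if tm.any() else 0.0
    non_tm = ~tm
    non_tm_in = (
        float(np.mean(np.abs(z[non_tm]) <= membrane_edge)) if non_tm.any() else 0.0
    )
    res = oriented.residues["resseq"].to_numpy()
    spans = []
    for _, row in oriented.helices.iterrows():
        sel = (res >= row["start"]) & (res <= row["end"])
        spans.append(float(z[sel].max() - z[sel].min()))
    min_helix_span = min(spans)
    passed = (tm_ok >= min_tm_fraction) and (min_helix_span >= min_span)
    return QCResult(tm_ok, non_tm_in, min_helix_span, passed)


def assign_layers(
    oriented: OrientedStructure, boundaries=(6.0, 15.0, 20.0, 30.0)
) -> pd.Series:
    """Layer per residue from |z|.

    boundaries = (inner/outer, outer/interface, interface/polar,
    polar/water); only the 6 A and 30 A ends are fixed by the slab
    definition, the intermediate two default to 15/20 A with the membrane
    edge at 20 A.
    """
    b = tuple(float(v) for v in boundaries)
    if len(b) != 4 or any(np.diff(b) <= 0):
        raise ValueError("boundaries must be 4 strictly increasing values")
    az = np.abs(oriented.z)
    layer = np.select(
        [az < b[0], az < b[1], az < b[2], az < b[3]],
        ["inner_hydrophobic", "outer_hydrophobic", "interface", "polar"],
        default="water",
    )
    return pd.Series(layer, index=oriented.residues.index, name="layer")


def _alpha_surface(points: np.ndarray, alpha: float):
    """Boundary triangles of the alpha complex of ``points``.

    Tetrahedra of the Delaunay triangulation with circumradius < alpha are
    kept; faces belonging to exactly one kept tetrahedron form the outer
    (and any cavity) surface.  Returns an (n_tri, 3) index array or None
    when the complex is degenerate/empty.
    """
    if len(points) < 4:
        return None
    try:
        tri = Delaunay(points)
    except QhullError:
        return None
    tets = tri.simplices
    a, b, c, d = (points[tets[:, i]] for i in range(4))
    # circumradius via the standard determinant-free formulation
    ba, ca, da = b - a, c - a, d - a
    det = np.einsum("ij,ij->i", ba, np.cross(ca, da))
    with np.errstate(divide="ignore", invalid="ignore"):
        num = (
            np.einsum("ij,ij->i", ba, ba)[:, None] * np.cross(ca, da)
            + np.einsum("ij,ij->i", ca, ca)[:, None] * np.cross(da, ba)
            + np.einsum("ij,ij->i", da, da)[:, None] * np.cross(ba, ca)
        )
        circ = num / (2.0 * det[:, None])
        radius = np.linalg.norm(circ, axis=1)
    keep = np.isfinite(radius) & (radius < alpha)
    if not keep.any():
        return None
    faces = {}
    for tet in tets[keep]:
        for f in ((0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)):
            key = tuple(sorted(tet[list(f)]))
            faces[key] = faces.get(key, 0) + 1
    boundary = np.array([k for k, n in faces.items() if n == 1], int)
    return boundary if len(boundary) else None


def _surface_distance(triangles: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Min distance from each point to a triangle soup (exact, vectorized)."""
    n_t = triangles.shape[0]
    n_p = points.shape[0]
    tri_rep = np.repeat(triangles, n_p, axis=0)
    pts_rep = np.tile(points, (n_t, 1))
    closest = trimesh.triangles.closest_point(tri_rep, pts_rep)
    d = np.linalg.norm(closest - pts_rep, axis=1).reshape(n_t, n_p)
    return d.min(axis=0)


def lipid_shell(
    oriented: OrientedStructure,
    layers: pd.Series,
    alpha_scale: float = 2.5,
    contact_cutoff: float = 4.0,
    membrane_edge: float = 20.0,
    extend_factor: float = 20.0,
) -> pd.Series:
    """Shell per residue: interior / membrane_contacting / external.

    The outer surface that the surrounding lipids can reach is the alpha
    shape of the residue centroids, with alpha = ``alpha_scale`` times the
    median nearest-neighbor centroid distance (scaling the tightness with
    protein size).  Surface vertices outside the membrane slab are pushed
    radially far from the protein so only the intramembrane surface is
    reachable.  Membrane-layer residues closer than ``contact_cutoff`` to
    the surface contact the lipid; the rest are interior.  Polar and water
    residues are external.
    """
    pts = oriented.centroids
    membrane = layers.isin(MEMBRANE_LAYERS).to_numpy()
    shell = np.where(membrane, "interior", "external").astype(object)
    n_mem = int(membrane.sum())
    if n_mem == 0:
        return pd.Series(shell, index=layers.index, name="shell")
    if n_mem < 4:
        warnings.warn("fewer than 4 membrane residues; all marked "
                      "membrane_contacting", stacklevel=2)
        shell[membrane] = "membrane_contacting"
        return pd.Series(shell, index=layers.index, name="shell")

    nn_d, _ = cKDTree(pts).query(pts, k=2)
    alpha = alpha_scale * float(np.median(nn_d[:, 1]))
    faces = _alpha_surface(pts, alpha)
    if faces is None:
        warnings.warn("degenerate alpha complex; all membrane residues marked "
                      "membrane_contacting", stacklevel=2)
        shell[membrane] = "membrane_contacting"
        return pd.Series(shell, index=layers.index, name="shell")

    verts = pts.copy()
    outside = np.abs(verts[:, 2]) > membrane_edge
    if outside.any():
        # push the extramembranous surface far away radially in xy
        xy = verts[outside, :2]
        r = np.linalg.norm(xy, axis=1, keepdims=True)
        direction = np.where(r > 1e-9, xy / np.maximum(r, 1e-9), [[1.0, 0.0]])
        verts[outside, :2] = xy + direction * extend_factor * max(alpha, 1.0)
        verts[outside, 2] *= extend_factor

    mem_pts = pts[membrane]
    dist = _surface_distance(verts[faces], mem_pts)
    contact = dist < contact_cutoff
    mem_shell = np.where(contact, "membrane_contacting", "interior")
    shell[membrane] = mem_shell
    return pd.Series(shell, index=layers.index, name="shell")


class ProbabilityReference:
    """Amino-acid location enrichment over a reference residue set.

    For a residue of type ``aa`` in location bin (layer, shell, depth bin),
    the metric is freq(aa | bin) / freq(aa overall) with add-one smoothing,
    counted across every residue table registered in the reference.
    """

    def __init__(self):
        self._rows = []
        self._bin_counts = None

    @staticmethod
    def depth_bin(depth: int) -> int:
        return int(np.searchsorted(DEPTH_BIN_EDGES, depth, side="right"))

    def add(self, table: pd.DataFrame):
        """Register residues (columns aa, layer, shell, depth)."""
        self._rows.append(table[["aa", "layer", "shell", "depth"]].copy())
        self._bin_counts = None
        return self

    def _counts(self):
        if self._bin_counts is None:
            if not self._rows:
                raise ValueError("empty probability reference")
            all_rows = pd.concat(self._rows, ignore_index=True)
            all_rows["dbin"] = [self.depth_bin(d) for d in all_rows["depth"]]
            self._bin_counts = {
                "joint": all_rows.groupby(["layer", "shell", "dbin", "aa"]).size(),
                "bin": all_rows.groupby(["layer", "shell", "dbin"]).size(),
                "aa": all_rows.groupby("aa").size(),
                "total": len(all_rows),
                "n_aa": max(all_rows["aa"].nunique(), 1),
            }
        return self._bin_counts

    def enrichment(self, aa, layer, shell, depth) -> float:
        c = self._counts()
        dbin = self.depth_bin(depth)
        joint = c["joint"].get((layer, shell, dbin, aa), 0)
        bin_total = c["bin"].get((layer, shell, dbin), 0)
        aa_total = c["aa"].get(aa, 0)
        p_cond = (joint + 1) / (bin_total + c["n_aa"])
        p_marg = (aa_total + 1) / (c["total"] + c["n_aa"])
        return float(p_cond / p_marg)


def residue_metrics(
    oriented: OrientedStructure,
    layers: pd.Series,
    shells: pd.Series,
    reference: ProbabilityReference | None = None,
    neighbor_radius: float = 6.0,
) -> pd.DataFrame:
    """Per-residue charge, hydrophobicity, depth, and probability.

    Depth counts other residue centroids within ``neighbor_radius``.  With
    no reference supplied the working structure itself is the reference
    for the probability metric.
    """
    res = oriented.residues
    aa = res["aa"].to_numpy()
    unknown = sorted(set(aa) - set(WIMLEY_WHITE_INTERFACE))
    if unknown:
        warnings.warn(f"unknown residue codes {unknown}; metrics set to neutral",
                      stacklevel=2)
    scale_mean = float(np.mean(list(WIMLEY_WHITE_INTERFACE.values())))
    charge = np.array([CHARGE.get(a, 0) if a in WIMLEY_WHITE_INTERFACE else 0
                       for a in aa], float)
    hydro = np.array(
        [WIMLEY_WHITE_INTERFACE.get(a, scale_mean) for a in aa], float
    )
    pts = oriented.centroids
    tree = cKDTree(pts)
    depth = np.array(
        [len(tree.query_ball_point(p, neighbor_radius)) - 1 for p in pts], int
    )
    table = pd.DataFrame(
        {"aa": aa, "layer": layers.to_numpy(), "shell": shells.to_numpy(),
         "depth": depth},
        index=res.index,
    )
    if reference is None:
        reference = ProbabilityReference().add(table)
    prob = np.array(
        [
            reference.enrichment(r.aa, r.layer, r.shell, r.depth)
            for r in table.itertuples()
        ]
    )
    out = table.copy()
    out["charge"] = charge
    out["hydrophobicity"] = hydro
    out["probability"] = prob
    return out


def featurize_structure(
    structure: AnnotatedStructure,
    reference: ProbabilityReference | None = None,
    boundaries=(6.0, 15.0, 20.0, 30.0),
    alpha_scale: float = 2.5,
    contact_cutoff: float = 4.0,
    expanded: bool = False,
    require_qc: bool = True,
):
    """Full per-structure pipeline -> (feature Series, QCResult, mask).

    ``mask`` flags bins that held no residues (their features are 0).
    Raises when QC fails and ``require_qc`` is set.
    """
    oriented = orient(structure)
    qc_res = qc(oriented, membrane_edge=boundaries[2])
    if require_qc and not qc_res.passed:
        raise ValueError(
            f"structure failed orientation QC: {qc_res}"
        )
    layers = assign_layers(oriented, boundaries)
    shells = lipid_shell(
        oriented, layers, alpha_scale=alpha_scale,
        contact_cutoff=contact_cutoff, membrane_edge=boundaries[2],
    )
    metrics = residue_metrics(oriented, layers, shells, reference=reference)
    stats = ("mean",) if not expanded else ("mean", "min", "max", "sum")
    values, mask = {}, {}
    for layer, shell in LOCATION_BINS:
        sel = metrics[(metrics["layer"] == layer) & (metrics["shell"] == shell)]
        empty = sel.empty
        mask[f"{layer}_{shell}"] = empty
        for metric in METRICS:
            col = sel[metric] if not empty else None
            for stat in stats:
                name = f"{layer}_{shell}__{metric}"
                if expanded:
                    name += f"__{stat}"
                if empty:
                    values[name] = 0.0
                else:
                    values[name] = float(getattr(col, stat)())
    return pd.Series(values, name="features"), qc_res, pd.Series(mask)


def featurize(
    structures: dict,
    reference: ProbabilityReference | None = None,
    expanded: bool = False,
    **kwargs,
) -> pd.DataFrame:
    """Featurize a mapping of id -> AnnotatedStructure.

    QC-failing structures are excluded (reason recorded in the returned
    frame's ``attrs['excluded']``).  When no external reference is given,
    the probability metric's reference set is built from the passing
    structures themselves.
    """
    oriented_cache, excluded = {}, {}
    if reference is None:
        reference = ProbabilityReference()
        for sid, st in structures.items():
            try:
                o = orient(st)
                q = qc(o, membrane_edge=kwargs.get("boundaries",
                                                   (6.0, 15.0, 20.0, 30.0))[2])
                if not q.passed:
                    excluded[sid] = f"qc failed: {q}"
                    continue
                layers = assign_layers(o, kwargs.get("boundaries",
                                                     (6.0, 15.0, 20.0, 30.0)))
                shells = lipid_shell(o, layers,
                                     alpha_scale=kwargs.get("alpha_scale", 2.5))
                m = residue_metrics(o, layers, shells)
                reference.add(m[["aa", "layer", "shell", "depth"]])
                oriented_cache[sid] = st
            except ValueError as err:
                excluded[sid] = str(err)
    else:
        oriented_cache = dict(structures)
    rows = {}
    for sid, st in oriented_cache.items():
        try:
            feats, _, _ = featurize_structure(
                st, reference=reference, expanded=expanded, **kwargs
            )
            rows[sid] = feats
        except ValueError as err:
            excluded[sid] = str(err)
    out = pd.DataFrame(rows).T
    out.attrs["excluded"] = excluded
    return out
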