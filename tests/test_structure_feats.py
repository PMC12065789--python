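"""Membrane orientation, QC, layers, lipid shell, metrics, features."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import ConvexHull

from memscreen import structure_feats as sf
from memscreen.synthetic_data import BundleConfig, gen_helix_bundle


def _rigid_transform(structure, seed=0):
    """Apply a random rotation + translation to all coordinates."""
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    t = rng.uniform(-30, 30, 3)

    def go(df):
        out = df.copy()
        out[["x", "y", "z"]] = df[["x", "y", "z"]].to_numpy() @ Q.T + t
        return out

    return sf.AnnotatedStructure(
        go(structure.residues), go(structure.atoms), structure.helices
    )


class TestReadAndOrient:
    def test_orientation_of_ideal_bundle_is_near_identity(self, structure4):
        o = sf.orient(structure4)
        # generated bundle is already in the membrane frame
        assert np.allclose(o.rotation, np.eye(3), atol=1e-6)
        assert np.allclose(o.translation, 0.0, atol=0.2)

    def test_orientation_recovers_frame_after_rigid_transform(self, structure4):
        o_ref = sf.orient(structure4)
        moved = _rigid_transform(structure4, seed=3)
        o_moved = sf.orient(moved)
        assert np.allclose(o_ref.z, o_moved.z, atol=1e-6)

    def test_orientation_idempotent(self, structure4):
        o1 = sf.orient(structure4)
        o2 = sf.orient(o1.structure)
        assert np.allclose(o1.centroids, o2.centroids, atol=1e-9)

    def test_single_helix_rejected(self):
        b = gen_helix_bundle(BundleConfig(n_helices=1, helix_length=20,
                                          seed=0))
        st = sf.annotated_from_bundle(b)
        with pytest.raises(ValueError, match="2 TM helices"):
            sf.orient(st)

    def test_annotation_index_missing_errors(self, structure4):
        bad = pd.DataFrame({"helix_index": [0], "start": [1], "end": [999]})
        with pytest.raises(ValueError, match="999"):
            sf.AnnotatedStructure(structure4.residues, structure4.atoms, bad)

    def test_overlapping_helix_ranges_rejected(self, structure4):
        bad = pd.DataFrame({"helix_index": [0, 1], "start": [1, 10],
                            "end": [20, 25]})
        with pytest.raises(ValueError, match="overlap"):
            sf.AnnotatedStructure(structure4.residues, structure4.atoms, bad)


class TestQC:
    def test_ideal_bundle_passes_with_full_accuracy(self):
        # 20-residue helices span 28.5 A, entirely inside the 20 A slab
        b = gen_helix_bundle(BundleConfig(n_helices=4, helix_length=20,
                                          ring_radius=8.0, seed=0))
        res = sf.qc(sf.orient(sf.annotated_from_bundle(b)))
        assert res.passed and res.tm_within_membrane == 1.0

    def test_juxtamembrane_helix_ends_tolerated(self, structure4):
        # 30-residue helices poke past the 20 A edge yet still pass QC
        res = sf.qc(sf.orient(structure4))
        assert res.passed and 0.75 <= res.tm_within_membrane < 1.0

    def test_short_helix_annotation_fails_span_rule(self):
        # 5 residues at 1.5 A rise span 6 A < 10 A: impossible TM label
        b = gen_helix_bundle(BundleConfig(n_helices=2, helix_length=30,
                                          ring_radius=8.0, seed=0))
        st = sf.annotated_from_bundle(b)
        ann = pd.DataFrame({
            "helix_index": [0, 1],
            "start": [13, 31], "end": [17, 60],
        })
        short = sf.AnnotatedStructure(st.residues, st.atoms, ann)
        res = sf.qc(sf.orient(short))
        assert res.min_helix_span < 10.0
        assert not res.passed

    def test_displaced_helix_lowers_accuracy(self, structure4):
        # push one helix far along z: its residues leave the membrane slab
        res_df = structure4.residues.copy()
        atoms = structure4.atoms.copy()
        mask = res_df["resseq"] <= 30
        res_df.loc[mask, "z"] += 45.0
        atoms.loc[atoms["resseq"] <= 30, "z"] += 45.0
        shifted = sf.AnnotatedStructure(res_df, atoms, structure4.helices)
        res = sf.qc(sf.OrientedStructure(shifted, np.eye(3), np.zeros(3)))
        assert res.tm_within_membrane < 1.0


class TestLayers:
    @pytest.mark.parametrize("z,expected", [
        (0.0, "inner_hydrophobic"),
        (35.0, "water"),
        (-17.0, "interface"),
        (7.0, "outer_hydrophobic"),
        (-25.0, "polar"),
    ])
    def test_bin_lookup(self, z, expected, structure4):
        o = sf.orient(structure4)
        res = o.residues.copy()
        res.loc[res.index[0], "z"] = z
        st = sf.AnnotatedStructure(res, o.structure.atoms, o.helices)
        layers = sf.assign_layers(sf.OrientedStructure(st, np.eye(3),
                                                       np.zeros(3)))
        assert layers.iloc[0] == expected

    def test_layers_partition_residues(self, structure4):
        layers = sf.assign_layers(sf.orient(structure4))
        assert layers.isin(sf.LAYERS).all()

    def test_bad_boundaries_rejected(self, structure4):
        with pytest.raises(ValueError):
            sf.assign_layers(sf.orient(structure4), boundaries=(6, 5, 20, 30))


def _hull_shell_oracle(oriented, layers, cutoff=4.0, slab=6.0):
    """Brute-force shell reference for ring bundles: per 6 A z-slab (one
    helical turn per helix, full azimuthal rim coverage), a membrane
    residue contacts the lipid iff it is within ``cutoff`` of the slab's
    2D convex-hull boundary in the xy plane."""
    pts = oriented.centroids
    mem = layers.isin(sf.MEMBRANE_LAYERS).to_numpy()
    zb = np.floor(pts[:, 2] / slab).astype(int)
    oracle = np.full(len(pts), "external", object)
    for s in np.unique(zb[mem]):
        sel = np.flatnonzero(mem & (zb == s))
        xy = pts[sel, :2]
        if len(sel) < 4:
            oracle[sel] = "membrane_contacting"
            continue
        hull = ConvexHull(xy)
        verts = xy[hull.vertices]
        segs = list(zip(verts, np.roll(verts, -1, axis=0)))
        for i, p in zip(sel, xy):
            d = min(
                np.linalg.norm(
                    p - (a + np.clip(np.dot(p - a, b - a)
                                     / np.dot(b - a, b - a), 0, 1) * (b - a))
                )
                for a, b in segs
            )
            oracle[i] = "membrane_contacting" if d < cutoff else "interior"
    return oracle, mem


class TestLipidShell:
    def test_two_helix_bundle_all_contacting(self):
        # with no possible interior, every membrane residue touches lipid
        b = gen_helix_bundle(BundleConfig(n_helices=2, helix_length=30,
                                          ring_radius=8.0, seed=1))
        o = sf.orient(sf.annotated_from_bundle(b))
        layers = sf.assign_layers(o)
        shells = sf.lipid_shell(o, layers)
        mem = layers.isin(sf.MEMBRANE_LAYERS)
        assert (shells[mem] == "membrane_contacting").all()

    def test_center_helix_buried_ring_facing_exposed(self):
        b = gen_helix_bundle(BundleConfig(n_helices=7, helix_length=34,
                                          ring_radius=10.0, seed=2,
                                          center_helix=True))
        o = sf.orient(sf.annotated_from_bundle(b))
        layers = sf.assign_layers(o)
        shells = sf.lipid_shell(o, layers)
        res = b.residues
        mem = layers.isin(sf.MEMBRANE_LAYERS).to_numpy()
        center = (res["helix"] == 0).to_numpy()
        facing = res["lipid_facing"].to_numpy()
        assert (shells[center & mem] == "interior").mean() > 0.6
        assert (shells[~center & mem & facing]
                == "membrane_contacting").mean() > 0.95

    def test_agrees_with_hull_oracle(self):
        for seed in range(3):
            b = gen_helix_bundle(BundleConfig(n_helices=7, helix_length=34,
                                              ring_radius=10.0, seed=seed,
                                              center_helix=True))
            o = sf.orient(sf.annotated_from_bundle(b))
            layers = sf.assign_layers(o)
            shells = sf.lipid_shell(o, layers)
            oracle, mem = _hull_shell_oracle(o, layers)
            agree = (shells.to_numpy()[mem] == oracle[mem]).mean()
            assert agree >= 0.95

    def test_invariant_under_rotation_about_z(self, structure4):
        o = sf.orient(structure4)
        layers = sf.assign_layers(o)
        base = sf.lipid_shell(o, layers)
        th = 1.1
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])

        def rot(df):
            out = df.copy()
            out[["x", "y", "z"]] = df[["x", "y", "z"]].to_numpy() @ R.T
            return out

        st = sf.AnnotatedStructure(rot(o.residues), rot(o.structure.atoms),
                                   o.helices)
        o2 = sf.OrientedStructure(st, np.eye(3), np.zeros(3))
        rotated = sf.lipid_shell(o2, sf.assign_layers(o2))
        assert (base == rotated).all()


class TestResidueMetrics:
    @pytest.mark.parametrize("aa,charge", [
        ("LYS", 1), ("ARG", 1), ("HIS", 1), ("ASP", -1), ("GLU", -1),
        ("GLY", 0), ("LEU", 0),
    ])
    def test_charge_rule(self, aa, charge, structure4):
        o = sf.orient(structure4)
        res = o.residues.copy()
        res.loc[res.index[0], "aa"] = aa
        st = sf.AnnotatedStructure(res, o.structure.atoms, o.helices)
        o2 = sf.OrientedStructure(st, np.eye(3), np.zeros(3))
        layers = sf.assign_layers(o2)
        shells = sf.lipid_shell(o2, layers)
        m = sf.residue_metrics(o2, layers, shells)
        assert m["charge"].iloc[0] == charge

    def test_depth_counts_neighbors_symmetrically(self, structure4):
        o = sf.orient(structure4)
        layers = sf.assign_layers(o)
        shells = sf.lipid_shell(o, layers)
        m = sf.residue_metrics(o, layers, shells)
        pts = o.centroids
        # brute-force pairwise check: i counts j iff j counts i
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        counts = ((d < 6.0).sum(axis=1) - 1)
        assert np.array_equal(m["depth"].to_numpy(), counts)

    def test_isolated_residue_depth_zero(self, structure4):
        o = sf.orient(structure4)
        res = o.residues.copy()
        res.loc[res.index[0], ["x", "y"]] = [500.0, 500.0]
        st = sf.AnnotatedStructure(res, o.structure.atoms, o.helices)
        o2 = sf.OrientedStructure(st, np.eye(3), np.zeros(3))
        layers = sf.assign_layers(o2)
        shells = sf.lipid_shell(o2, layers)
        m = sf.residue_metrics(o2, layers, shells)
        assert m["depth"].iloc[0] == 0

    def test_uniform_reference_gives_unit_probability(self):
        # every amino acid equally distributed over the bins -> ratio 1
        ref = sf.ProbabilityReference()
        rows = []
        for aa in ("LEU", "SER"):
            for layer in ("inner_hydrophobic", "polar"):
                shell = ("membrane_contacting"
                         if layer == "inner_hydrophobic" else "external")
                rows += [{"aa": aa, "layer": layer, "shell": shell,
                          "depth": 1}] * 10
        ref.add(pd.DataFrame(rows))
        assert ref.enrichment("LEU", "inner_hydrophobic",
                              "membrane_contacting", 1) == pytest.approx(1.0)

    def test_unknown_residue_neutral_with_warning(self, structure4):
        o = sf.orient(structure4)
        res = o.residues.copy()
        res.loc[res.index[0], "aa"] = "XYZ"
        st = sf.AnnotatedStructure(res, o.structure.atoms, o.helices)
        o2 = sf.OrientedStructure(st, np.eye(3), np.zeros(3))
        layers = sf.assign_layers(o2)
        shells = sf.lipid_shell(o2, layers)
        with pytest.warns(UserWarning, match="XYZ"):
            m = sf.residue_metrics(o2, layers, shells)
        assert m["charge"].iloc[0] == 0


class TestFeaturize:
    def test_default_mode_emits_exactly_32(self, structure4):
        feats, qc_res, mask = sf.featurize_structure(structure4)
        assert len(feats) == 32
        assert qc_res.passed
        assert list(feats.index) == sf.feature_names()

    def test_expanded_mode_emits_128(self, structure4):
        feats, _, _ = sf.featurize_structure(structure4, expanded=True)
        assert len(feats) == 32 * 4

    def test_empty_bins_zero_with_mask(self):
        # a short bundle never reaches the water layer
        b = gen_helix_bundle(BundleConfig(n_helices=4, helix_length=20,
                                          ring_radius=8.0, seed=4))
        feats, _, mask = sf.featurize_structure(
            sf.annotated_from_bundle(b))
        assert mask["water_external"]
        water = [n for n in feats.index if n.startswith("water_external")]
        assert np.allclose(feats[water], 0.0)

    def test_rigid_body_invariance(self, structure4):
        base, _, _ = sf.featurize_structure(structure4)
        for seed in (1, 2):
            moved = _rigid_transform(structure4, seed=seed)
            got, _, _ = sf.featurize_structure(moved)
            assert np.allclose(base.to_numpy(), got.to_numpy(), atol=1e-6)

    def test_batch_featurize_excludes_qc_failures(self, structure4):
        b = gen_helix_bundle(BundleConfig(n_helices=2, helix_length=30,
                                          ring_radius=8.0, seed=5))
        st = sf.annotated_from_bundle(b)
        bad_ann = pd.DataFrame({"helix_index": [0, 1], "start": [13, 31],
                                "end": [17, 60]})
        bad = sf.AnnotatedStructure(st.residues, st.atoms, bad_ann)
        out = sf.featurize({"good": structure4, "bad": bad})
        assert list(out.index) == ["good"]
        assert "bad" in out.attrs["excluded"]
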