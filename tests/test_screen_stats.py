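"""Outlier removal, success calling, BH correction, and screen summaries."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from memscreen import design, synthetic_data
from memscreen.screen_stats import (
    bh_correct,
    call_screen,
    call_success,
    extract_cv_qc,
    interaction_model,
    preferred_composition,
    remove_outliers,
    trajectory_norm,
)


class TestRemoveOutliers:
    def test_tight_cluster_untouched(self):
        kept, n = remove_outliers([1.0, 1.1, 0.9, 1.0])
        assert n == 0 and len(kept) == 4

    def test_single_gross_outlier_removed(self):
        # median 1, sample SD 4.5: |10 - 1| = 9 >= 2 SD
        kept, n = remove_outliers([1.0, 1.0, 1.0, 10.0])
        assert n == 1
        assert 10.0 not in kept

    def test_never_below_three_replicates(self):
        kept, n = remove_outliers([0.0, 100.0, -100.0, 50.0])
        assert len(kept) >= 3

    def test_small_sets_returned_unchanged(self):
        with pytest.warns(UserWarning):
            kept, n = remove_outliers([1.0, 2.0, 3.0])
        assert n == 0 and len(kept) == 3

    def test_contamination_rate_recovered(self, grid):
        """On a screen with 7.5% injected outliers the removal step flags
        approximately that fraction (binomial tolerance)."""
        cfg = synthetic_data.LandscapeConfig(
            n_proteins=2, grid=grid, noise_sd=0.5, outlier_rate=0.075,
            replicates=4, seed=21,
        )
        rec, _ = synthetic_data.gen_yield_landscape(cfg)
        removed = total = 0
        for _, grp in rec.groupby(["protein", "condition", "liposome"]):
            _, n = remove_outliers(grp["yield_pmol"].to_numpy())
            removed += n
            total += len(grp)
        rate = removed / total
        p = 0.075
        se = np.sqrt(p * (1 - p) / total)
        assert abs(rate - p) < 4 * se + 0.01


class TestCallSuccess:
    def test_identical_arms_fail(self):
        call = call_success([1.0, 1.0, 1.0, 1.0], [1.0, 1.0, 1.0, 1.0])
        assert not call.passed and call.p == 1.0

    def test_clear_separation_passes_welch(self):
        a = [5.0, 5.1, 4.9, 5.0]
        b = [1.0, 1.1, 0.9, 1.0]
        call = call_success(a, b)
        # direct Welch computation is the oracle
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert call.p == pytest.approx(ref.pvalue)
        assert call.delta == pytest.approx(4.0)
        assert call.passed

    def test_sign_symmetry(self):
        a = [5.0, 5.2, 4.8, 5.1]
        b = [1.0, 1.3, 0.8, 1.2]
        fwd = call_success(a, b)
        rev = call_success(b, a)
        assert fwd.p == pytest.approx(rev.p)
        assert fwd.delta == pytest.approx(-rev.delta)

    def test_null_simulation_type_one_error(self):
        """Raw t-test false-positive rate over ~1000 null conditions stays
        at or below the nominal level (Monte-Carlo slack)."""
        rng = np.random.default_rng(9)
        n = 1000
        hits = 0
        for _ in range(n):
            a = rng.normal(2.0, 0.5, 4)
            b = rng.normal(2.0, 0.5, 4)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if call_success(a, b, remove=False).p < 0.05:
                    hits += 1
        assert hits / n <= 0.05 + 2.5 * np.sqrt(0.05 * 0.95 / n)

    def test_power_monotone_in_effect_size(self):
        """Detection power at delta = 3 noise SD exceeds power at 1 SD."""
        rng = np.random.default_rng(10)
        power = []
        for effect in (0.5, 1.5):  # 1x and 3x the 0.5 noise SD
            hits = 0
            for _ in range(400):
                a = rng.normal(2.0 + effect, 0.5, 4)
                b = rng.normal(2.0, 0.5, 4)
                hits += call_success(a, b, min_delta=0.0, remove=False).passed
            power.append(hits / 400)
        assert power[1] > power[0]


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_correct([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_step_up(self):
        adj = bh_correct([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert np.allclose(bh_correct([1.0, 1.0, 1.0]), 1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_never_decreases_and_preserves_order(self, pvals):
        p = np.asarray(pvals)
        adj = bh_correct(p)
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= 1.0 + 1e-12)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_correct([0.5, 1.5])


class TestPreferredComposition:
    def _calls(self, deltas, encodings):
        return pd.DataFrame({
            "delta": deltas,
            "p": np.linspace(0.01, 0.04, len(deltas)),
            "PEG": [e[0] for e in encodings],
            "lipid": [e[1] for e in encodings],
        })

    def test_unanimous_top_three(self):
        calls = self._calls([5, 4, 3, 0.1], [(1, 0), (1, 0.5), (1, 1), (0, 0)])
        pref = preferred_composition(calls, ["PEG", "lipid"])
        assert pref["PEG"] == pytest.approx(1.0)
        assert pref["lipid"] == pytest.approx(0.5)

    def test_planted_optimum_recovered(self, grid, small_landscape):
        """The top-3 composition sits within one grid step of the planted
        optimum on a low-noise landscape."""
        records, truth = small_landscape
        calls = call_screen(records, condition_cols=["condition"])
        factor_names = grid.names
        enc = truth.conditions
        for protein, grp in calls.groupby("protein"):
            merged = grp.join(enc, on="condition")
            pref = preferred_composition(merged, factor_names)
            opt = truth.optimum_encoding.loc[protein]
            # one grid step on a 3-level [0, 1] grid is 0.5
            assert np.all(np.abs(pref - opt) <= 0.5 + 1e-9)


class TestInteractionModel:
    def _simulate(self, seed, with_interaction):
        rng = np.random.default_rng(seed)
        X = rng.uniform(size=(400, 5))
        y = 1.2 * X[:, 0] - 0.7 * X[:, 1] + 0.4 * X[:, 2]
        if with_interaction:
            y = y + 1.5 * X[:, 0] * X[:, 1]
        y = y + rng.normal(0, 0.1, 400)
        return X, (y - y.mean()) / y.std()

    def test_coefficients_match_normal_equations(self):
        X, y = self._simulate(0, True)
        table = interaction_model(X, y, factor_names=list("ABCDE"))
        # brute-force normal-equations solve
        cols = [X[:, j] for j in range(5)]
        cols += [X[:, i] * X[:, j] for i in range(5) for j in range(i + 1, 5)]
        D = np.column_stack([np.ones(len(X)), *cols])
        beta = np.linalg.solve(D.T @ D, D.T @ y)
        assert np.allclose(table["coef"].to_numpy(), beta, atol=1e-8)

    def test_planted_pair_detected(self):
        X, y = self._simulate(1, True)
        table = interaction_model(X, y, factor_names=list("ABCDE"))
        assert table.loc["AxB", "p"] < 0.05
        other = [t for t in table.index
                 if "x" in t and t != "AxB"]
        assert (table.loc[other, "p"] > 0.05).mean() > 0.8

    def test_pure_main_effects_have_null_interactions(self):
        """With only main effects planted, interaction estimates are small
        against the main effects and mostly insignificant (a ~5% false
        positive rate is the nominal behaviour of the per-term t-test)."""
        X, y = self._simulate(2, False)
        table = interaction_model(X, y, factor_names=list("ABCDE"))
        inter = [t for t in table.index if "x" in t]
        main = table.loc[["A", "B", "C"], "coef"].abs().min()
        assert np.all(np.abs(table.loc[inter, "coef"]) < main)
        assert (table.loc[inter, "p"] > 0.05).mean() >= 0.8

    def test_collinear_terms_named(self):
        X = np.random.default_rng(3).uniform(size=(50, 5))
        X[:, 4] = X[:, 3]
        with pytest.raises(ValueError, match="collinear"):
            interaction_model(X, X[:, 0], factor_names=list("ABCDE"))


class TestTrajectoryNorm:
    def test_identical_conditions_zero(self):
        assert np.allclose(trajectory_norm([0.5] * 5, [0.5] * 5, 1.0, 1.0), 0)

    def test_three_four_five(self):
        out = trajectory_norm([0.0], [4.0], 0.0, 3.0)
        assert out[0] == pytest.approx(5.0)

    def test_zero_concentration_change(self):
        out = trajectory_norm([0.2, 0.2], [0.2, 0.9], 0.0, 2.0)
        assert out[0] == pytest.approx(2.0)


class TestExtractCV:
    def test_identical_replicates_pass(self):
        cv, ok = extract_cv_qc({"a": [1.0, 1.0, 1.0]})
        assert ok and cv["a"] == 0.0

    def test_high_variance_fails(self):
        reps = {c: [1.0, 1.0 + 0.4, 1.0 - 0.35] for c in range(4)}
        cv, ok = extract_cv_qc(reps)
        assert cv.mean() > 0.10 and not ok

    def test_boundary_is_pass(self):
        cv, ok = extract_cv_qc({"a": [1.0, 1.0, 1.0]}, threshold=0.0)
        assert ok  # strict inequality: fail only above the threshold
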