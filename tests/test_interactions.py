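"""Median polish, moderated t, BH and significance calls, with oracles."""
import subprocess
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays
from scipy import optimize, special, stats

from phenoscreen import interactions as ia
from phenoscreen import synthgen as sg
from _oracles import medpolish_oracle, moderated_t_oracle


# ---------------------------------------------------------------------------
# cell-number normalization
# ---------------------------------------------------------------------------


class TestNormalizeCellNumber:
    def test_anchors_map_to_zero_and_one(self):
        assert ia.normalize_cell_number(3.0, negctrl_median=10.0, kill_ref=3.0) == 0.0
        assert ia.normalize_cell_number(10.0, negctrl_median=10.0, kill_ref=3.0) == 1.0

    def test_midpoint_maps_to_half(self):
        assert ia.normalize_cell_number(6.5, 10.0, 3.0) == pytest.approx(0.5)

    def test_values_outside_unit_interval_are_allowed(self):
        assert ia.normalize_cell_number(12.0, 10.0, 3.0) > 1.0
        assert ia.normalize_cell_number(1.0, 10.0, 3.0) < 0.0

    def test_degenerate_anchors_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            ia.normalize_cell_number(1.0, 5.0, 5.0)

    def test_table_normalization_uses_per_line_anchors(self, clean_screen):
        _, truth, tables = clean_screen
        normed = ia.normalize_cell_number_table(tables[0])
        kills = normed[normed["role"] == sg.ROLE_KILL]["cell_number"]
        vehicles = normed[normed["role"] == sg.ROLE_VEHICLE]["cell_number"]
        np.testing.assert_allclose(kills, 0.0, atol=1e-12)
        np.testing.assert_allclose(vehicles, 1.0, atol=1e-12)


# ---------------------------------------------------------------------------
# median polish
# ---------------------------------------------------------------------------


class TestMedianPolish:
    def test_additive_matrix_leaves_zero_residuals(self, rng):
        r = rng.normal(size=6)
        c = rng.normal(size=5)
        M = r[:, None] + c[None, :]
        res = ia.median_polish(M)
        np.testing.assert_allclose(res.residuals, 0.0, atol=1e-12)

    def test_single_outlier_in_even_zero_matrix_stays_in_residual(self):
        M = np.zeros((4, 4))
        M[1, 2] = 8.0
        res = ia.median_polish(M)
        assert res.residuals[1, 2] == pytest.approx(8.0)
        assert res.overall == 0.0
        np.testing.assert_allclose(res.row_effects, 0.0)
        np.testing.assert_allclose(res.col_effects, 0.0)

    @pytest.mark.parametrize("shape", [(5, 7), (12, 9), (50, 12)])
    def test_matches_independent_oracle(self, shape, rng):
        M = rng.normal(size=shape)
        res = ia.median_polish(M)
        _, _, _, z = medpolish_oracle(M)
        np.testing.assert_allclose(res.residuals, z, atol=1e-8)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(arrays(float, (6, 4), elements=st.floats(-100, 100, allow_nan=False)))
    def test_reconstruction_identity(self, M):
        res = ia.median_polish(M)
        np.testing.assert_allclose(res.reconstruct(), M, atol=1e-9)

    def test_residuals_invariant_to_global_and_row_shifts(self, rng):
        # constants over the whole matrix or a whole row are absorbed
        # exactly by the first row-median sweep
        M = rng.normal(size=(8, 6))
        shifted = M + 3.5
        shifted[2, :] += 1.25
        a = ia.median_polish(M).residuals
        b = ia.median_polish(shifted).residuals
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_residuals_nearly_invariant_to_column_shifts(self, rng):
        """A whole-column shift is absorbed by the column effect, but the
        alternating sweeps visit rows first, so the decomposition (which is
        unique only up to the iteration path) can differ by a small amount
        relative to the matrix spread."""
        M = rng.normal(size=(8, 6))
        shifted = M.copy()
        shifted[:, 4] -= 0.75
        a = ia.median_polish(M).residuals
        b = ia.median_polish(shifted).residuals
        np.testing.assert_allclose(a, b, atol=0.02)

    def test_missing_entries_are_ignored_and_stay_missing(self, rng):
        M = rng.normal(size=(6, 5))
        M[1, 3] = np.nan
        res = ia.median_polish(M)
        assert np.isnan(res.residuals[1, 3])
        assert np.isfinite(np.delete(res.residuals.ravel(), 8)).all()

    def test_all_missing_row_rejected(self):
        M = np.ones((3, 3))
        M[1] = np.nan
        with pytest.raises(ValueError, match="missing"):
            ia.median_polish(M)


# ---------------------------------------------------------------------------
# interaction estimation
# ---------------------------------------------------------------------------


class TestEstimateInteractions:
    def test_additive_screen_has_zero_interactions(self, clean_screen):
        _, _, tables = clean_screen
        res = ia.estimate_interactions(tables)
        np.testing.assert_allclose(np.nan_to_num(res.pi), 0.0, atol=1e-9)

    def test_single_planted_interaction_recovered(self):
        design = sg.gen_screen_design(20, 8, 2, seed=0)
        truth = sg.gen_ground_truth(20, 8, 3, gamma_density=0.0, sigma=0.0, seed=0)
        truth.gamma[4, 2, 1] = 2.0
        tables, _ = sg.gen_feature_tables(design, truth)
        res = ia.estimate_interactions(tables, normalize_cellnum=False)
        pooled = res.pooled_pi()
        d, l = res.compounds.index("C0005"), res.lines.index("L03")
        assert pooled[d, l, 1] == pytest.approx(2.0, abs=0.05)
        others = np.delete(
            pooled.ravel(), np.ravel_multi_index((d, l, 1), pooled.shape)
        )
        assert np.nanmax(np.abs(others)) < 0.05

    def test_growth_defect_yields_negative_cell_number_coefficient(self):
        # a compound that kills one genotype specifically must come out with
        # a negative normalized cell-number interaction coefficient
        design = sg.gen_screen_design(10, 4, 2, seed=2)
        truth = sg.gen_ground_truth(10, 4, 2, gamma_density=0.0, sigma=0.0, seed=2)
        truth.gamma[3, 1, 0] = -2.0  # genotype-specific growth defect
        tables, _ = sg.gen_feature_tables(design, truth)
        res = ia.estimate_interactions(tables, normalize_cellnum=True)
        d, l = res.compounds.index("C0004"), res.lines.index("L02")
        assert res.pooled_pi()[d, l, 0] < -0.1

    def test_permuting_compounds_permutes_interactions(self, small_screen):
        _, _, tables = small_screen
        res = ia.estimate_interactions(tables, normalize_cellnum=False)
        relabel = {c: f"Z{i:03d}" for i, c in enumerate(reversed(res.compounds))}
        shuffled = [t.assign(compound_id=t["compound_id"].map(lambda x: relabel.get(x, x)))
                    for t in tables]
        res2 = ia.estimate_interactions(shuffled, normalize_cellnum=False)
        for old, new in relabel.items():
            i, j = res.compounds.index(old), res2.compounds.index(new)
            np.testing.assert_allclose(res.pi[:, i], res2.pi[:, j], atol=1e-12)

    def test_replicate_noise_passes_through_at_the_planted_scale(self):
        # gamma == 0: polish residuals are mean-zero with sd close to sigma
        sigma = 0.25
        design = sg.gen_screen_design(40, 8, 2, seed=3)
        truth = sg.gen_ground_truth(40, 8, 4, gamma_density=0.0, sigma=sigma, seed=3)
        tables, _ = sg.gen_feature_tables(design, truth)
        res = ia.estimate_interactions(tables, normalize_cellnum=False)
        resid = res.pi[np.isfinite(res.pi)]
        assert abs(resid.mean()) < 0.01
        assert 0.75 * sigma < resid.std() < 1.05 * sigma


# ---------------------------------------------------------------------------
# moderated t
# ---------------------------------------------------------------------------


class TestModeratedT:
    def test_identical_variances_reduce_to_ordinary_t(self, rng):
        means = rng.normal(0, 1, size=60)
        X = np.stack([means - 0.5, means + 0.5], axis=1)  # every s^2 identical
        res = ia.moderated_one_sample_t(X)
        assert np.isinf(res.df_prior)
        assert res.s2_prior == pytest.approx(X.var(axis=1, ddof=1).mean())
        ordinary = X.mean(1) / (X.std(1, ddof=1) / np.sqrt(2))
        np.testing.assert_allclose(res.t, ordinary, atol=1e-10)

    def test_zero_variance_unit_still_gets_finite_t(self, rng):
        X = rng.normal(0, 1, size=(50, 3))
        X[7] = 2.0  # exact replicates
        res = ia.moderated_one_sample_t(X)
        assert np.isfinite(res.t[7]) and res.t[7] > 0

    def test_prior_estimators_recover_simulation_truth(self):
        # with a single residual df per unit the moment estimators carry
        # substantial sampling noise, so judge them by their median over
        # independent simulations at the stated size
        d0_true, s0_true, n, R = 4.0, 1.0, 2000, 2
        d0s, s0s = [], []
        for seed in range(7):
            rng = np.random.default_rng(seed)
            s2 = d0_true * s0_true / rng.chisquare(d0_true, n)
            X = rng.normal(0.0, np.sqrt(s2)[:, None], (n, R))
            res = ia.moderated_one_sample_t(X)
            d0s.append(res.df_prior)
            s0s.append(res.s2_prior)
        assert np.median(d0s) == pytest.approx(d0_true, rel=0.25)
        assert np.median(s0s) == pytest.approx(s0_true, rel=0.10)

    def test_matches_closed_form_oracle(self):
        rng = np.random.default_rng(7)
        s2 = 4.0 * 1.0 / rng.chisquare(4.0, 500)
        X = rng.normal(0.1, np.sqrt(s2)[:, None], (500, 2))
        res = ia.moderated_one_sample_t(X)
        t, p, d0, s0 = moderated_t_oracle(X)
        assert res.df_prior == pytest.approx(d0, abs=1e-6)
        assert res.s2_prior == pytest.approx(s0, abs=1e-6)
        np.testing.assert_allclose(res.t, t, atol=1e-6)
        np.testing.assert_allclose(res.p, p, atol=1e-6)

    def test_matches_limma_reference_implementation(self, tmp_path):
        rng = np.random.default_rng(42)
        s2 = 4.0 * 0.7 / rng.chisquare(4.0, 400)
        X = rng.normal(0.1, np.sqrt(s2)[:, None], (400, 3))
        mpath = tmp_path / "m.csv"
        np.savetxt(mpath, X, delimiter=",")
        out = tmp_path / "out.csv"
        script = (
            "suppressMessages(library(limma));"
            f"m <- as.matrix(read.csv('{mpath}', header=FALSE));"
            "fit <- eBayes(lmFit(m, design=matrix(1, ncol(m), 1)));"
            "write.csv(data.frame(t=fit$t, p=fit$p.value, d0=fit$df.prior,"
            f" s0=fit$s2.prior), '{out}', row.names=FALSE)"
        )
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        ref = pd.read_csv(out)
        res = ia.moderated_one_sample_t(X)
        assert res.df_prior == pytest.approx(ref["d0"][0], abs=1e-6)
        assert res.s2_prior == pytest.approx(ref["s0"][0], abs=1e-6)
        np.testing.assert_allclose(res.t, ref.iloc[:, 0], atol=1e-6)
        np.testing.assert_allclose(res.p, ref.iloc[:, 1], atol=1e-6)

    def test_null_p_values_are_uniform(self):
        rng = np.random.default_rng(11)
        s2 = 4.0 * 0.5 / rng.chisquare(4.0, 2000)
        X = rng.normal(0.0, np.sqrt(s2)[:, None], (2000, 2))
        res = ia.moderated_one_sample_t(X)
        assert stats.kstest(res.p, "uniform").statistic < 0.05

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            ia.moderated_one_sample_t(np.ones((5, 1)))

    def test_all_zero_variance_falls_back_with_warning(self):
        X = np.tile(np.arange(5.0)[:, None], (1, 2))
        with pytest.warns(UserWarning, match="zero"):
            res = ia.moderated_one_sample_t(X)
        assert np.isfinite(res.t[1:]).all()


class TestBHAdjust:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([0.001, 0.5], [0.002, 0.5]),
            ([0.2], [0.2]),
        ],
    )
    def test_closed_form_examples(self, p, expected):
        np.testing.assert_allclose(ia.bh_adjust(p), expected)

    def test_adjusted_never_below_raw(self, rng):
        p = rng.uniform(size=200)
        assert (ia.bh_adjust(p) >= p - 1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ia.bh_adjust([0.5, 1.5])

    def test_nan_preserved(self):
        out = ia.bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(out[1]) and np.isfinite(out[0])


class TestCalls:
    def test_unit_p_values_give_no_calls(self, clean_screen):
        _, _, tables = clean_screen
        res = ia.estimate_interactions(tables)
        calls = ia.test_interactions(res, fdr=0.01)
        # noise-free additive data: all pi zero, nothing callable
        assert calls["significant"].sum() == 0

    def test_summary_counts_are_consistent(self, small_screen):
        from phenoscreen.preprocess import default_category_map

        _, truth, tables = small_screen
        res = ia.estimate_interactions(tables, normalize_cellnum=False)
        calls = ia.test_interactions(res, fdr=0.05)
        summary = ia.call_interactions(
            calls, fdr=0.05, category_map=default_category_map(res.features)
        )
        assert summary.n_significant == int(calls["significant"].sum())
        assert summary.per_line.sum() == summary.n_significant
        assert summary.n_compounds_with_interactions <= len(res.compounds)
        if summary.per_category_exclusive is not None:
            assert summary.per_category_exclusive.sum() <= summary.n_significant
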