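"""The core model: per-locus OLS, latent-dimension selection, the
reference-free adjustment, bootstrap inference, and multiple testing —
each against an independent oracle."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from refewas.ewas import (
    ReferenceFreeEWAS,
    build_design,
    estimate_dimension,
    fit_reffree,
    fit_unadjusted,
    multiple_testing,
    run_ewas,
)
from refewas.simulate import SimConfig, null_config, simulate_beta_matrix

from conftest import NO_BATCH, NO_MISSING


def _design(n, seed=0):
    rng = np.random.default_rng(seed)
    return np.hstack([np.ones((n, 1)), rng.normal(size=(n, 3))])


class TestFitUnadjusted:
    def test_intercept_only_gives_locus_means(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=(20, 15))
        b, e = fit_unadjusted(y, np.ones((15, 1)))
        assert np.allclose(b[:, 0], y.mean(axis=1), atol=1e-12)

    def test_noiseless_data_interpolated_exactly(self):
        rng = np.random.default_rng(1)
        x = _design(12, 1)
        b0 = rng.normal(size=(30, 4))
        y = b0 @ x.T
        b, e = fit_unadjusted(y, x)
        assert np.max(np.abs(b - b0)) < 1e-10
        assert np.max(np.abs(e)) < 1e-10

    def test_matches_normal_equations_oracle(self):
        """Small case against an explicit per-locus normal-equations
        solve."""
        rng = np.random.default_rng(2)
        x = _design(8, 2)
        y = rng.normal(size=(5, 8))
        b, e = fit_unadjusted(y, x)
        for j in range(5):
            expected = np.linalg.inv(x.T @ x) @ x.T @ y[j]
            assert np.max(np.abs(b[j] - expected)) < 1e-10

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(3)
        x = _design(25, 3)
        y = rng.normal(size=(40, 25))
        _, e = fit_unadjusted(y, x)
        assert np.max(np.abs(e @ x)) < 1e-9

    def test_rank_deficient_design_names_columns(self):
        samples = pd.DataFrame(
            {
                "placenta_as": [1.0, 2, 3, 4, 5, 6],
                "maternal_age": [30.0] * 6,  # constant: aliased with intercept
                "gestational_age": [39, 40, 38, 39, 41, 40.0],
                "infant_sex": [0, 1, 0, 1, 0, 1],
            },
            index=[f"s{i}" for i in range(6)],
        )
        with pytest.raises(ValueError, match="aliased.*(intercept|maternal_age)"):
            build_design(samples, "placenta_as")


class TestEstimateDimension:
    def test_pure_noise_gives_zero(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            y = rng.normal(size=(5000, 200))
            x = _design(200, seed + 50)
            _, e = fit_unadjusted(y, x)
            assert estimate_dimension(e, x.shape[1]) == 0

    def test_mixture_structure_detected(self):
        """K = 4 cell types with strong marker contrast leave a rank
        K-1 (or K) residual signature after the intercept."""
        for seed in range(3):
            cfg = null_config(
                n_samples=150, n_loci=3000, seed=seed, n_marker_loci=300,
                block_factor_sd=0.0, **NO_BATCH,
            )
            bm, _ = simulate_beta_matrix(cfg)
            x = build_design(bm.samples, "placenta_as").to_numpy()
            _, e = fit_unadjusted(bm.values(), x)
            assert estimate_dimension(e, x.shape[1]) in (3, 4)

    def test_override_wins(self):
        e = np.random.default_rng(0).normal(size=(100, 30))
        assert estimate_dimension(e, 2, override=7) == 7

    def test_too_few_samples_rejected(self):
        e = np.random.default_rng(0).normal(size=(100, 5))
        with pytest.raises(ValueError, match="samples"):
            estimate_dimension(e, 4)


class TestFitReffree:
    def test_d0_adjusted_equals_unadjusted(self):
        rng = np.random.default_rng(4)
        x = _design(30, 4)
        y = rng.normal(size=(50, 30))
        b, bstar, lam, u, conv = fit_reffree(y, x, 0)
        assert np.array_equal(b, bstar)  # identical arithmetic path
        assert lam.shape == (50, 0) and u.shape == (30, 0)
        assert conv

    def test_d_too_large_rejected(self):
        rng = np.random.default_rng(5)
        x = _design(10, 5)
        y = rng.normal(size=(20, 10))
        with pytest.raises(ValueError, match="d="):
            fit_reffree(y, x, 6)

    def test_proportion_mediated_effects_shrunk(self):
        """Exposure acting only through cell proportions: the adjusted
        coefficient collapses relative to the unadjusted one."""
        cfg = SimConfig(
            n_samples=300, n_loci=2000, seed=31, n_direct_loci=0,
            block_effect_size=0.0, n_marker_loci=200,
            background_contrast_sd=0.0, missing_frac=NO_MISSING, **NO_BATCH,
        )
        bm, truth = simulate_beta_matrix(cfg)
        fit = run_ewas(bm, "placenta_as", n_boot=0, seed=0)
        med = truth.mediated_loci
        assert med.sum() > 50
        e = fit.exposure_index
        ratio = np.median(np.abs(fit.Bstar[med, e])) / np.median(np.abs(fit.B[med, e]))
        assert ratio < 0.25

    def test_direct_effect_recovered(self):
        cfg = null_config(
            n_samples=300, n_loci=2000, seed=32, n_marker_loci=200, **NO_BATCH
        )
        cfg = dataclasses.replace(cfg, n_direct_loci=50)
        bm, truth = simulate_beta_matrix(cfg)
        fit = run_ewas(bm, "placenta_as", n_boot=0, seed=0)
        e = fit.exposure_index
        mean_eff = fit.Bstar[truth.direct_effect_loci, e].mean()
        assert mean_eff == pytest.approx(-0.002, rel=0.20)


class TestBootstrap:
    def test_same_seed_identical_inference(self):
        cfg = null_config(n_samples=60, n_loci=300, seed=7, **NO_BATCH)
        bm, _ = simulate_beta_matrix(cfg)
        f1 = run_ewas(bm, "placenta_as", n_boot=60, seed=3)
        f2 = run_ewas(bm, "placenta_as", n_boot=60, seed=3)
        assert np.array_equal(f1.SE_Bstar, f2.SE_Bstar)
        assert np.array_equal(f1.p_Bstar, f2.p_Bstar)

    def test_nominal_interval_coverage_under_null(self):
        cfg = null_config(n_samples=150, n_loci=500, seed=8, **NO_BATCH)
        bm, _ = simulate_beta_matrix(cfg)
        fit = run_ewas(bm, "placenta_as", n_boot=200, seed=4)
        e = fit.exposure_index
        covered = (
            np.abs(fit.Bstar[:, e]) <= 1.96 * fit.SE_Bstar[:, e]
        ).mean()
        assert 0.92 <= covered <= 0.97

    def test_se_shrinks_like_sqrt_n(self):
        """Quadrupling n halves the SE, once the realized exposure
        spread (heavy-tailed, so it differs between draws) is factored
        out: SE ~ sigma / (sd(exposure) * sqrt(n))."""
        ses, spreads = {}, {}
        for n in (150, 600):
            cfg = null_config(n_samples=n, n_loci=400, seed=9, **NO_BATCH)
            bm, _ = simulate_beta_matrix(cfg)
            fit = run_ewas(bm, "placenta_as", n_boot=100, seed=5)
            ses[n] = np.median(fit.SE_Bstar[:, fit.exposure_index])
            spreads[n] = bm.samples.loc[fit.sample_ids, "placenta_as"].std()
        ratio = (ses[150] * spreads[150]) / (ses[600] * spreads[600])
        assert 1.8 <= ratio <= 2.2

    def test_tiny_n_boot_rejected(self):
        x = _design(20, 1)
        y = np.random.default_rng(0).normal(size=(30, 20))
        with pytest.raises(ValueError, match="n_boot"):
            ReferenceFreeEWAS(d=0, n_boot=1).fit(x, y)


class TestMultipleTesting:
    @staticmethod
    def _bh_oracle(p):
        """Independent step-up recursion."""
        p = np.asarray(p, float)
        m = len(p)
        order = np.argsort(p, kind="stable")
        q = np.empty(m)
        prev = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            val = min(prev, p[i] * m / rank)
            q[i] = val
            prev = val
        return q

    def test_stepup_example_by_hand(self):
        q, bonf = multiple_testing(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])
        assert np.allclose(bonf, [0.04, 0.08, 0.12, 0.16])

    def test_singleton_identity(self):
        q, bonf = multiple_testing(np.array([0.5]))
        assert q[0] == 0.5 and bonf[0] == 0.5

    def test_matches_independent_stepup_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(10)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 200))
            q, bonf = multiple_testing(p)
            assert np.allclose(q, self._bh_oracle(p), atol=1e-12)
            # second, library-independent route
            assert np.allclose(q, multipletests(p, method="fdr_bh")[1], atol=1e-12)
            assert np.allclose(bonf, np.minimum(p * len(p), 1.0), atol=1e-15)
            assert np.all(q <= bonf + 1e-12)  # BH dominates Bonferroni

    def test_invalid_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            multiple_testing(np.array([]))
        with pytest.raises(ValueError, match="NaN|\\[0, 1\\]"):
            multiple_testing(np.array([0.1, np.nan]))


class TestRunEwas:
    def test_missing_exposure_samples_dropped(self, small_cohort):
        _, bm, _ = small_cohort
        bm2 = bm.subset_samples(bm.beta.columns)
        bm2.samples = bm2.samples.copy()
        bm2.samples.loc[bm2.samples.index[:10], "placenta_as"] = np.nan
        fit = run_ewas(bm2, "placenta_as", n_boot=0, seed=0)
        assert len(fit.sample_ids) == bm.n_samples - 10
        assert not set(bm2.samples.index[:10]) & set(fit.sample_ids)

    def test_results_table_ordering_and_columns(self, small_cohort):
        _, bm, _ = small_cohort
        fit = run_ewas(bm, "placenta_as", n_boot=60, seed=1)
        tab = fit.results_table(bm.annotation)
        assert list(tab.columns[:8]) == [
            "beta_unadj", "beta_adj", "se_unadj", "se_adj",
            "p_unadj", "p_adj", "q", "p_bonf",
        ]
        assert tab["p_adj"].is_monotonic_increasing
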