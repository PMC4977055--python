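"""The delta = beta* - beta confounding statistic and stratified CMH
enrichment, against closed-form, brute-force and simulation oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.stats import chi2_contingency

from refewas.confound import (
    assign_strata,
    cmh_enrichment,
    cmh_test,
    compute_delta,
)
from refewas.ewas import EwasFit, run_ewas
from refewas.simulate import SimConfig, simulate_beta_matrix, simulate_pathways

from conftest import NO_BATCH, NO_MISSING


def _fake_fit(b, bstar, se_b, se_s, cov):
    m = len(b)
    zeros = np.zeros((m, 2))
    return EwasFit(
        probe_ids=pd.Index([f"cg{i}" for i in range(m)], name="probe_id"),
        design_columns=["intercept", "exposure"],
        B=np.column_stack([np.zeros(m), b]),
        Bstar=np.column_stack([np.zeros(m), bstar]),
        Lambda=np.empty((m, 0)),
        U=np.empty((0, 0)),
        d=0,
        SE_B=np.column_stack([np.zeros(m), se_b]),
        SE_Bstar=np.column_stack([np.zeros(m), se_s]),
        p_B=np.ones(m),
        p_Bstar=np.ones(m),
        q=np.ones(m),
        p_bonf=np.ones(m),
        boot_cov=cov,
        n_boot=100,
        seed=0,
        converged=True,
    )


class TestDelta:
    def test_identical_estimates_give_null(self):
        b = np.array([0.1, -0.2, 0.0])
        fit = _fake_fit(b, b.copy(), np.full(3, 0.01), np.full(3, 0.01), np.full(3, 1e-4))
        out = compute_delta(fit)
        assert (out["delta"] == 0).all()
        assert (out["p"] == 1).all()
        assert not out["confounded"].any()

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        b = rng.normal(0, 0.01, 50)
        bs = rng.normal(0, 0.01, 50)
        se = np.full(50, 0.005)
        cov = np.full(50, 1e-6)
        out1 = compute_delta(_fake_fit(b, bs, se, se, cov))
        out2 = compute_delta(_fake_fit(bs, b, se, se, cov))
        assert np.allclose(out1["delta"], -out2["delta"])
        assert np.allclose(out1["p"], out2["p"])

    def test_degenerate_zero_se(self):
        fit = _fake_fit(
            np.array([0.0, 0.1]), np.array([0.0, 0.2]),
            np.zeros(2), np.zeros(2), np.zeros(2),
        )
        with pytest.warns(UserWarning, match="zero SE"):
            out = compute_delta(fit)
        assert out["p"].iloc[0] == 1.0  # delta = 0, se = 0
        assert out["p"].iloc[1] == 0.0  # delta != 0, se = 0

    def test_point_estimate_independent_of_bootstrap_size(self):
        cfg = SimConfig(
            n_samples=120, n_loci=400, seed=3, n_marker_loci=60,
            missing_frac=NO_MISSING, **NO_BATCH,
        )
        bm, _ = simulate_beta_matrix(cfg)
        f1 = run_ewas(bm, "placenta_as", n_boot=60, seed=1)
        f2 = run_ewas(bm, "placenta_as", n_boot=120, seed=1)
        d1 = compute_delta(f1)["delta"]
        d2 = compute_delta(f2)["delta"]
        assert np.allclose(d1, d2, atol=1e-12)

    def test_adjustment_removes_spurious_discoveries(self):
        """On proportion-mediated data the adjusted model yields strictly
        fewer FDR discoveries than the unadjusted one."""
        from refewas.ewas import multiple_testing

        cfg = SimConfig(
            n_samples=250, n_loci=1500, seed=55, n_direct_loci=0,
            block_effect_size=0.0, n_marker_loci=200,
            background_contrast_sd=0.0, missing_frac=NO_MISSING, **NO_BATCH,
        )
        bm, _ = simulate_beta_matrix(cfg)
        fit = run_ewas(bm, "placenta_as", n_boot=150, seed=5)
        q_unadj, _ = multiple_testing(fit.p_B)
        n_unadj = int((q_unadj < 0.05).sum())
        n_adj = int((fit.q < 0.05).sum())
        assert n_unadj > 0
        assert n_adj < n_unadj

    def test_truth_labeled_separation(self):
        """Proportion-mediated loci are flagged far more often than
        direct-effect loci."""
        cfg = SimConfig(
            n_samples=250, n_loci=1200, seed=21, n_direct_loci=40,
            n_marker_loci=150, background_contrast_sd=0.0,
            missing_frac=NO_MISSING, **NO_BATCH,
        )
        bm, truth = simulate_beta_matrix(cfg)
        fit = run_ewas(bm, "placenta_as", n_boot=200, seed=2)
        out = compute_delta(fit)
        conf = out["confounded"].to_numpy()
        med_rate = conf[truth.mediated_loci].mean()
        dir_rate = conf[truth.direct_effect_loci].mean()
        assert med_rate > 0.5
        assert dir_rate <= 0.10


class TestCmh:
    def test_single_stratum_equals_pearson(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            t = rng.integers(1, 200, size=(2, 2)).astype(float)
            chi2, p, _ = cmh_test(t)
            ref = chi2_contingency(t, correction=False)
            assert chi2 == pytest.approx(ref.statistic, abs=1e-8)
            assert p == pytest.approx(ref.pvalue, abs=1e-8)

    def test_two_identical_strata_match_brute_force(self):
        t = np.array([[[10, 90], [5, 195]]] * 2, dtype=float)
        chi2, p, or_mh = cmh_test(t)
        # brute-force evaluation of the Mantel-Haenszel sums
        num = 0.0
        den = 0.0
        or_num = 0.0
        or_den = 0.0
        for a, b, c, d in [(10, 90, 5, 195)] * 2:
            n = a + b + c + d
            num += a - (a + b) * (a + c) / n
            den += (a + b) * (c + d) * (a + c) * (b + d) / n**3
            or_num += a * d / n
            or_den += b * c / n
        assert chi2 == pytest.approx(num**2 / den, abs=1e-10)
        assert or_mh == pytest.approx(or_num / or_den, abs=1e-10)
        assert p == pytest.approx(stats.chi2.sf(num**2 / den, 1), abs=1e-12)

    def test_stratum_relabeling_invariance(self):
        rng = np.random.default_rng(2)
        tables = rng.integers(1, 50, size=(4, 2, 2)).astype(float)
        ref = cmh_test(tables)
        perm = cmh_test(tables[[2, 0, 3, 1]])
        assert ref == pytest.approx(perm)

    def test_simpsons_paradox_pooling_direction(self):
        """With a stratifier confounding the association, the pooled
        chi-square exceeds the stratified one; both match brute force."""
        # stratum 1: mostly in-term, high confounded rate; stratum 2: reverse.
        # Within each stratum the odds ratio is exactly 1.
        s1 = np.array([[40.0, 40.0], [10.0, 10.0]])
        s2 = np.array([[5.0, 45.0], [15.0, 135.0]])
        strat_chi2, _, or_strat = cmh_test(np.stack([s1, s2]))
        pooled_chi2, _, or_pooled = cmh_test(s1 + s2)
        assert strat_chi2 == pytest.approx(0.0, abs=1e-10)
        assert or_strat == pytest.approx(1.0, abs=1e-10)
        assert pooled_chi2 > strat_chi2
        assert or_pooled > 1.0

    def test_empty_stratum_rejected(self):
        with pytest.raises(ValueError, match="empty stratum"):
            cmh_test(np.array([[[0.0, 0.0], [0.0, 0.0]]]))


class TestEnrichment:
    @staticmethod
    def _random_inputs(seed, m=2000, n_terms=300, term_size=30, frac_conf=0.1):
        rng = np.random.default_rng(seed)
        probes = pd.Index([f"cg{i:05d}" for i in range(m)], name="probe_id")
        confounded = pd.Series(rng.random(m) < frac_conf, index=probes)
        strata = pd.Series(
            [
                f"{isl}|{reg}"
                for isl, reg in zip(
                    rng.choice(["Island", "Shore", "Shelf", "OpenSea"], m),
                    rng.choice(["TSS200", "Body", "3'UTR"], m),
                )
            ],
            index=probes,
        )
        rows = []
        for t in range(n_terms):
            for i in rng.choice(m, size=term_size, replace=False):
                rows.append((probes[i], f"{t:07d}"))
        membership = pd.DataFrame(rows, columns=["probe_id", "term_id"])
        return confounded, membership, strata

    def test_null_terms_calibrated(self):
        """Terms independent of the flags: p uniform.  Table cells are
        kept large enough (expected a ~ 12) for the chi-square reference
        to hold."""
        confounded, membership, strata = self._random_inputs(
            0, n_terms=1000, term_size=60, frac_conf=0.2
        )
        out = cmh_enrichment(confounded, membership, strata)
        frac = (out["p"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_small_terms_skipped(self):
        confounded, membership, strata = self._random_inputs(1, n_terms=10)
        tiny = pd.DataFrame(
            {"probe_id": ["cg00000", "cg00001"], "term_id": ["tiny"] * 2}
        )
        out = cmh_enrichment(confounded, pd.concat([membership, tiny]), strata)
        assert "tiny" not in out.index

    def test_planted_enrichment_ranks_first(self):
        """Terms deliberately loaded with confounded loci outrank the
        random ones."""
        for seed in range(3):
            confounded, membership, strata = self._random_inputs(seed + 10, n_terms=50)
            conf_ids = confounded.index[confounded]
            rng = np.random.default_rng(seed)
            planted = pd.DataFrame(
                {
                    "probe_id": rng.choice(conf_ids, size=30, replace=False),
                    "term_id": "planted",
                }
            )
            out = cmh_enrichment(confounded, pd.concat([membership, planted]), strata)
            assert out.index[0] == "planted"
            assert out.loc["planted", "significant"]

    def test_degenerate_strata_pooled_not_dropped(self):
        probes = pd.Index([f"cg{i}" for i in range(40)], name="probe_id")
        confounded = pd.Series([True] * 10 + [False] * 30, index=probes)
        # one stratum has zero confounded loci overall -> zero column margin
        strata = pd.Series(
            ["Island|TSS200"] * 20 + ["OpenSea|Body"] * 20, index=probes
        )
        confounded.iloc[:10] = True
        membership = pd.DataFrame(
            {"probe_id": probes[:12], "term_id": ["t1"] * 12}
        )
        out = cmh_enrichment(confounded, membership, strata, min_term_size=5)
        assert len(out) == 1
        assert np.isfinite(out["chi2_mh"].iloc[0])

    def test_pipeline_level_power(self, small_cohort):
        """Planted pathway enrichment is recovered end-to-end from a
        simulated cohort with proportion effects."""
        cfg = SimConfig(
            n_samples=250, n_loci=1500, seed=33, n_direct_loci=30,
            n_marker_loci=250, background_contrast_sd=0.0,
            n_terms=80, missing_frac=NO_MISSING, **NO_BATCH,
        )
        bm, truth = simulate_beta_matrix(cfg)
        membership, truth = simulate_pathways(cfg, truth, bm.beta.index)
        fit = run_ewas(bm, "placenta_as", n_boot=150, seed=3)
        delta = compute_delta(fit)
        out = cmh_enrichment(
            delta["confounded"], membership, assign_strata(bm.annotation)
        )
        ranks = [list(out.index).index(t) for t in truth.enriched_terms]
        assert max(ranks) < max(5, int(0.05 * len(out)))


def test_assign_strata_promoter_priority():
    ann = pd.DataFrame(
        {
            "gene_region": ["Body;TSS200", "3'UTR;5'UTR", "Body"],
            "island_relation": ["Island", "Shore", "OpenSea"],
        },
        index=pd.Index(["a", "b", "c"], name="probe_id"),
    )
    s = assign_strata(ann)
    assert s["a"] == "Island|TSS200"
    assert s["b"] == "Shore|5'UTR"
    assert s["c"] == "OpenSea|Body"
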