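"""Generator behaviour: Hardy-Weinberg structure, APOE haplotypes,
mediator models, outcome models and determinism."""

import numpy as np
import pandas as pd
import pytest

from brainpath.errors import ValidationError
from brainpath.phenotypes import proxy_scores
from brainpath.synthetic import (
    CohortConfig,
    OutcomeParams,
    VariantSpec,
    default_outcome_params,
    default_panel,
    generate_apoe_genotypes,
    generate_cohort,
    generate_genotypes,
    generate_mediators,
    generate_outcome,
)


def _config(n, seed=7, **kw):
    return CohortConfig(n_participants=n, seed=seed, **kw)


class TestGenotypes:
    def test_sample_allele_frequency_matches_specification(self):
        panel = [VariantSpec("v1", "A", 0.5)]
        g = generate_genotypes(_config(10_000), panel)
        assert abs(g["v1"].mean() / 2 - 0.5) < 0.02

    def test_genotype_classes_follow_hardy_weinberg(self):
        panel = [VariantSpec("v1", "A", 0.2)]
        g = generate_genotypes(_config(50_000), panel)["v1"]
        props = np.array([(g == k).mean() for k in (0, 1, 2)])
        expected = np.array([0.64, 0.32, 0.04])
        # 5 sigma Monte-Carlo band per class
        tol = 5 * np.sqrt(expected * (1 - expected) / 50_000)
        assert np.all(np.abs(props - expected) < tol)

    @pytest.mark.parametrize("freq", [0.0, 1.0, -0.1, float("nan"), float("inf")])
    def test_out_of_range_frequency_rejected(self, freq):
        with pytest.raises(ValidationError):
            VariantSpec("v1", "A", freq)

    def test_duplicate_variant_ids_rejected(self):
        panel = [VariantSpec("v1", "A", 0.2), VariantSpec("v1", "C", 0.3)]
        with pytest.raises(ValidationError):
            generate_genotypes(_config(10), panel)

    def test_missingness_rate_applied(self):
        panel = [VariantSpec("v1", "A", 0.3)]
        g = generate_genotypes(_config(20_000), panel, missing_rate=0.1)["v1"]
        assert abs(g.isna().mean() - 0.1) < 0.01

    def test_same_seed_gives_identical_matrix(self):
        panel = [VariantSpec("v1", "A", 0.3), VariantSpec("v2", "C", 0.1)]
        g1 = generate_genotypes(_config(500, seed=11), panel)
        g2 = generate_genotypes(_config(500, seed=11), panel)
        pd.testing.assert_frame_equal(g1, g2)


class TestApoe:
    def test_pure_e4_population(self):
        g = generate_apoe_genotypes(50, {"e4": 1.0}, seed=1)
        assert (g["rs429358"] == "C/C").all()
        assert (g["rs7412"] == "C/C").all()
        assert (g["e4_count"] == 2).all()

    def test_pure_e3_population(self):
        g = generate_apoe_genotypes(50, {"e3": 1.0}, seed=1)
        assert (g["rs429358"] == "T/T").all()
        assert (g["rs7412"] == "C/C").all()
        assert (g["e4_count"] == 0).all()

    def test_mean_e4_count_matches_haplotype_frequency(self):
        g = generate_apoe_genotypes(50_000, {"e3": 0.85, "e4": 0.15}, seed=5)
        # two independent haplotype draws: E[count] = 2 * 0.15
        assert abs(g["e4_count"].mean() - 0.30) < 0.01

    def test_frequencies_must_sum_to_one(self):
        with pytest.raises(ValidationError):
            generate_apoe_genotypes(10, {"e3": 0.5, "e4": 0.4}, seed=1)

    def test_unknown_haplotype_rejected(self):
        with pytest.raises(ValidationError):
            generate_apoe_genotypes(10, {"e5": 1.0}, seed=1)


class TestMediators:
    def test_null_effects_give_null_association(self):
        panel = [VariantSpec("v1", "A", 0.3, mediator_effects={"m__volume": 0.0})]
        cfg = _config(5000)
        g = generate_genotypes(cfg, panel)
        m = generate_mediators(g, None, panel, residual_sd=1.0, rng=np.random.default_rng(4))
        slope, se = _ols_slope(g["v1"].to_numpy(), m["m__volume"].to_numpy())
        assert abs(slope) < 3 * se

    def test_known_coefficient_recovered(self):
        beta = -0.424
        panel = [VariantSpec("v1", "A", 0.15, mediator_effects={"hippocampus__volume": beta})]
        cfg = _config(5000, seed=9)
        g = generate_genotypes(cfg, panel)
        m = generate_mediators(g, None, panel, residual_sd=1.0, rng=np.random.default_rng(10))
        slope, _ = _ols_slope(g["v1"].to_numpy(), m["hippocampus__volume"].to_numpy())
        assert abs(slope - beta) < 0.05

    def test_noiseless_identity(self):
        panel = [VariantSpec("v1", "A", 0.5, mediator_effects={"m__area": 1.0})]
        cfg = _config(200)
        g = generate_genotypes(cfg, panel)
        m = generate_mediators(g, None, panel, residual_sd=0.0, rng=np.random.default_rng(0))
        np.testing.assert_array_equal(m["m__area"].to_numpy(), g["v1"].to_numpy())

    def test_dimension_mismatch_rejected(self):
        panel = [VariantSpec("v1", "A", 0.5, mediator_effects={"m__area": 1.0})]
        g = generate_genotypes(_config(100), panel)
        cov = pd.DataFrame({"age": np.zeros(50)})
        with pytest.raises(ValidationError):
            generate_mediators(g, cov, panel, residual_sd=1.0)


class TestOutcome:
    def test_null_model_case_fraction_half(self):
        cfg = _config(20_000, cohort_style="case_control",
                      outcome_params=OutcomeParams(intercept=0.0))
        g = generate_genotypes(cfg, [VariantSpec("v1", "A", 0.3)])
        out = generate_outcome(g, None, None, cfg, rng=np.random.default_rng(2))
        assert abs(out["status"].mean() - 0.5) < 0.015

    def test_direct_effect_without_mediation(self):
        """With path b zero, the outcome associates with dosage but not with
        the mediator once dosage is conditioned on."""
        import statsmodels.api as sm

        panel = [VariantSpec("v1", "A", 0.3, mediator_effects={"m__volume": 0.5},
                             direct_outcome_effect=0.8)]
        cfg = _config(8000, cohort_style="case_control",
                      outcome_params=OutcomeParams(intercept=-0.5, mediator_coefficients={}))
        r = np.random.default_rng(3)
        g = generate_genotypes(cfg, panel, rng=r)
        m = generate_mediators(g, None, panel, residual_sd=1.0, rng=r)
        out = generate_outcome(g, m, None, cfg, rng=r, panel=panel)
        X = sm.add_constant(np.column_stack([g["v1"], m["m__volume"]]))
        fit = sm.GLM(out["status"], X, family=sm.families.Binomial()).fit()
        assert fit.pvalues.iloc[1] < 1e-6                    # dosage association present
        assert abs(fit.params.iloc[2]) < 3 * fit.bse.iloc[2]  # mediator null given dosage

    def test_proxy_null_slope_gives_null_correlation(self):
        cfg = _config(5000, cohort_style="proxy",
                      outcome_params=OutcomeParams(liability_slope=0.0))
        panel = [VariantSpec("v1", "A", 0.3, direct_outcome_effect=1.0)]
        r = np.random.default_rng(8)
        g = generate_genotypes(cfg, panel, rng=r)
        out = generate_outcome(g, None, None, cfg, rng=r, panel=panel)
        score = proxy_scores(out)
        corr = np.corrcoef(g["v1"], score)[0, 1]
        assert abs(corr) < 3 / np.sqrt(len(score))

    def test_proxy_score_correlates_with_risk_dosage(self):
        cfg = _config(8000, cohort_style="proxy", outcome_params=OutcomeParams())
        panel = [VariantSpec("v1", "A", 0.3, direct_outcome_effect=1.0)]
        r = np.random.default_rng(8)
        g = generate_genotypes(cfg, panel, rng=r)
        out = generate_outcome(g, None, None, cfg, rng=r, panel=panel)
        score = proxy_scores(out)
        assert np.corrcoef(g["v1"], score)[0, 1] > 0.02

    def test_unknown_cohort_style_rejected(self):
        with pytest.raises(ValidationError):
            _config(10, cohort_style="registry")


class TestFullCohort:
    def test_fixed_seed_bit_identical(self):
        cfg = _config(300, seed=77, cohort_style="case_control",
                      outcome_params=default_outcome_params("case_control"))
        c1 = generate_cohort(cfg)
        c2 = generate_cohort(cfg)
        pd.testing.assert_frame_equal(c1.genotypes, c2.genotypes)
        pd.testing.assert_frame_equal(c1.phenotypes, c2.phenotypes)

    def test_proxy_score_distribution_near_study_profile(self):
        """Default proxy parameters target a score distribution with mean
        near 0.66 and SD near 0.41 (shape itself is unspecified)."""
        cfg = _config(20_000, seed=5, cohort_style="proxy")
        c = generate_cohort(cfg, panel=default_panel())
        score = proxy_scores(c.phenotypes)
        assert abs(score.mean() - 0.66) < 0.10
        assert abs(score.std() - 0.41) < 0.08

    def test_regional_table_covers_catalog(self):
        from brainpath.catalog import measure_catalog

        cfg = _config(50, seed=1, cohort_style="case_control",
                      outcome_params=default_outcome_params("case_control"))
        c = generate_cohort(cfg)
        for region, mtype in measure_catalog():
            assert f"{region}__{mtype}__L" in c.phenotypes.columns
            assert f"{region}__{mtype}__R" in c.phenotypes.columns
        assert "icv" in c.phenotypes.columns


def _ols_slope(x, y):
    x = np.column_stack([np.ones_like(x), x])
    beta, res, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    sigma2 = resid @ resid / (len(y) - 2)
    cov = sigma2 * np.linalg.inv(x.T @ x)
    return beta[1], np.sqrt(cov[1, 1])
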