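"""REML engine: closed-form oracles, invariances, LRT/Wald behaviour."""

import numpy as np
import pandas as pd
import pytest

from owl_divergence import (
    MixedModelSpec,
    TraitSimConfig,
    lrt_random_effect,
    reml_fit,
    simulate_trait_table,
    wald_fixed_effect,
)
from owl_divergence.reml import _RemlProblem, _indicator, build_design
from helpers import anova_oracle, one_way


class TestAgainstClosedForm:
    @pytest.mark.parametrize("g,n", [(3, 2), (5, 10), (8, 4), (10, 20)])
    def test_balanced_one_way_matches_anova(self, g, n):
        df = one_way(g, n, sigma_pop=1.0, sigma_res=0.5, seed=10 * g + n)
        s_pop, s_res = anova_oracle(df, g, n)
        assert s_pop > 0  # interior optimum for these draws
        fit = reml_fit(
            df, MixedModelSpec(response="y", random_terms=("population_id",))
        )
        assert fit.estimates["population_id"] == pytest.approx(s_pop, rel=1e-8)
        assert fit.estimates["residual"] == pytest.approx(s_res, rel=1e-8)

    def test_constant_response_gives_zero_variances(self):
        df = pd.DataFrame(
            {"y": np.ones(40), "population_id": np.repeat(list("abcd"), 10)}
        )
        fit = reml_fit(
            df, MixedModelSpec(response="y", random_terms=("population_id",))
        )
        assert fit.estimates["population_id"] < 1e-8
        assert fit.estimates["residual"] < 1e-8


class TestRecovery:
    def test_crossed_components_recovered_from_synthetic_tables(self):
        """Population/individual/residual recovery at the measurement level."""
        truth = {"population_id": 0.09, "individual_id": 0.10, "residual": 0.12}
        est = {k: [] for k in truth}
        spec = MixedModelSpec(
            response="plumulaceous_length",
            fixed_terms=("1",),
            random_terms=("population_id", "individual_id"),
        )
        for rep in range(30):
            cfg = TraitSimConfig(
                n_individuals_per_pop=12,
                sigma2_pop=0.09,
                sigma2_ind=0.10,
                sigma2_year=0.0,
                sigma2_res=0.12,
                morph_effect=0.0,
                length_slope=0.0,
                years=(2021,),
                seed=500 + rep,
            )
            table, _ = simulate_trait_table(cfg)
            sub = table.data[table.data["side"] == "ventral"].copy()
            fit = reml_fit(sub, spec)
            for k in truth:
                est[k].append(fit.estimates[k])
        for k, target in truth.items():
            vals = np.array(est[k])
            mc_se = vals.std(ddof=1) / np.sqrt(len(vals))
            assert abs(vals.mean() - target) < 3 * mc_se, (
                f"{k}: mean {vals.mean():.4f} vs {target} (MC SE {mc_se:.4f})"
            )


class TestInvariances:
    def test_affine_recoding_of_covariate_leaves_variances_unchanged(self):
        df = one_way(8, 6, 0.8, 0.5, seed=77)
        rng = np.random.default_rng(78)
        df["x"] = rng.normal(size=len(df))
        spec1 = MixedModelSpec(
            response="y", fixed_terms=("1", "x"), random_terms=("population_id",)
        )
        fit1 = reml_fit(df, spec1)
        df2 = df.copy()
        df2["x"] = 2.0 * df["x"] + 3.0
        fit2 = reml_fit(df2, spec1)
        for k in fit1.estimates:
            assert fit1.estimates[k] == pytest.approx(fit2.estimates[k], rel=1e-6)
        # slope absorbs the rescaling
        assert fit2.fixed_estimates["x"][0] == pytest.approx(
            fit1.fixed_estimates["x"][0] / 2.0, rel=1e-6
        )

    def test_loglik_is_maximal_at_reported_optimum(self):
        df = one_way(6, 8, 1.0, 0.6, seed=5)
        spec = MixedModelSpec(response="y", random_terms=("population_id",))
        fit = reml_fit(df, spec)
        y, X, _, random = build_design(df, spec)
        Z = _indicator(random["population_id"])
        prob = _RemlProblem(y, X, [Z @ Z.T])
        s2_hat = np.array(
            [fit.estimates["population_id"], fit.estimates["residual"]]
        )
        ll_hat = prob.loglik(s2_hat)
        for k in range(2):
            for fac in (0.95, 1.05):
                s2 = s2_hat.copy()
                s2[k] *= fac
                assert prob.loglik(s2) <= ll_hat + 1e-9

    def test_aliased_fixed_columns_dropped_with_warning(self):
        df = one_way(4, 5, 1.0, 0.5, seed=9)
        df["x"] = 1.0  # aliased with the intercept
        with pytest.warns(UserWarning, match="aliased"):
            fit = reml_fit(
                df,
                MixedModelSpec(
                    response="y",
                    fixed_terms=("1", "x"),
                    random_terms=("population_id",),
                ),
            )
        assert "x" not in fit.fixed_estimates


class TestLikelihoodRatio:
    def test_identical_loglik_gives_null_result(self):
        df = one_way(6, 6, 1.0, 0.5, seed=21)
        full = reml_fit(
            df, MixedModelSpec(response="y", random_terms=("population_id",))
        )
        reduced_same = full
        # construct a formally reduced fit with the same loglik
        reduced = reml_fit(
            df, MixedModelSpec(response="y", random_terms=())
        )
        reduced.reml_loglik = full.reml_loglik
        chi2, p = lrt_random_effect(full, reduced)
        assert chi2 == 0.0 and p == 1.0
        del reduced_same

    def test_chi2_quantile_identity(self):
        df = one_way(6, 6, 1.0, 0.5, seed=22)
        full = reml_fit(
            df, MixedModelSpec(response="y", random_terms=("population_id",))
        )
        reduced = reml_fit(df, MixedModelSpec(response="y", random_terms=()))
        reduced.reml_loglik = full.reml_loglik - 3.841459 / 2.0
        chi2, p = lrt_random_effect(full, reduced)
        assert chi2 == pytest.approx(3.841459, abs=1e-6)
        assert p == pytest.approx(0.050, abs=1e-3)

    def test_non_nested_specs_rejected(self):
        df = one_way(6, 6, 1.0, 0.5, seed=23)
        a = reml_fit(
            df, MixedModelSpec(response="y", random_terms=("population_id",))
        )
        with pytest.raises(ValueError, match="exactly one random term"):
            lrt_random_effect(a, a)

    def test_null_rejection_rate_is_conservative_at_boundary(self):
        """With sigma2_pop = 0 the 1-df LRT rejects less than 5% of the time."""
        rejections = 0
        reps = 200
        for rep in range(reps):
            df = one_way(9, 10, sigma_pop=0.0, sigma_res=1.0, seed=3000 + rep)
            full = reml_fit(
                df, MixedModelSpec(response="y", random_terms=("population_id",))
            )
            reduced = reml_fit(df, MixedModelSpec(response="y", random_terms=()))
            _, p = lrt_random_effect(full, reduced)
            rejections += p < 0.05
        rate = rejections / reps
        assert rate < 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)


class TestWald:
    def test_zero_estimate_gives_p_one(self):
        df = one_way(6, 6, 1.0, 0.5, seed=31)
        fit = reml_fit(
            df, MixedModelSpec(response="y", random_terms=("population_id",))
        )
        fit.fixed_estimates["fake"] = (0.0, 1.0)
        chi2, p = wald_fixed_effect(fit, "fake")
        assert chi2 == 0.0 and p == 1.0

    def test_z_quantile_identity(self):
        df = one_way(6, 6, 1.0, 0.5, seed=32)
        fit = reml_fit(
            df, MixedModelSpec(response="y", random_terms=("population_id",))
        )
        fit.fixed_estimates["fake"] = (1.959964, 1.0)
        _, p = wald_fixed_effect(fit, "fake")
        assert p == pytest.approx(0.050, abs=1e-3)

    def test_zero_se_is_an_error(self):
        df = one_way(6, 6, 1.0, 0.5, seed=33)
        fit = reml_fit(
            df, MixedModelSpec(response="y", random_terms=("population_id",))
        )
        fit.fixed_estimates["fake"] = (1.0, 0.0)
        with pytest.raises(ValueError, match="zero SE"):
            wald_fixed_effect(fit, "fake")

    def test_morph_effect_detected_at_scale(self):
        """A 0.3-unit morph shift against ~0.1 residual variance is found."""
        detected = 0
        for rep in range(10):
            df = one_way(
                9, 40, sigma_pop=0.15, sigma_res=0.3, seed=4000 + rep,
                beta_morph=0.3,
            )
            fit = reml_fit(
                df,
                MixedModelSpec(
                    response="y",
                    fixed_terms=("1", "morph"),
                    random_terms=("population_id",),
                ),
            )
            _, p = wald_fixed_effect(fit, "morph")
            detected += p < 0.001
        assert detected >= 9
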