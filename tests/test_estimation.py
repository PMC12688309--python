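"""Estimation: logistic / multinomial / random-intercept logistic ML,
checked against closed forms, statsmodels, lme4 and simulation truth."""

import math
import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from climmed import enfr
from climmed import synthetic as syn
from climmed.estimation import (
    ModelSpec,
    fit_logistic,
    fit_logistic_ri,
    fit_multinomial,
    information_criteria,
)
from climmed.exceptions import (
    InvalidArgumentError,
    RankDeficiencyError,
    SeparationError,
    VarianceUnidentifiedError,
)

from conftest import make_logistic_data


class TestLogistic:
    def test_two_by_two_matches_closed_form_log_or(self):
        """On data expanded from a 2x2 table the sex coefficient is the
        contingency-table log odds ratio, exactly."""
        data = enfr.expand_counts("sex")
        fit = fit_logistic(data, ModelSpec("overweight", "binary", ["sex"]))
        (m_no, m_yes) = enfr.TABLE1_COUNTS["sex"]["male"]
        (f_no, f_yes) = enfr.TABLE1_COUNTS["sex"]["female"]
        expected = math.log((f_yes * m_no) / (f_no * m_yes))
        assert fit.coefficients["sex[female]"] == pytest.approx(expected, abs=1e-8)

    def test_matches_statsmodels(self, default_cohort):
        sm = pytest.importorskip("statsmodels.api")
        _, _, cohort = default_cohort
        d = cohort.dropna(subset=["fv_adequate"]).reset_index(drop=True)
        spec = ModelSpec(
            "overweight", "binary",
            ["mean_temp_c", "sex", "age", "education", "fv_adequate", "pa_level"],
        )
        fit = fit_logistic(d, spec)
        from climmed.estimation import _binary_response, build_design

        X, _ = build_design(d, spec.predictors, {})
        ref = sm.Logit(_binary_response(d, "overweight"), X).fit(disp=0)
        np.testing.assert_allclose(fit.coefficients.to_numpy(), ref.params, atol=1e-7)
        np.testing.assert_allclose(
            fit.standard_errors.to_numpy(), ref.bse, rtol=1e-5
        )
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-7)
        assert fit.aic == pytest.approx(ref.aic, abs=1e-6)

    def test_constant_response_is_degenerate(self):
        data = pd.DataFrame({"x": [0.0, 1.0, 2.0], "y": [1.0, 1.0, 1.0]})
        with pytest.raises(SeparationError):
            fit_logistic(data, ModelSpec("y", "binary", ["x"]))

    def test_perfect_separation_names_term(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        data = pd.DataFrame({"x": x, "y": (x > 0).astype(float)})
        with pytest.raises(SeparationError, match="x"):
            fit_logistic(data, ModelSpec("y", "binary", ["x"]))

    def test_duplicated_column_is_rank_deficient(self):
        data = make_logistic_data(200, (0.0, 1.0), seed=1)
        data["x2"] = data["x"]
        with pytest.raises(RankDeficiencyError):
            fit_logistic(data, ModelSpec("y", "binary", ["x", "x2"]))

    def test_simulation_recovery(self):
        data = make_logistic_data(100_000, (-0.3, 0.6), seed=4)
        fit = fit_logistic(data, ModelSpec("y", "binary", ["x"]))
        assert abs(fit.coefficients["x"] - 0.6) < 3 * fit.standard_errors["x"]
        assert abs(fit.coefficients["intercept"] + 0.3) < 3 * fit.standard_errors["intercept"]

    def test_affine_reparameterization(self, default_cohort):
        """Scaling the exposure by 10 divides its coefficient by 10 and
        leaves the log-likelihood unchanged."""
        _, _, cohort = default_cohort
        d = cohort.dropna(subset=["fv_adequate"]).reset_index(drop=True)
        spec = ModelSpec("overweight", "binary", ["mean_temp_c", "sex", "age"])
        fit = fit_logistic(d, spec)
        scaled = d.assign(mean_temp_c=10.0 * d["mean_temp_c"])
        fit10 = fit_logistic(scaled, spec)
        assert fit10.coefficients["mean_temp_c"] == pytest.approx(
            fit.coefficients["mean_temp_c"] / 10.0, rel=1e-6
        )
        assert fit10.loglik == pytest.approx(fit.loglik, abs=1e-6)

    def test_loglik_monotone_in_predictors(self, default_cohort):
        _, _, cohort = default_cohort
        d = cohort.dropna(subset=["fv_adequate"]).reset_index(drop=True)
        lls = []
        preds = []
        for add in (["mean_temp_c"], ["sex"], ["age"], ["education"]):
            preds += add
            lls.append(fit_logistic(d, ModelSpec("overweight", "binary", list(preds))).loglik)
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))

    def test_wald_interval_uses_z975(self, default_cohort):
        _, _, cohort = default_cohort
        fit = fit_logistic(cohort, ModelSpec("overweight", "binary", ["mean_temp_c"]))
        ci = fit.conf_int()
        term = "mean_temp_c"
        assert ci.loc[term, "low"] == pytest.approx(
            fit.coefficients[term] - 1.959964 * fit.standard_errors[term]
        )


class TestMultinomial:
    def test_two_level_reduces_to_binary(self, default_cohort):
        """Collapsing to two categories, the multinomial block equals the
        binary logistic fit to 1e-8."""
        _, _, cohort = default_cohort
        d = cohort.copy()
        d["pa2"] = np.where(d["pa_level"] == "low", "no", "yes")
        from climmed.estimation import _newton_multinomial, build_design

        X, names = build_design(d, ["mean_temp_c", "sex", "age"])
        Y = (d["pa2"] == "yes").to_numpy(dtype=float)[:, None]
        theta, _, ll_mn, _ = _newton_multinomial(X, Y, None, names, ["yes"])
        binary = fit_logistic(d.assign(y=Y[:, 0]), ModelSpec("y", "binary", ["mean_temp_c", "sex", "age"]))
        np.testing.assert_allclose(theta, binary.coefficients.to_numpy(), atol=1e-8)
        assert ll_mn == pytest.approx(binary.loglik, abs=1e-8)

    def test_saturated_model_closed_form(self):
        """With one categorical predictor the saturated multinomial
        coefficients are log relative-frequency ratios of the cross-tab."""
        rng = np.random.default_rng(8)
        sexes = rng.choice(["male", "female"], 4000)
        pa = rng.choice(["low", "moderate", "high"], 4000, p=[0.5, 0.3, 0.2])
        data = pd.DataFrame({"sex": sexes, "pa_level": pa})
        fit = fit_multinomial(data, ModelSpec("pa_level", "multinomial3", ["sex"]), reference="low")
        tab = pd.crosstab(data["sex"], data["pa_level"])
        for level in ("moderate", "high"):
            intercept = math.log(tab.loc["male", level] / tab.loc["male", "low"])
            slope = (
                math.log(tab.loc["female", level] / tab.loc["female", "low"]) - intercept
            )
            assert fit.coefficients[f"{level}:intercept"] == pytest.approx(intercept, abs=1e-6)
            assert fit.coefficients[f"{level}:sex[female]"] == pytest.approx(slope, abs=1e-6)

    def test_matches_statsmodels(self, default_cohort):
        sm = pytest.importorskip("statsmodels.api")
        _, _, cohort = default_cohort
        spec = ModelSpec("pa_level", "multinomial3", ["mean_temp_c", "sex", "age", "education"])
        fit = fit_multinomial(cohort, spec)
        from climmed.estimation import build_design

        X, _ = build_design(cohort, spec.predictors, {})
        codes = pd.Categorical(
            cohort["pa_level"], categories=["low", "moderate", "high"]
        ).codes
        ref = sm.MNLogit(np.asarray(codes), X).fit(disp=0)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-6)
        np.testing.assert_allclose(
            fit.coefficients.to_numpy().reshape(2, -1),
            np.asarray(ref.params).T,
            atol=1e-6,
        )

    def test_relabeling_symmetry(self, default_cohort):
        """Swapping the two non-reference labels permutes the blocks and
        leaves the log-likelihood unchanged."""
        _, _, cohort = default_cohort
        swapped = cohort.assign(
            pa_level=cohort["pa_level"].map(
                {"low": "low", "moderate": "high", "high": "moderate"}
            )
        )
        spec = ModelSpec("pa_level", "multinomial3", ["mean_temp_c", "sex"])
        fit = fit_multinomial(cohort, spec)
        fit_sw = fit_multinomial(swapped, spec)
        assert fit_sw.loglik == pytest.approx(fit.loglik, abs=1e-8)
        for term in ("intercept", "mean_temp_c", "sex[female]"):
            assert fit_sw.coefficients[f"moderate:{term}"] == pytest.approx(
                fit.coefficients[f"high:{term}"], abs=1e-7
            )

    def test_absent_category_rejected(self, default_cohort):
        _, _, cohort = default_cohort
        two_level = cohort[cohort["pa_level"] != "high"]
        with pytest.raises(InvalidArgumentError):
            fit_multinomial(two_level, ModelSpec("pa_level", "multinomial3", ["mean_temp_c"]))


class TestRandomInterceptLogistic:
    def test_sigma_zero_equals_plain_logistic(self, default_cohort):
        _, _, cohort = default_cohort
        spec = ModelSpec(
            "overweight", "binary", ["mean_temp_c", "sex", "age"], cluster="province_id"
        )
        constrained = fit_logistic_ri(cohort, spec, fix_sigma2=0.0)
        plain = fit_logistic(cohort, ModelSpec("overweight", "binary", spec.predictors))
        assert constrained.loglik == pytest.approx(plain.loglik, abs=1e-8)

    def test_quadrature_doubling_stable(self, default_cohort):
        _, _, cohort = default_cohort
        spec = ModelSpec(
            "overweight", "binary", ["mean_temp_c", "sex", "age"], cluster="province_id"
        )
        fit7 = fit_logistic_ri(cohort, spec, quadrature_points=7)
        fit14 = fit_logistic_ri(cohort, spec, quadrature_points=14)
        assert abs(fit7.loglik - fit14.loglik) < 1e-6

    def test_variance_recovery(self):
        """200 clusters of 200 with σ² = 0.026: the estimate lands within
        3 reported SEs of the truth."""
        data = make_logistic_data(40_000, (0.2, 0.4), seed=6, n_clusters=200, sigma2=0.026)
        fit = fit_logistic_ri(data, ModelSpec("y", "binary", ["x"], cluster="cluster"))
        assert fit.variance_component == pytest.approx(
            0.026, abs=3 * fit.variance_component_se
        )
        assert abs(fit.coefficients["x"] - 0.4) < 3 * fit.standard_errors["x"]

    def test_permuted_clusters_drive_variance_to_zero(self):
        data = make_logistic_data(20_000, (0.0, 0.5), seed=9, n_clusters=50, sigma2=0.3)
        rng = np.random.default_rng(10)
        data["cluster"] = rng.permutation(data["cluster"].to_numpy())
        fit = fit_logistic_ri(data, ModelSpec("y", "binary", ["x"], cluster="cluster"))
        assert fit.variance_component < 0.005

    def test_single_cluster_unidentified(self):
        data = make_logistic_data(500, (0.0, 0.5), seed=2)
        data["cluster"] = 0
        with pytest.raises(VarianceUnidentifiedError):
            fit_logistic_ri(data, ModelSpec("y", "binary", ["x"], cluster="cluster"))

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
    def test_matches_lme4_glmer(self, tmp_path):
        """Independent oracle: lme4::glmer with nAGQ=7 on a clustered
        testbed reproduces coefficients, σ² and the log-likelihood."""
        data = make_logistic_data(6_000, (0.3, -0.4), seed=13, n_clusters=30, sigma2=0.3)
        csv = tmp_path / "d.csv"
        data.to_csv(csv, index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- glmer(y ~ x + (1|cluster), data=d, family=binomial, nAGQ=7)
            cat(sprintf("%.12f", c(fixef(m), VarCorr(m)$cluster[1],
                                   as.numeric(logLik(m)))), sep="\\n")
        """)
        out = subprocess.run(
            ["Rscript", "-"], input=script, capture_output=True, text=True, check=True
        )
        b0, b1, s2, ll = (float(v) for v in out.stdout.strip().splitlines())
        fit = fit_logistic_ri(data, ModelSpec("y", "binary", ["x"], cluster="cluster"))
        assert fit.coefficients["intercept"] == pytest.approx(b0, abs=1e-4)
        assert fit.coefficients["x"] == pytest.approx(b1, abs=1e-4)
        assert fit.variance_component == pytest.approx(s2, abs=1e-4)
        assert fit.loglik == pytest.approx(ll, abs=1e-4)


class TestInformationCriteria:
    @pytest.mark.parametrize(
        "loglik,k,n,expected",
        [
            (0.0, 0, 10, (0.0, 0.0)),
            (-50.0, 0, 7, (100.0, 100.0)),
        ],
    )
    def test_degenerate_cases(self, loglik, k, n, expected):
        assert information_criteria(loglik, k, n) == pytest.approx(expected)

    def test_formula(self):
        aic, bic = information_criteria(-123.5, 4, 250)
        assert aic == pytest.approx(2 * 4 + 247.0)
        assert bic == pytest.approx(4 * math.log(250) + 247.0)

    def test_invalid_n(self):
        with pytest.raises(InvalidArgumentError):
            information_criteria(-1.0, 2, 0)
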