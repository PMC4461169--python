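"""Mixed-model fitting: recovery checks, conversions and an lme4 oracle."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit
from scipy.stats import chi2, norm

from speakvar.stats_report import (
    ModelSpec,
    StatsError,
    center_predictors,
    fit_mixed_model,
    likelihood_ratio_test,
    logit_to_odds_prob,
    null_spec,
    render_model_report,
    t_to_p,
)


def _binomial_table(seed=60, n_participants=24, trials=72, beta0=0.4, beta1=-0.5, sd=0.5):
    rng = np.random.default_rng(seed)
    rows = []
    u = rng.normal(0, sd, n_participants)
    for p in range(n_participants):
        x = np.repeat([0.5, -0.5], trials // 2)
        eta = beta0 + beta1 * x + u[p]
        y = (rng.random(trials) < expit(eta)).astype(int)
        for xi, yi in zip(x, y):
            rows.append({"participant": p, "x": xi, "y": yi})
    return pd.DataFrame(rows)


class TestCentering:
    def test_balanced_binary_becomes_half_codes(self):
        df = pd.DataFrame({"a": [0, 0, 1, 1], "b": [1.0, 2.0, 3.0, 4.0]})
        out = center_predictors(df, ["a"])
        assert sorted(out["a"].unique()) == [-0.5, 0.5]
        assert (out["b"] == df["b"]).all()

    def test_unbalanced_binary(self):
        df = pd.DataFrame({"a": [0, 0, 1]})
        out = center_predictors(df, ["a"])
        assert sorted(out["a"].round(6).unique()) == [round(-1 / 3, 6), round(2 / 3, 6)]

    def test_constant_column_rejected(self):
        with pytest.raises(StatsError, match="constant"):
            center_predictors(pd.DataFrame({"a": [1, 1, 1]}), ["a"])

    def test_interaction_terms_skipped(self):
        df = pd.DataFrame({"a": [0, 1], "b": [0, 1]})
        out = center_predictors(df, ["a", "b", "a:b"])
        assert set(out.columns) == {"a", "b"}


class TestConversions:
    def test_published_intercept_conversion(self):
        odds, prob = logit_to_odds_prob(0.343)
        assert odds == pytest.approx(1.41, abs=0.005)
        assert prob == pytest.approx(0.585, abs=0.002)

    def test_speaker_effect_conversion(self):
        odds, _ = logit_to_odds_prob(-0.439)
        assert 1 / odds == pytest.approx(1.55, abs=0.01)

    def test_zero_and_nonfinite(self):
        assert logit_to_odds_prob(0.0) == (1.0, 0.5)
        with pytest.raises(StatsError):
            logit_to_odds_prob(np.inf)

    def test_t_to_p(self):
        assert t_to_p(0.0, 100) == pytest.approx(1.0)
        assert t_to_p(1.984, 100) == pytest.approx(0.05, abs=2e-3)
        # for large df the t tail matches the normal tail
        assert t_to_p(2.0, 100_000) == pytest.approx(2 * norm.sf(2.0), abs=1e-4)
        with pytest.raises(StatsError):
            t_to_p(1.0, 0)


class TestGaussianFamily:
    def test_noiseless_recovery(self):
        # residual-free data are a degenerate boundary case for ML (scale -> 0),
        # so recovery is checked to 1e-3 rather than machine precision
        rows = []
        for p in range(12):
            off = 0.1 * (p - 5.5) / 11
            for x in (-0.5, 0.5):
                for _ in range(6):
                    rows.append({"participant": p, "x": x, "y": 0.7 + 0.2 * x + off})
        df = pd.DataFrame(rows)
        fit = fit_mixed_model(df, ModelSpec("y", "gaussian-identity", ("x",)))
        assert fit.beta("intercept") == pytest.approx(0.7, abs=1e-3)
        assert fit.beta("x") == pytest.approx(0.2, abs=1e-3)

    def test_noisy_recovery_and_df(self):
        rng = np.random.default_rng(62)
        rows = []
        u = rng.normal(0, 0.05, 20)
        for p in range(20):
            for rnd in range(1, 7):
                x = rnd - 3.5
                y = 0.6 + 0.06 * x + u[p] + rng.normal(0, 0.1)
                rows.append({"participant": p, "x": x, "y": y})
        df = pd.DataFrame(rows)
        fit = fit_mixed_model(df, ModelSpec("y", "gaussian-identity", ("x",)))
        assert fit.converged
        assert fit.beta("x") == pytest.approx(0.06, abs=0.02)
        assert fit.random_intercept_sd == pytest.approx(0.05, abs=0.05)
        # default t df = n_obs - n_fixed
        t = fit.coefficients["x"]["stat"]
        assert fit.coefficients["x"]["p"] == pytest.approx(t_to_p(t, 120 - 2))

    def test_maximal_slope_fallback_flagged_or_converged(self):
        df = _binomial_table(seed=63)
        df["y"] = df["y"].astype(float)
        fit = fit_mixed_model(
            df, ModelSpec("y", "gaussian-identity", ("x",), maximal=True)
        )
        assert fit.converged or any("maximal" in f for f in fit.flags)


class TestBinomialFamily:
    def test_intercept_only_matches_pooled_logit_with_zero_sd(self):
        # with participant_sd ~ 0 in the data the ML intercept approaches
        # the pooled empirical logit
        df = _binomial_table(seed=64, sd=0.0)
        fit = fit_mixed_model(df, ModelSpec("y", "binomial-logit"))
        pooled = logit(df["y"].mean())
        assert fit.beta("intercept") == pytest.approx(pooled, abs=2e-2)
        assert fit.random_intercept_sd < 0.15

    def test_parameter_recovery(self):
        df = _binomial_table(seed=65, n_participants=48)
        fit = fit_mixed_model(df, ModelSpec("y", "binomial-logit", ("x",)))
        assert fit.converged
        lo, hi = fit.ci95("x")
        assert lo < -0.5 < hi
        lo, hi = fit.ci95("intercept")
        assert lo < 0.4 < hi

    def test_matches_lme4(self, tmp_path):
        """Cross-validate the hand-rolled adaptive-quadrature fit against
        lme4's glmer (nAGQ=25) on the same data."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not on PATH")
        df = _binomial_table(seed=66, n_participants=16, trials=36)
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            textwrap.dedent(
                f"""
                suppressMessages(library(lme4))
                d <- read.csv("{csv}")
                m <- glmer(y ~ x + (1 | participant), data = d,
                           family = binomial, nAGQ = 25)
                co <- summary(m)$coefficients
                cat(co[1,1], co[1,2], co[2,1], co[2,2],
                    as.numeric(logLik(m)), sqrt(unlist(VarCorr(m))[1]), sep="\\n")
                """
            )
        )
        proc = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, timeout=300
        )
        if proc.returncode != 0:
            pytest.skip(f"lme4 unavailable: {proc.stderr[-200:]}")
        b0, se0, b1, se1, llf, sd = map(float, proc.stdout.split())
        fit = fit_mixed_model(df, ModelSpec("y", "binomial-logit", ("x",)))
        assert fit.beta("intercept") == pytest.approx(b0, abs=2e-3)
        assert fit.beta("x") == pytest.approx(b1, abs=2e-3)
        assert fit.se("intercept") == pytest.approx(se0, abs=5e-3)
        assert fit.se("x") == pytest.approx(se1, abs=5e-3)
        assert fit.llf == pytest.approx(llf, abs=5e-3)
        assert fit.random_intercept_sd == pytest.approx(sd, abs=2e-2)

    def test_constant_response_flagged(self):
        df = pd.DataFrame(
            {"participant": [0, 0, 1, 1], "x": [0.5, -0.5] * 2, "y": [1, 1, 1, 1]}
        )
        fit = fit_mixed_model(df, ModelSpec("y", "binomial-logit", ("x",)))
        assert not fit.converged
        assert any("separation" in f for f in fit.flags)

    def test_interaction_term(self):
        df = _binomial_table(seed=67)
        df["w"] = np.where(df["participant"] % 2 == 0, 0.5, -0.5)
        fit = fit_mixed_model(df, ModelSpec("y", "binomial-logit", ("x", "w", "x:w")))
        assert set(fit.coefficients) == {"intercept", "x", "w", "x:w"}
        assert fit.converged

    def test_missing_column_raises(self):
        df = _binomial_table(seed=68, n_participants=4, trials=8)
        with pytest.raises(StatsError, match="missing"):
            fit_mixed_model(df, ModelSpec("y", "binomial-logit", ("z",)))


class TestLRT:
    def test_null_spec_strips_fixed_effects(self):
        spec = ModelSpec("y", "binomial-logit", ("x", "x:w"), maximal=True)
        ns = null_spec(spec)
        assert ns.fixed_effects == () and not ns.maximal

    def test_lrt_null_distribution_behaviour(self):
        # with beta1 = 0 the LRT statistic should not be significant
        df = _binomial_table(seed=69, beta1=0.0)
        full = fit_mixed_model(df, ModelSpec("y", "binomial-logit", ("x",)))
        null = fit_mixed_model(df, null_spec(ModelSpec("y", "binomial-logit", ("x",))))
        chi_sq, dof, p = likelihood_ratio_test(full, null)
        assert dof == 1
        assert chi_sq >= 0.0
        assert p == pytest.approx(float(chi2.sf(chi_sq, 1)))

    def test_lrt_detects_real_effect(self):
        df = _binomial_table(seed=70, n_participants=48, beta1=-0.8)
        spec = ModelSpec("y", "binomial-logit", ("x",))
        full = fit_mixed_model(df, spec)
        null = fit_mixed_model(df, null_spec(spec))
        _, _, p = likelihood_ratio_test(full, null)
        assert p < 0.001

    def test_mismatched_models_rejected(self):
        df = _binomial_table(seed=71, n_participants=4, trials=8)
        fit = fit_mixed_model(df, ModelSpec("y", "binomial-logit", ("x",)))
        other = fit_mixed_model(df.iloc[:16], ModelSpec("y", "binomial-logit", ("x",)))
        with pytest.raises(StatsError, match="same observations"):
            likelihood_ratio_test(fit, other)


class TestReport:
    def test_render_contains_conversions(self):
        df = _binomial_table(seed=72)
        fit = fit_mixed_model(df, ModelSpec("y", "binomial-logit", ("x",)))
        null = fit_mixed_model(df, null_spec(ModelSpec("y", "binomial-logit", ("x",))))
        text = render_model_report(fit, likelihood_ratio_test(fit, null), "Demo")
        assert "Demo" in text
        assert "odds" in text and "accuracy" in text
        assert "vs null model" in text
        assert "intercept" in text
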