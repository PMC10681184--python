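"""Mixed-model engine: external oracle, closed forms, selection, outliers."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pcstroop import lmm


def crossed_data(seed=42, P=20, I=10, reps=4, sd_int=0.5, sd_slope=0.3,
                 sd_img=0.4, sd_e=1.0, beta=(1.0, 0.8)):
    rng = np.random.default_rng(seed)
    n = P * I * reps
    part = np.repeat(np.arange(P), I * reps)
    img = np.tile(np.repeat(np.arange(I), reps), P)
    x = rng.normal(size=n)
    bp = rng.normal(0, sd_int, P)
    sp = rng.normal(0, sd_slope, P)
    bi = rng.normal(0, sd_img, I)
    y = (beta[0] + beta[1] * x + bp[part] + sp[part] * x + bi[img]
         + rng.normal(0, sd_e, n))
    return pd.DataFrame({"y": y, "x": x, "participant": part, "image": img})


SPEC = lmm.ModelSpec(fixed=("1", "x"),
                     random={"participant": ("1", "x"), "image": ("1",)},
                     response="y")


class TestTermAlgebra:
    def test_term_columns_and_containment(self):
        assert lmm.term_columns("a:b:c") == ("a", "b", "c")
        assert lmm.term_columns("1") == ()
        assert lmm.term_contains("a:b", "a")
        assert not lmm.term_contains("a", "a:b")

    def test_expand_with_lower_order(self):
        out = lmm.expand_with_lower_order(["a:b"])
        assert out == ["a", "b", "a:b"]


class TestFitAgainstLme4:
    def test_matches_lme4_reml(self, tmp_path):
        """Crossed correlated-slope fit agrees with lme4 to tight tolerance."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        df = crossed_data()
        fit = lmm.fit_mixed_model(SPEC, df)
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- lmer(y ~ x + (1 + x | participant) + (1 | image), data = d)
            fe <- fixef(m)
            vc <- as.data.frame(VarCorr(m))
            cat(fe[1], fe[2], REMLcrit(m), sigma(m), "\\n")
        """)
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        b0, b1, remlcrit, sig = map(float, out.stdout.split())
        assert fit.fixef["1"] == pytest.approx(b0, abs=1e-4)
        assert fit.fixef["x"] == pytest.approx(b1, abs=1e-4)
        assert fit.deviance == pytest.approx(remlcrit, abs=1e-3)
        assert fit.sigma == pytest.approx(sig, abs=1e-4)

    def test_balanced_one_way_matches_anova_closed_form(self):
        """REML equals the method-of-moments ANOVA estimators when balanced."""
        rng = np.random.default_rng(7)
        G, m = 12, 15
        g = np.repeat(np.arange(G), m)
        y = 2.0 + rng.normal(0, 1.3, G)[g] + rng.normal(0, 0.8, G * m)
        df = pd.DataFrame({"y": y, "g": g})
        spec = lmm.ModelSpec(fixed=("1",), random={"g": ("1",)},
                             response="y")
        fit = lmm.fit_mixed_model(spec, df)
        means = df.groupby("g")["y"].mean()
        msb = m * np.var(means, ddof=1)
        msw = (df.groupby("g")["y"].var(ddof=1)).mean()
        assert fit.sigma ** 2 == pytest.approx(msw, rel=1e-6)
        assert fit.random_cov["g"].iloc[0, 0] == pytest.approx(
            (msb - msw) / m, rel=1e-5)
        # intercept equals the grand mean under balance
        assert fit.fixef["1"] == pytest.approx(df["y"].mean(), rel=1e-9)


class TestFitBehavior:
    def test_zero_random_effects_hit_boundary(self):
        df = crossed_data(sd_int=0.0, sd_slope=0.0, sd_img=0.0, seed=3)
        fit = lmm.fit_mixed_model(SPEC, df)
        for g, cov in fit.random_cov.items():
            assert np.all(np.diag(cov.to_numpy())
                          < 0.01 * fit.sigma ** 2)
        assert fit.boundary

    def test_row_order_invariance(self):
        df = crossed_data(seed=11)
        fit1 = lmm.fit_mixed_model(SPEC, df)
        shuffled = df.sample(frac=1.0, random_state=0).reset_index(drop=True)
        fit2 = lmm.fit_mixed_model(SPEC, shuffled)
        assert np.allclose(fit1.fixef, fit2.fixef, atol=1e-6)

    def test_ci_contains_estimate_and_r2_ordering(self):
        df = crossed_data(seed=9)
        fit = lmm.fit_mixed_model(SPEC, df)
        assert ((fit.params["ci_low"] <= fit.params["estimate"])
                & (fit.params["estimate"] <= fit.params["ci_high"])).all()
        r2m, r2c = lmm.variance_explained(fit)
        assert 0 <= r2m <= r2c <= 1

    def test_ml_loglik_ordering_full_vs_reduced(self):
        df = crossed_data(seed=21)
        full = lmm.fit_mixed_model(SPEC, df, method="ML")
        red = lmm.fit_mixed_model(
            lmm.ModelSpec(fixed=("1", "x"),
                          random={"participant": ("1",), "image": ("1",)},
                          response="y"), df, method="ML")
        assert full.loglik >= red.loglik - 1e-6

    def test_too_few_levels_rejected(self):
        df = crossed_data().assign(participant=0)
        with pytest.raises(ValueError):
            lmm.fit_mixed_model(SPEC, df)


class TestBackwardElimination:
    def test_null_slope_removed_and_marginality_respected(self):
        # z has no random slope and no fixed effect in the truth
        rng = np.random.default_rng(1700)
        df = crossed_data(seed=17)
        df["z"] = rng.normal(size=len(df))
        spec = lmm.ModelSpec(
            fixed=("1", "x", "z", "x:z"),
            random={"participant": ("1", "x", "z"), "image": ("1",)},
            response="y")
        final, log, cmp_ = lmm.backward_eliminate(spec, df)
        dropped_random = [e["term"] for e in log if e["kind"] == "random"]
        assert "z" in dropped_random
        assert "x" in final.random["participant"]
        # fixed x is protected by its surviving random slope and by x:z
        assert "x" in final.fixed
        assert cmp_.chi_square >= 0 and cmp_.df >= 1

    def test_replay_determinism(self):
        df = crossed_data(seed=23)
        spec = lmm.ModelSpec(fixed=("1", "x"),
                             random={"participant": ("1", "x"),
                                     "image": ("1",)}, response="y")
        a = lmm.backward_eliminate(spec, df)
        b = lmm.backward_eliminate(spec, df)
        assert a[0] == b[0]
        assert a[1] == b[1]


class TestOutlierRefit:
    def test_infinite_threshold_is_identity(self):
        df = crossed_data(seed=31)
        fit = lmm.fit_mixed_model(SPEC, df)
        same, frac = lmm.outlier_refit(fit, threshold=np.inf)
        assert frac == 0.0
        assert same is fit

    def test_gaussian_fraction_near_two_tailed_expectation(self):
        """~2 Phi(-2.5) = 1.24% of rows beyond 2.5 SD for Gaussian noise."""
        fracs = []
        for seed in (1, 2, 3):
            df = crossed_data(seed=seed, P=30, I=10, reps=6)
            fit = lmm.fit_mixed_model(SPEC, df)
            _, frac = lmm.outlier_refit(fit, threshold=2.5)
            fracs.append(frac)
        assert 0.005 <= np.mean(fracs) <= 0.03

    def test_second_pass_removes_no_more(self):
        df = crossed_data(seed=37)
        fit = lmm.fit_mixed_model(SPEC, df)
        refit, frac1 = lmm.outlier_refit(fit, threshold=2.5)
        _, frac2 = lmm.outlier_refit(refit, threshold=2.5)
        assert frac2 <= frac1


class TestVarianceExplained:
    def test_zero_random_variance_makes_marginal_equal_conditional(self):
        df = crossed_data(sd_int=0.0, sd_slope=0.0, sd_img=0.0, seed=41)
        fit = lmm.fit_mixed_model(SPEC, df)
        r2m, r2c = lmm.variance_explained(fit)
        assert r2c - r2m < 0.01

    def test_intercept_only_marginal_near_zero(self):
        df = crossed_data(seed=43)
        spec = lmm.ModelSpec(fixed=("1",),
                             random={"participant": ("1",)}, response="y")
        fit = lmm.fit_mixed_model(spec, df)
        r2m, r2c = lmm.variance_explained(fit)
        assert r2m == pytest.approx(0.0, abs=1e-8)
        assert r2c > 0.05
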