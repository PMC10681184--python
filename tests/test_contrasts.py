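"""Slope/marginal-mean contrasts and the Tukey adjustment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pcstroop import contrasts as ct
from pcstroop import lmm


@pytest.fixture(scope="module")
def slope_fit():
    """Data with a known congruency x lwpc x emotion fixed structure."""
    rng = np.random.default_rng(101)
    n_part, n_img, reps = 24, 8, 40
    n = n_part * reps
    part = np.repeat(np.arange(n_part), reps)
    img = rng.integers(0, n_img, n)
    con = rng.choice([-1.0, 1.0], n)
    emo = rng.choice([-1.0, 1.0], n)
    lwpc = rng.normal(size=n)
    beta = {"1": -2.3, "congruency": 0.2, "lwpc": 0.06, "emotion": 0.0,
            "congruency:lwpc": 0.05, "congruency:emotion": -0.003,
            "lwpc:emotion": 0.013, "congruency:lwpc:emotion": -0.008}
    y = (beta["1"] + beta["congruency"] * con + beta["lwpc"] * lwpc
         + beta["emotion"] * emo + beta["congruency:lwpc"] * con * lwpc
         + beta["congruency:emotion"] * con * emo
         + beta["lwpc:emotion"] * lwpc * emo
         + beta["congruency:lwpc:emotion"] * con * lwpc * emo
         + rng.normal(0, 0.15, n_part)[part] + rng.normal(0, 0.3, n))
    df = pd.DataFrame({"y": y, "congruency": con, "emotion": emo,
                       "lwpc": lwpc, "participant": part, "image": img})
    spec = lmm.ModelSpec(
        fixed=tuple(beta), random={"participant": ("1",), "image": ("1",)},
        response="y")
    return lmm.fit_mixed_model(spec, df), beta


class TestEstimateSlopes:
    def test_cell_slope_is_coding_algebra(self, slope_fit):
        fit, _ = slope_fit
        slopes = ct.estimate_slopes(fit, "lwpc",
                                    by={"congruency": [-1, 1],
                                        "emotion": [-1, 1]})
        b = fit.fixef
        cell = slopes[(slopes["congruency"] == -1)
                      & (slopes["emotion"] == 1)].iloc[0]
        expected = (b["lwpc"] - b["congruency:lwpc"] + b["lwpc:emotion"]
                    - b["congruency:lwpc:emotion"])
        assert cell["estimate"] == pytest.approx(expected, rel=1e-12)

    def test_no_interaction_model_gives_constant_slope(self):
        rng = np.random.default_rng(5)
        n = 400
        df = pd.DataFrame({
            "x": rng.normal(size=n), "f": rng.choice([-1.0, 1.0], n),
            "participant": rng.integers(0, 10, n)})
        df["y"] = 1 + 0.5 * df["x"] + rng.normal(0, 1, n)
        fit = lmm.fit_mixed_model(
            lmm.ModelSpec(fixed=("1", "x", "f"),
                          random={"participant": ("1",)}, response="y"), df)
        slopes = ct.estimate_slopes(fit, "x", by={"f": [-1, 1]})
        assert slopes["estimate"].nunique() == 1

    def test_simple_effect_family_has_four_contrasts(self, slope_fit):
        fit, _ = slope_fit
        slopes = ct.estimate_slopes(fit, "lwpc",
                                    by={"congruency": [-1, 1],
                                        "emotion": [-1, 1]})
        simple = ct.slope_contrasts(fit, slopes, family="simple",
                                    family_size=4)
        assert len(simple) == 4
        assert (simple["family_size"] == 4).all()
        full = ct.slope_contrasts(fit, slopes)
        assert len(full) == 6

    def test_missing_modifier_errors(self, slope_fit):
        fit, _ = slope_fit
        with pytest.raises(ValueError):
            ct.estimate_slopes(fit, "nope", by={"emotion": [-1, 1]})

    def test_slope_difference_pattern_recovered(self, slope_fit):
        """The sad-vs-neutral slope gap is wider in congruent cells (the
        generating three-way interaction's sign pattern)."""
        fit, beta = slope_fit
        slopes = ct.estimate_slopes(fit, "lwpc",
                                    by={"congruency": [-1, 1],
                                        "emotion": [-1, 1]})

        def slope(c, e):
            m = (slopes["congruency"] == c) & (slopes["emotion"] == e)
            return float(slopes.loc[m, "estimate"].iloc[0])

        gap_con = slope(-1, 1) - slope(-1, -1)
        gap_inc = slope(1, 1) - slope(1, -1)
        true_gap_con = 2 * (beta["lwpc:emotion"]
                            - beta["congruency:lwpc:emotion"])
        true_gap_inc = 2 * (beta["lwpc:emotion"]
                            + beta["congruency:lwpc:emotion"])
        assert true_gap_con > true_gap_inc  # generating pattern
        assert gap_con == pytest.approx(true_gap_con, abs=0.02)


class TestMarginalMeans:
    def test_eight_means_give_28_contrasts(self, slope_fit):
        fit, _ = slope_fit
        means = ct.marginal_means_at(fit, "lwpc", [-1.5, 1.5],
                                     by={"congruency": [-1, 1],
                                         "emotion": [-1, 1]})
        assert len(means) == 8
        pairs = ct.mean_contrasts(fit, means)
        assert len(pairs) == 28
        assert (pairs["family_size"] == 28).all()

    def test_intercept_only_means_all_equal(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame({"y": rng.normal(size=200), "x": 0.0,
                           "g": rng.integers(0, 8, 200)})
        df["x"] = rng.normal(size=200)
        fit = lmm.fit_mixed_model(
            lmm.ModelSpec(fixed=("1",), random={"g": ("1",)},
                          response="y"), df)
        means = ct.marginal_means_at(fit, "x", [0.0, 2.0], by={})
        assert means["estimate"].nunique() == 1

    def test_means_affine_in_modifier(self, slope_fit):
        fit, _ = slope_fit
        means = ct.marginal_means_at(fit, "lwpc", [-1.0, 0.0, 1.0],
                                     by={"congruency": [-1, 1],
                                         "emotion": [-1, 1]})
        for (_, _), grp in means.groupby(["congruency", "emotion"]):
            vals = grp.sort_values("lwpc")["estimate"].to_numpy()
            assert vals[2] - vals[1] == pytest.approx(vals[1] - vals[0],
                                                      rel=1e-9)

    def test_extrapolation_warns(self, slope_fit):
        fit, _ = slope_fit
        with pytest.warns(UserWarning):
            ct.marginal_means_at(fit, "lwpc", [10.0], by={},
                                 observed_range=(-3.0, 3.0))


class TestTukeyAdjust:
    def test_k1_identity(self):
        z = 1.96
        assert ct.tukey_adjust(z, k=1)[0] == pytest.approx(
            2 * stats.norm.sf(z), abs=1e-4)

    def test_monotone_in_family_size(self):
        z = 2.1
        ps = [ct.tukey_adjust(z, k=k)[0] for k in (1, 2, 4, 6, 10, 28)]
        assert np.all(np.diff(ps) >= -1e-12)
        assert all(0 <= p <= 1 for p in ps)

    def test_adjusted_geq_unadjusted(self):
        z = np.array([0.5, 1.5, 2.5, 3.5])
        padj = ct.tukey_adjust(z, k=28)
        punadj = 2 * stats.norm.sf(np.abs(z))
        assert (padj >= punadj - 1e-12).all()

    def test_family_smaller_than_statistics_errors(self):
        with pytest.raises(ValueError):
            ct.tukey_adjust([1.0, 2.0, 3.0], k=2)

    def test_monte_carlo_oracle_k28(self):
        """Studentized-range tail matches a multivariate-normal simulation
        of the max over 28 pairwise comparisons of 8 means."""
        p_sr = ct.tukey_adjust(1.96, k=28)[0]
        rng = np.random.default_rng(12345)
        zs = rng.standard_normal((10 ** 6, 8))
        qmax = (zs.max(axis=1) - zs.min(axis=1)) / np.sqrt(2.0)
        p_mc = float((qmax > 1.96).mean())
        assert p_sr == pytest.approx(p_mc, abs=5e-3)
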