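"""Belief-tracker correctness against an independent transcription oracle."""

import math

import numpy as np
import pytest

from pcstroop import hgf
from pcstroop.design import TrialList


def oracle_update(mu2, s2, mu3, s3, u, kappa, omega, theta):
    """Independent line-by-line transcription of the binary HGF update.

    Kept deliberately separate from the implementation (different variable
    naming and expression grouping) so it can serve as an oracle.
    """
    muhat1 = 1.0 / (1.0 + math.exp(-mu2))
    delta1 = u - muhat1
    expv = math.exp(kappa * mu3 + omega)
    sigmahat2 = s2 + expv
    precision2 = 1.0 / sigmahat2 + muhat1 * (1.0 - muhat1)
    mu2_post = mu2 + delta1 / precision2
    s2_post = 1.0 / precision2
    delta2 = (s2_post + (mu2_post - mu2) ** 2) / sigmahat2 - 1.0
    pihat3 = 1.0 / (s3 + theta)
    w2 = expv / sigmahat2
    r2 = (expv - s2) / sigmahat2
    precision3 = pihat3 + 0.5 * kappa ** 2 * w2 * (w2 + r2 * delta2)
    assert precision3 > 0
    mu3_post = mu3 + 0.5 * kappa * w2 * delta2 / precision3
    return mu2_post, s2_post, mu3_post, 1.0 / precision3


class TestUpdateEquations:
    def test_prior_prediction_is_half(self):
        params = hgf.HGFParams(mu2_0=0.0)
        assert hgf.initial_state(params).prediction == 0.5

    @pytest.mark.parametrize("u,direction", [(1, 1), (0, -1)])
    def test_update_moves_tendency_toward_observation(self, u, direction):
        params = hgf.HGFParams()
        state = hgf.initial_state(params)
        new = hgf.hgf_update(state, u, params)
        assert np.sign(new.mu2 - state.mu2) == direction
        assert new.sigma2 > 0 and new.sigma3 > 0
        assert 0 < new.prediction < 1

    def test_oracle_equivalence_short_sequences(self):
        """Filter matches the independent equation transcription to 1e-12."""
        params = hgf.HGFParams(kappa=1.3, omega=-4.0, theta=0.1,
                               mu2_0=0.2, sigma2_0=1.5, mu3_0=0.5,
                               sigma3_0=0.8)
        rng = np.random.default_rng(2024)
        for _ in range(20):
            seq = rng.integers(0, 2, size=rng.integers(1, 11))
            state = hgf.initial_state(params)
            ostate = (params.mu2_0, params.sigma2_0,
                      params.mu3_0, params.sigma3_0)
            for u in seq:
                state = hgf.hgf_update(state, int(u), params)
                ostate = oracle_update(*ostate, int(u), params.kappa,
                                       params.omega, params.theta)
                assert state.mu2 == pytest.approx(ostate[0], abs=1e-12)
                assert state.sigma2 == pytest.approx(ostate[1], abs=1e-12)
                assert state.mu3 == pytest.approx(ostate[2], abs=1e-12)
                assert state.sigma3 == pytest.approx(ostate[3], abs=1e-12)

    def test_frozen_three_step_trajectory(self):
        """Regression freeze of one (1, 1, 0) trajectory, oracle-derived."""
        params = hgf.HGFParams(kappa=1.0, omega=-2.0, theta=0.5,
                               mu2_0=0.0, sigma2_0=1.0, mu3_0=1.0,
                               sigma3_0=1.0)
        state = hgf.initial_state(params)
        ostate = (0.0, 1.0, 1.0, 1.0)
        for u in (1, 1, 0):
            state = hgf.hgf_update(state, u, params)
            ostate = oracle_update(*ostate, u, 1.0, -2.0, 0.5)
        assert state.mu2 == pytest.approx(ostate[0], abs=1e-12)
        # frozen values from the oracle transcription
        assert state.mu2 == pytest.approx(0.1296469832855741, abs=1e-9)
        assert state.sigma2 == pytest.approx(1.0852066200112251, abs=1e-9)
        assert state.mu3 == pytest.approx(1.0124546237862597, abs=1e-9)
        assert state.sigma3 == pytest.approx(2.1752730528834467, abs=1e-9)

    def test_unstable_regime_raises(self):
        params = hgf.HGFParams(kappa=1.5, omega=1.0, theta=2.0,
                               mu3_0=2.0, sigma3_0=2.0)
        state = hgf.initial_state(params)
        with pytest.raises((hgf.HGFError, OverflowError)):
            rng = np.random.default_rng(0)
            for _ in range(2000):
                state = hgf.hgf_update(state, int(rng.integers(0, 2)),
                                       params)


class TestTrackSequence:
    def test_constant_input_monotone(self):
        preds = hgf.track_binary_sequence([1] * 30)
        assert np.all(np.diff(preds) >= -1e-12)
        assert preds[0] == 0.5

    def test_first_prediction_is_prior(self):
        params = hgf.HGFParams(mu2_0=0.7)
        preds = hgf.track_binary_sequence([0, 1, 0], params)
        assert preds[0] == pytest.approx(1 / (1 + np.exp(-0.7)))

    def test_stationary_bernoulli_converges(self):
        """Terminal belief tracks a stationary Bernoulli(.75) source."""
        for seed in range(10):
            rng = np.random.default_rng(seed)
            u = (rng.random(500) < 0.75).astype(int)
            preds = hgf.track_binary_sequence(u)
            assert abs(preds[-1] - 0.75) < 0.1

    def test_fixed_volatility_limit(self):
        """theta = 0 with a tight level-3 prior freezes the volatility belief,
        reducing the filter to a constant-volatility tracker whose
        effective learning rate settles after burn-in."""
        params = hgf.HGFParams(theta=0.0, sigma3_0=1e-12, mu3_0=0.0)
        rng = np.random.default_rng(3)
        u = rng.integers(0, 2, 400)
        state = hgf.initial_state(params)
        lrs = []
        for ui in u:
            prev_mu2, phat = state.mu2, state.prediction
            state = hgf.hgf_update(state, int(ui), params)
            d1 = ui - phat
            if abs(d1) > 1e-9:
                lrs.append((state.mu2 - prev_mu2) / d1)
        # level-3 belief is pinned: the volatility increment is constant
        assert abs(state.mu3 - params.mu3_0) < 1e-6
        # and the implied learning rate stabilizes after burn-in
        tail = np.array(lrs[200:])
        assert np.ptp(tail) < 1e-3


class TestTrialwisePredictors:
    def test_first_trial_at_prior(self, trial_list):
        params = hgf.HGFParams(mu2_0=0.3)
        tab = hgf.trialwise_predictors(trial_list, params)
        for col in ("lwpc", "ispc", "prs", "pr", "pl"):
            assert tab[f"{col}_logit"].iloc[0] == pytest.approx(0.3)

    def test_unseen_location_stays_at_prior(self):
        # location 2 first appears at trial 3
        tl = TrialList(block=np.array([1, 1, 1, 1]),
                       location=np.array([0, 1, 0, 2]),
                       direction=np.array([1, 0, 3, 2]), seed=0)
        tab = hgf.trialwise_predictors(tl, hgf.HGFParams(mu2_0=0.0),
                                       columns=("ispc",))
        assert tab["ispc_logit"].iloc[3] == 0.0

    def test_probabilities_strictly_inside_unit_interval(self, beliefs):
        probs = beliefs[[c for c in beliefs.columns if c.endswith("_prob")]]
        assert (probs.to_numpy() > 0).all() and (probs.to_numpy() < 1).all()
        logits = beliefs[[c for c in beliefs.columns if c.endswith("_logit")]]
        assert np.isfinite(logits.to_numpy()).all()

    def test_lwpc_tracks_blockwise_level(self, design, trial_list, beliefs):
        blockwise = np.repeat(design.lwpc(), design.trials_per_block)
        r = np.corrcoef(beliefs["lwpc_prob"], blockwise)[0, 1]
        assert r > 0.5

    def test_posterior_flag_shifts_by_one(self, trial_list):
        params = hgf.HGFParams()
        pred = hgf.trialwise_predictors(trial_list, params,
                                        columns=("lwpc",))
        post = hgf.trialwise_predictors(trial_list, params,
                                        columns=("lwpc",),
                                        use_posterior=True)
        assert np.allclose(pred["lwpc_logit"].to_numpy()[1:],
                           post["lwpc_logit"].to_numpy()[:-1])

    def test_renormalized_one_vs_rest_sums_to_one(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.05, 0.95, size=(30, 4))
        assert np.allclose(hgf.renormalized_distribution(p).sum(axis=1), 1.0)
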