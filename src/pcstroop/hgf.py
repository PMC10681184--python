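"""Three-level binary Hierarchical Gaussian Filter (HGF).

The HGF is a variational-Bayes observer model for a binary sequence whose
hidden probability drifts over time.  Level 1 is the observed binary input;
level 2 a Gaussian random walk on the log-odds (tendency) of the input; and
level 3 a Gaussian random walk on the log-volatility of level 2.  Under a
mean-field approximation the posterior over each level stays Gaussian, and
the per-trial update is a precision-weighted prediction-error step — a
Bayesian generalization of Rescorla-Wagner learning with a dynamic learning
rate.

Here the filter serves as an ideal-observer device: it converts the binary
congruency / direction / location streams of a trial list into trial-wise
probability beliefs (one-step-ahead predictions on the logit scale) used as
continuous regressors, replacing block-wise constant proportions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .design import TrialList


class HGFError(RuntimeError):
    """Raised when an update produces an invalid (non-positive) precision."""


@dataclass(frozen=True)
class HGFParams:
    """Perceptual parameters of the 3-level binary HGF.

    kappa
        Coupling strength between level 3 and the level-2 volatility
        (dimensionless, > 0).
    omega
        Tonic log-volatility of the level-2 random walk.
    theta
        Innovation variance of the level-3 random walk (>= 0).
    mu2_0, sigma2_0
        Prior mean and variance of the level-2 tendency (logit scale).
    mu3_0, sigma3_0
        Prior mean and variance of the level-3 log-volatility.
    """

    kappa: float = 1.0
    omega: float = -6.0
    theta: float = 0.05
    mu2_0: float = 0.0
    sigma2_0: float = 1.0
    mu3_0: float = 0.0
    sigma3_0: float = 1.0

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.theta < 0:
            raise ValueError("theta must be non-negative")
        if self.sigma2_0 <= 0 or self.sigma3_0 <= 0:
            raise ValueError("prior variances must be positive")


@dataclass(frozen=True)
class HGFState:
    """Posterior state after ``trial_count`` observations."""

    mu2: float
    sigma2: float
    mu3: float
    sigma3: float
    trial_count: int = 0

    @property
    def prediction(self) -> float:
        """One-step-ahead probability that the next input is 1."""
        return sigmoid(self.mu2)


def sigmoid(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    z = math.exp(x)
    return z / (1.0 + z)


def logit(p: float) -> float:
    if not 0.0 < p < 1.0:
        raise ValueError("logit requires p strictly in (0, 1)")
    return math.log(p / (1.0 - p))


def initial_state(params: HGFParams) -> HGFState:
    return HGFState(mu2=params.mu2_0, sigma2=params.sigma2_0,
                    mu3=params.mu3_0, sigma3=params.sigma3_0, trial_count=0)


def hgf_update(state: HGFState, u: int, params: HGFParams) -> HGFState:
    """One variational update of the 3-level binary HGF.

    Level 1 prediction is ``sigmoid(mu2)``; the level-2 step adds the
    prediction error over the posterior precision (informational + predicted
    random-walk variance); the level-3 step corrects the log-volatility
    belief by the volatility prediction error ``d2`` weighted by ``w2``, the
    share of level-2 predicted variance attributable to volatility.
    """
    if u not in (0, 1):
        raise ValueError("input u must be binary (0 or 1)")

    mu2, sigma2, mu3, sigma3 = state.mu2, state.sigma2, state.mu3, state.sigma3
    kappa, omega, theta = params.kappa, params.omega, params.theta

    # level 1 / 2
    phat = sigmoid(mu2)
    d1 = u - phat
    ev = math.exp(kappa * mu3 + omega)        # predicted volatility increment
    v = sigma2 + ev                           # predicted level-2 variance
    pi2 = 1.0 / v + phat * (1.0 - phat)       # posterior level-2 precision
    mu2_new = mu2 + d1 / pi2
    sigma2_new = 1.0 / pi2

    # volatility prediction error
    dmu2 = mu2_new - mu2
    d2 = (sigma2_new + dmu2 * dmu2) / v - 1.0

    # level 3
    sigma3hat = sigma3 + theta
    w2 = ev / v
    r2 = (ev - sigma2) / v
    pi3 = 1.0 / sigma3hat + 0.5 * kappa * kappa * w2 * (w2 + r2 * d2)
    if pi3 <= 0.0:
        raise HGFError(
            "negative level-3 posterior precision; the parameter regime "
            f"(kappa={kappa}, omega={omega}, theta={theta}) is unstable here")
    mu3_new = mu3 + 0.5 * (kappa / pi3) * w2 * d2
    sigma3_new = 1.0 / pi3

    return HGFState(mu2=mu2_new, sigma2=sigma2_new, mu3=mu3_new,
                    sigma3=sigma3_new, trial_count=state.trial_count + 1)


def track_binary_sequence(inputs: Iterable[int],
                          params: HGFParams | None = None,
                          use_posterior: bool = False) -> np.ndarray:
    """Trial-wise tracked probabilities for one binary sequence.

    Element ``k`` is the one-step-ahead prediction ``sigmoid(mu2)`` held
    *before* observing input ``k`` (so element 0 is the prior belief).
    With ``use_posterior=True`` the belief *after* the update is returned
    instead.
    """
    params = params or HGFParams()
    inputs = list(inputs)
    if not inputs:
        raise ValueError("inputs must be non-empty")
    state = initial_state(params)
    out = np.empty(len(inputs))
    for k, u in enumerate(inputs):
        if not use_posterior:
            out[k] = state.prediction
        state = hgf_update(state, int(u), params)
        if use_posterior:
            out[k] = state.prediction
    return out


# ---------------------------------------------------------------------------
# Trial-wise predictors for a trial list
# ---------------------------------------------------------------------------

#: Belief columns the tracker can produce.
PREDICTORS = ("lwpc", "ispc", "prs", "pr", "pl")


def trialwise_predictors(trials: TrialList,
                         params: HGFParams | None = None,
                         columns: Sequence[str] = PREDICTORS,
                         use_posterior: bool = False) -> pd.DataFrame:
    """Belief table for a trial list (one row per trial).

    Five predictor families, each tracked by independent binary HGFs:

    - ``lwpc``: one tracker over the congruency stream of all trials;
    - ``ispc``: one tracker per location over that location's congruency
      stream, read from the current trial's location;
    - ``prs``: per location, four one-vs-rest trackers over direction
      identity, read for the actual direction (the contingency belief);
    - ``pr`` / ``pl``: four one-vs-rest trackers over direction / location
      across all trials, read for the actual direction / location.

    All values are reported on the logit (natural log-odds) scale together
    with probability-scale twins.  By default each predictor is the
    one-step-ahead prediction, i.e. the belief held *before* the current
    trial's outcome is seen.
    """
    params = params or HGFParams()
    unknown = set(columns) - set(PREDICTORS)
    if unknown:
        raise ValueError(f"unknown predictor columns: {sorted(unknown)}")
    n = len(trials)
    loc = trials.location
    drc = trials.direction
    con = trials.congruent

    kappa, omega, theta = params.kappa, params.omega, params.theta
    prior = (params.mu2_0, params.sigma2_0, params.mu3_0, params.sigma3_0)

    def update(st: tuple, u: int) -> tuple:
        mu2, sigma2, mu3, sigma3 = st
        phat = sigmoid(mu2)
        ev = math.exp(kappa * mu3 + omega)
        v = sigma2 + ev
        pi2 = 1.0 / v + phat * (1.0 - phat)
        mu2n = mu2 + (u - phat) / pi2
        s2n = 1.0 / pi2
        dmu2 = mu2n - mu2
        d2 = (s2n + dmu2 * dmu2) / v - 1.0
        w2 = ev / v
        r2 = (ev - sigma2) / v
        pi3 = 1.0 / (sigma3 + theta) + 0.5 * kappa * kappa * w2 * (w2 + r2 * d2)
        if pi3 <= 0.0:
            raise HGFError("negative level-3 posterior precision")
        return (mu2n, s2n, mu3 + 0.5 * (kappa / pi3) * w2 * d2, 1.0 / pi3)

    want = {c: c in columns for c in PREDICTORS}
    out: dict[str, np.ndarray] = {c: np.empty(n) for c in columns}

    st_lwpc = prior
    st_ispc = [prior] * 4
    st_prs = [[prior] * 4 for _ in range(4)]   # [location][direction]
    st_pr = [prior] * 4
    st_pl = [prior] * 4

    for k in range(n):
        L, D, C = int(loc[k]), int(drc[k]), int(con[k])
        if want["lwpc"]:
            if not use_posterior:
                out["lwpc"][k] = st_lwpc[0]
            st_lwpc = update(st_lwpc, C)
            if use_posterior:
                out["lwpc"][k] = st_lwpc[0]
        if want["ispc"]:
            if not use_posterior:
                out["ispc"][k] = st_ispc[L][0]
            st_ispc[L] = update(st_ispc[L], C)
            if use_posterior:
                out["ispc"][k] = st_ispc[L][0]
        if want["prs"]:
            if not use_posterior:
                out["prs"][k] = st_prs[L][D][0]
            row = st_prs[L]
            for d in range(4):
                row[d] = update(row[d], 1 if d == D else 0)
            if use_posterior:
                out["prs"][k] = st_prs[L][D][0]
        if want["pr"]:
            if not use_posterior:
                out["pr"][k] = st_pr[D][0]
            for d in range(4):
                st_pr[d] = update(st_pr[d], 1 if d == D else 0)
            if use_posterior:
                out["pr"][k] = st_pr[D][0]
        if want["pl"]:
            if not use_posterior:
                out["pl"][k] = st_pl[L][0]
            for l in range(4):
                st_pl[l] = update(st_pl[l], 1 if l == L else 0)
            if use_posterior:
                out["pl"][k] = st_pl[L][0]

    table = {}
    for c in columns:
        table[f"{c}_logit"] = out[c]
        table[f"{c}_prob"] = 1.0 / (1.0 + np.exp(-out[c]))
    return pd.DataFrame(table)


def renormalized_distribution(one_vs_rest_probs: np.ndarray) -> np.ndarray:
    """Turn one-vs-rest probabilities into a proper distribution.

    Each row of independent one-vs-rest beliefs is divided by its sum, so
    rows sum to one exactly by construction.
    """
    p = np.asarray(one_vs_rest_probs, dtype=float)
    return p / p.sum(axis=-1, keepdims=True)
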