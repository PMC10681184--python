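"""Power analysis for fully-crossed participant x stimulus designs.

Implements the noncentral-t power computation for a standardized mean
difference in a design where every participant responds to every stimulus
and stimuli appear in both conditions (counterbalanced), in the style of
Westfall, Kenny & Judd's variance-partitioning approach: all random-effect
variances are expressed as proportions of the total outcome variance
(variance partitioning coefficients, VPCs), the standardized effect d is
divided by the standard error implied by those components, and power is
evaluated from the noncentral t with Satterthwaite-style effective degrees
of freedom.  Also provides the minimal detectable effect (inverse power),
conversions among d, f and partial eta squared, and the repeated-measures
ANOVA sensitivity solve used to cross-reference the crossed-design result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

#: Order of the VPC components.
VPC_KEYS = ("participant_intercept", "stimulus_intercept",
            "participant_slope", "stimulus_slope",
            "participant_stimulus", "residual")


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of the crossed-design power computation.

    ``vpc`` holds the six variance partitioning coefficients in
    :data:`VPC_KEYS` order; they must be non-negative and sum to one.
    ``design='counterbalanced'`` means each stimulus is seen by every
    participant and appears in both conditions (so intercept variances
    cancel from the condition contrast); ``'stimuli_within_condition'``
    nests stimuli in conditions, leaving stimulus intercept variance in
    the contrast.
    """

    d: float
    p: int
    q: int
    vpc: tuple = (0.1, 0.1, 0.2, 0.0, 0.0, 0.6)
    alpha: float = 0.05
    design: str = "counterbalanced"

    def __post_init__(self) -> None:
        v = np.asarray(self.vpc, dtype=float)
        if v.shape != (6,) or (v < 0).any():
            raise ValueError("vpc needs six non-negative components")
        if abs(v.sum() - 1.0) > 1e-9:
            raise ValueError("vpc components must sum to 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.design not in ("counterbalanced", "stimuli_within_condition"):
            raise ValueError(f"unknown design {self.design!r}")
        if self.p < 2 or self.q < 2:
            raise ValueError("need at least 2 participants and 2 stimuli")


def _variance_terms(spec: PowerSpec) -> list[tuple[float, float]]:
    """(variance contribution, df) pairs of the effect-estimate variance.

    In VPC units, the condition-difference estimate has variance
    ``2 V_ps / p + 2 V_ss / q + 4 (V_pxs + V_e) / (p q)`` for the
    counterbalanced design; participant intercepts always cancel (both
    conditions within participant) and stimulus intercepts cancel only
    under counterbalancing — with stimuli nested in conditions they add
    ``4 V_si / q``.
    """
    v = dict(zip(VPC_KEYS, spec.vpc))
    p, q = spec.p, spec.q
    terms = [
        (2.0 * v["participant_slope"] / p, p - 1),
        (2.0 * v["stimulus_slope"] / q, q - 1),
        (4.0 * (v["participant_stimulus"] + v["residual"]) / (p * q),
         (p - 1) * (q - 1)),
    ]
    if spec.design == "stimuli_within_condition":
        terms.append((4.0 * v["stimulus_intercept"] / q, q - 2))
    return [(var, df) for var, df in terms if var > 0]


def crossed_power(spec: PowerSpec) -> float:
    """Two-tailed power for the condition contrast in the crossed design."""
    terms = _variance_terms(spec)
    if not terms:
        raise ValueError("all relevant variance components are zero")
    var = sum(t[0] for t in terms)
    # Satterthwaite effective df of the variance estimate
    df = var ** 2 / sum(t[0] ** 2 / t[1] for t in terms)
    ncp = spec.d / np.sqrt(var)
    tcrit = stats.t.ppf(1.0 - spec.alpha / 2.0, df)
    return float(stats.nct.sf(tcrit, df, ncp)
                 + stats.nct.cdf(-tcrit, df, ncp))


def minimal_detectable_effect(spec: PowerSpec, target_power: float = 0.8,
                              tol: float = 1e-6) -> float:
    """Smallest d reaching ``target_power``, by bisection on d."""
    if not spec.alpha < target_power < 1.0:
        raise ValueError("target power must lie in (alpha, 1)")

    def gap(d: float) -> float:
        return crossed_power(PowerSpec(d=d, p=spec.p, q=spec.q, vpc=spec.vpc,
                                       alpha=spec.alpha,
                                       design=spec.design)) - target_power

    hi = 0.1
    while gap(hi) < 0:
        hi *= 2.0
        if hi > 1e3:
            raise ValueError("target power unattainable for this design")
    return float(optimize.brentq(gap, 1e-12, hi, xtol=tol))


# ---------------------------------------------------------------------------
# Effect-size conversions
# ---------------------------------------------------------------------------

def effect_size_convert(value: float, source: str, target: str) -> float:
    """Convert among d, f and partial eta squared for a two-level contrast.

    Uses f = d/2 and eta_p2 = f^2 / (1 + f^2); inverse maps accordingly.
    Rounding is left to presentation.
    """
    kinds = ("d", "f", "eta_p2")
    if source not in kinds or target not in kinds:
        raise ValueError(f"source/target must be one of {kinds}")
    if source in ("d", "f") and value < 0:
        raise ValueError("d and f must be non-negative")
    if source == "eta_p2" and not 0.0 <= value < 1.0:
        raise ValueError("eta_p2 must lie in [0, 1)")
    # to f
    if source == "d":
        f = value / 2.0
    elif source == "f":
        f = value
    else:
        f = float(np.sqrt(value / (1.0 - value)))
    # from f
    if target == "d":
        return 2.0 * f
    if target == "f":
        return f
    return f * f / (1.0 + f * f)


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA sensitivity
# ---------------------------------------------------------------------------

def rm_anova_power(f: float, n: int, m: int, rho: float,
                   alpha: float = 0.05) -> float:
    """Power of the within-factor F test in a one-group rm-ANOVA.

    Noncentrality ``lambda = f^2 n m / (1 - rho)`` with ``df1 = m - 1`` and
    ``df2 = (m - 1)(n - 1)`` (the G*Power convention with the
    nonsphericity correction at 1).
    """
    if n < 2 or m < 2:
        raise ValueError("need n >= 2 subjects and m >= 2 measurements")
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must lie in [0, 1)")
    lam = f * f * n * m / (1.0 - rho)
    df1, df2 = m - 1, (m - 1) * (n - 1)
    fcrit = stats.f.ppf(1.0 - alpha, df1, df2)
    return float(stats.ncf.sf(fcrit, df1, df2, lam))


def rm_anova_sensitivity(n: int, m: int, rho: float, alpha: float = 0.05,
                         target_power: float = 0.8, tol: float = 1e-6) -> float:
    """Effect size f detectable at ``target_power`` in a rm-ANOVA."""
    if not alpha < target_power < 1.0:
        raise ValueError("target power must lie in (alpha, 1)")

    def gap(f: float) -> float:
        return rm_anova_power(f, n, m, rho, alpha) - target_power

    hi = 0.05
    while gap(hi) < 0:
        hi *= 2.0
        if hi > 1e3:
            raise ValueError("target power unattainable")
    return float(optimize.brentq(gap, 1e-12, hi, xtol=tol))
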