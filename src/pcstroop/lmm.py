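"""Linear mixed models with crossed, correlated random effects.

Fits the Gaussian LMM

    y = X beta + Z b + e,   b ~ N(0, Sigma),  e ~ N(0, sigma^2 I)

by profiled (RE)ML over a Cholesky-parameterized relative covariance
factor, the same formulation used by lme4: with ``Sigma = sigma^2 *
Lambda(theta) Lambda(theta)'`` and spherical ``u`` such that ``b = Lambda
u``, the deviance can be evaluated for any ``theta`` by one penalized
least-squares solve, and both ``beta`` and ``sigma^2`` profile out.  The
optimizer then searches only the covariance parameters.

Grouping factors may be crossed (e.g. participants x stimulus images);
each factor carries an arbitrary list of terms (intercept, slopes and
interaction slopes) with a fully correlated covariance block.

Wald inference with a normal approximation for the fixed effects (the
degrees-of-freedom method is labeled in the output), likelihood-ratio
model comparison, backward elimination of random then fixed terms,
standardized-residual outlier removal with a single refit, and a
Nakagawa-style marginal / conditional R^2 decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.optimize
import scipy.sparse as sp
from scipy import stats


class ConvergenceError(RuntimeError):
    """Raised when the deviance optimizer fails to converge."""


# ---------------------------------------------------------------------------
# Model specification
# ---------------------------------------------------------------------------

def term_columns(term: str) -> tuple[str, ...]:
    """Split a canonical ``A:B:C`` interaction term into its columns."""
    return tuple(term.split(":")) if term != "1" else ()


def term_contains(big: str, small: str) -> bool:
    """True when ``small``'s columns are a strict subset of ``big``'s."""
    a, b = set(term_columns(big)), set(term_columns(small))
    return b < a


def build_term_column(data: pd.DataFrame, term: str) -> np.ndarray:
    """Evaluate one model term (``1`` or a product of numeric columns)."""
    if term == "1":
        return np.ones(len(data))
    cols = term_columns(term)
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise KeyError(f"term {term!r}: missing columns {missing}")
    out = np.ones(len(data))
    for c in cols:
        out = out * data[c].to_numpy(float)
    return out


def expand_with_lower_order(terms: list[str]) -> list[str]:
    """Close a term list under marginality (interactions imply mains)."""
    from itertools import combinations

    seen: dict[str, None] = {}
    for t in terms:
        cols = term_columns(t)
        # all non-empty subsets, lowest order first
        for size in range(1, len(cols) + 1):
            for sub in combinations(cols, size):
                seen[":".join(sub)] = None
        if t == "1":
            seen["1"] = None
    ordered = sorted(seen, key=lambda s: (len(term_columns(s)), s))
    return ordered


@dataclass(frozen=True)
class ModelSpec:
    """Fixed terms plus per-grouping-factor random terms.

    ``random`` maps a grouping column name to the list of terms that get
    correlated random coefficients for that factor, e.g.
    ``{"participant": ["1", "congruency"], "image": ["1"]}``.
    Interaction terms use the canonical ``A:B`` colon syntax; ``"1"`` is
    the intercept.
    """

    fixed: tuple[str, ...]
    random: dict[str, tuple[str, ...]]
    response: str = "irt"

    def __post_init__(self) -> None:
        object.__setattr__(self, "fixed", tuple(self.fixed))
        object.__setattr__(
            self, "random", {g: tuple(ts) for g, ts in self.random.items()})

    def n_cov_params(self) -> int:
        return sum(k * (k + 1) // 2 for k in
                   (len(ts) for ts in self.random.values()))

    def drop_random(self, group: str, term: str) -> "ModelSpec":
        terms = tuple(t for t in self.random[group] if t != term)
        random = {g: (terms if g == group else ts)
                  for g, ts in self.random.items() if g != group or terms}
        return replace(self, random=random)

    def drop_fixed(self, term: str) -> "ModelSpec":
        return replace(self, fixed=tuple(t for t in self.fixed if t != term))


# ---------------------------------------------------------------------------
# Profiled deviance machinery
# ---------------------------------------------------------------------------

class _PLS:
    """Cross-product matrices and the penalized least-squares solve."""

    def __init__(self, spec: ModelSpec, data: pd.DataFrame):
        self.spec = spec
        self.n = len(data)
        y = data[spec.response].to_numpy(float)
        X = np.column_stack([build_term_column(data, t) for t in spec.fixed])
        self.p = X.shape[1]

        # random-effects design, one block of columns per grouping factor
        blocks = []
        self.group_info: list[tuple[str, int, int]] = []  # (name, levels, k)
        self.level_index: dict[str, pd.Index] = {}
        for g, terms in spec.random.items():
            codes, levels = pd.factorize(data[g], sort=True)
            k = len(terms)
            m = len(levels)
            vals = np.column_stack([build_term_column(data, t) for t in terms])
            rows = np.repeat(np.arange(self.n), k)
            cols = (codes[:, None] * k + np.arange(k)[None, :]).ravel()
            blocks.append(sp.csr_matrix((vals.ravel(), (rows, cols)),
                                        shape=(self.n, m * k)))
            self.group_info.append((g, m, k))
            self.level_index[g] = levels
        Z = sp.hstack(blocks, format="csr") if blocks else sp.csr_matrix((self.n, 0))
        self.q = Z.shape[1]

        self.X, self.y, self.Z = X, y, Z
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.ZtZ = np.asarray((Z.T @ Z).todense())
        self.ZtX = np.asarray(Z.T @ X) if self.q else np.zeros((0, self.p))
        self.Zty = np.asarray(Z.T @ y)

    # -- theta layout: per group, the lower triangle of T (column-major
    #    within rows), diagonal entries first within each row's slice.
    def theta_template(self) -> tuple[np.ndarray, list[tuple[float, float]]]:
        theta0, bounds = [], []
        for _, _, k in self.group_info:
            for i in range(k):
                for j in range(i + 1):
                    if i == j:
                        theta0.append(1.0)
                        bounds.append((0.0, np.inf))
                    else:
                        theta0.append(0.0)
                        bounds.append((-np.inf, np.inf))
        return np.asarray(theta0), bounds

    def _lambda(self, theta: np.ndarray) -> sp.csr_matrix:
        mats, pos = [], 0
        for _, m, k in self.group_info:
            T = np.zeros((k, k))
            for i in range(k):
                for j in range(i + 1):
                    T[i, j] = theta[pos]
                    pos += 1
            mats.append(sp.kron(sp.eye(m), T, format="csr"))
        return sp.block_diag(mats, format="csr") if mats else sp.csr_matrix((0, 0))

    def solve(self, theta: np.ndarray) -> dict:
        Lam = self._lambda(theta)
        LtZtZL = np.asarray((Lam.T @ self.ZtZ @ Lam))
        A = LtZtZL + np.eye(self.q)
        L = np.linalg.cholesky(A)
        LtZty = Lam.T @ self.Zty
        LtZtX = Lam.T @ self.ZtX
        cu = sla.solve_triangular(L, LtZty, lower=True)
        CZX = sla.solve_triangular(L, LtZtX, lower=True)
        RXtRX = self.XtX - CZX.T @ CZX
        RX = np.linalg.cholesky(RXtRX)
        rhs = self.Xty - CZX.T @ cu
        beta = sla.cho_solve((RX, True), rhs)
        u = sla.solve_triangular(L.T, cu - CZX @ beta, lower=False)
        b = Lam @ u  # random effects relative to sigma... scaled below

        # penalized residual sum of squares from cross-products
        pwrss = (self.yty
                 - 2.0 * beta @ self.Xty
                 - 2.0 * b @ self.Zty
                 + beta @ self.XtX @ beta
                 + 2.0 * beta @ (self.ZtX.T @ b)
                 + b @ (self.ZtZ @ b)
                 + u @ u)
        pwrss = max(pwrss, 1e-300)
        ldL2 = 2.0 * np.log(np.diag(L)).sum()
        ldRX2 = 2.0 * np.log(np.diag(RX)).sum()
        return {"beta": beta, "u": u, "b": b, "pwrss": float(pwrss),
                "ldL2": float(ldL2), "ldRX2": float(ldRX2),
                "RXtRX": RXtRX, "Lam": Lam}

    # large finite penalty instead of inf: keeps quasi-Newton line searches
    # and finite differencing well-behaved near singular Lambda
    _PENALTY = 1e10

    def deviance(self, theta: np.ndarray, reml: bool) -> float:
        if not np.all(np.isfinite(theta)):
            return self._PENALTY
        try:
            s = self.solve(theta)
        except (np.linalg.LinAlgError, FloatingPointError):
            return self._PENALTY
        n, p = self.n, self.p
        if reml:
            df = n - p
            out = (s["ldL2"] + s["ldRX2"]
                   + df * (1.0 + np.log(2.0 * np.pi * s["pwrss"] / df)))
        else:
            out = s["ldL2"] + n * (1.0 + np.log(2.0 * np.pi * s["pwrss"] / n))
        return out if np.isfinite(out) else self._PENALTY


# ---------------------------------------------------------------------------
# Fit result
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """A converged mixed-model fit."""

    spec: ModelSpec
    params: pd.DataFrame            # term, estimate, se, z, p, ci_low, ci_high
    sigma: float                    # residual standard deviation
    random_cov: dict[str, pd.DataFrame]  # per group, covariance of effects
    loglik: float                   # (restricted) log-likelihood
    deviance: float
    method: str                     # "REML" | "ML"
    theta: np.ndarray
    converged: bool
    boundary: bool                  # any variance at (near) zero
    n_obs: int
    df_method: str = "normal"
    optimizer_message: str = ""
    data: pd.DataFrame | None = field(default=None, repr=False)
    _pls: "_PLS" = field(default=None, repr=False)
    _solution: dict = field(default=None, repr=False)

    @property
    def fixef(self) -> pd.Series:
        return self.params.set_index("term")["estimate"]

    @property
    def vcov(self) -> pd.DataFrame:
        """Covariance of the fixed-effect estimates."""
        V = self.sigma ** 2 * np.linalg.inv(self._solution["RXtRX"])
        idx = list(self.spec.fixed)
        return pd.DataFrame(V, index=idx, columns=idx)

    def fitted(self) -> np.ndarray:
        s = self._solution
        return self._pls.X @ s["beta"] + self._pls.Z @ s["b"]

    def residuals(self) -> np.ndarray:
        """Conditional residuals y - X beta - Z b."""
        return self._pls.y - self.fitted()

    def random_variances(self) -> dict[str, np.ndarray]:
        """Per-group covariance matrices on the response scale."""
        return {g: df.to_numpy() for g, df in self.random_cov.items()}

    def summary(self) -> str:
        lines = [f"Linear mixed model fit by {self.method} "
                 f"({self.df_method} df); n = {self.n_obs}",
                 f"logLik = {self.loglik:.2f}   sigma = {self.sigma:.4f}"]
        for g, cov in self.random_cov.items():
            sds = np.sqrt(np.diag(cov.to_numpy()))
            lines.append(f"random {g}: sd = "
                         + ", ".join(f"{t}={s:.4f}"
                                     for t, s in zip(cov.index, sds)))
        lines.append(self.params.to_string(index=False,
                                           float_format=lambda v: f"{v: .4f}"))
        return "\n".join(lines)


def _make_result(spec: ModelSpec, pls: _PLS, theta: np.ndarray, reml: bool,
                 converged: bool, message: str,
                 data: pd.DataFrame) -> FitResult:
    s = pls.solve(theta)
    n, p = pls.n, pls.p
    df = n - p if reml else n
    sigma2 = s["pwrss"] / df
    dev = pls.deviance(theta, reml)
    try:
        V = sigma2 * np.linalg.inv(s["RXtRX"])
    except np.linalg.LinAlgError as err:
        raise ConvergenceError(
            "singular fixed-effect design (collinear model terms)") from err
    se = np.sqrt(np.diag(V))
    beta = s["beta"]
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    pval = 2.0 * stats.norm.sf(np.abs(z))
    crit = stats.norm.ppf(0.975)
    params = pd.DataFrame({
        "term": list(spec.fixed), "estimate": beta, "se": se, "z": z,
        "p": pval, "ci_low": beta - crit * se, "ci_high": beta + crit * se})

    random_cov: dict[str, pd.DataFrame] = {}
    pos = 0
    boundary = False
    for g, m, k in pls.group_info:
        T = np.zeros((k, k))
        for i in range(k):
            for j in range(i + 1):
                T[i, j] = theta[pos]
                pos += 1
        cov = sigma2 * (T @ T.T)
        if np.any(np.diag(cov) < 1e-8 * sigma2):
            boundary = True
        terms = list(spec.random[g])
        random_cov[g] = pd.DataFrame(cov, index=terms, columns=terms)

    return FitResult(spec=spec, params=params, sigma=float(np.sqrt(sigma2)),
                     random_cov=random_cov, loglik=-dev / 2.0, deviance=dev,
                     method="REML" if reml else "ML", theta=theta,
                     converged=converged, boundary=boundary, n_obs=n,
                     optimizer_message=message, data=data,
                     _pls=pls, _solution=s)


def fit_mixed_model(spec: ModelSpec, data: pd.DataFrame,
                    method: str = "REML",
                    theta0: np.ndarray | None = None,
                    maxiter: int = 2000) -> FitResult:
    """Fit the LMM by profiled (RE)ML over the covariance parameters.

    ``data`` must contain the response, every column referenced by a model
    term, and one column per grouping factor.  A boundary fit (a variance
    estimated at zero) is flagged, not an error; a failure of the
    quasi-Newton search falls back to a derivative-free (Nelder-Mead)
    polish before giving up.
    """
    if method not in ("REML", "ML"):
        raise ValueError("method must be 'REML' or 'ML'")
    reml = method == "REML"
    for g in spec.random:
        if data[g].nunique() < 2:
            raise ValueError(f"grouping factor {g!r} needs >= 2 levels")
    pls = _PLS(spec, data)
    start, bounds = pls.theta_template()
    if theta0 is not None:
        start = np.asarray(theta0, dtype=float)

    res = scipy.optimize.minimize(
        pls.deviance, start, args=(reml,), method="L-BFGS-B", bounds=bounds,
        options={"maxiter": maxiter, "maxfun": 10 * maxiter, "ftol": 1e-12,
                 "gtol": 1e-8})
    best_x, best_f = res.x, res.fun
    bad = (not res.success or not np.isfinite(best_f)
           or not np.all(np.isfinite(best_x)) or best_f >= pls._PENALTY)
    if bad:
        x0 = best_x if (np.all(np.isfinite(best_x))
                        and best_f < pls._PENALTY) else start
        res2 = scipy.optimize.minimize(
            pls.deviance, x0, args=(reml,), method="Nelder-Mead",
            options={"maxiter": 20000, "fatol": 1e-10, "xatol": 1e-8})
        if res2.fun <= best_f or not np.isfinite(best_f):
            best_x, best_f = res2.x, res2.fun
        if not np.isfinite(best_f) or best_f >= pls._PENALTY:
            raise ConvergenceError(f"deviance optimization failed: "
                                   f"{res.message} / {res2.message}")
    best_x = np.asarray(best_x, dtype=float)
    # clamp tiny negative diagonals introduced by the line search
    pos = 0
    for _, _, k in pls.group_info:
        for i in range(k):
            for j in range(i + 1):
                if i == j and best_x[pos] < 0:
                    best_x[pos] = 0.0
                pos += 1
    return _make_result(spec, pls, best_x, reml, True, str(res.message), data)


# ---------------------------------------------------------------------------
# Model comparison and selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitComparison:
    """Likelihood-ratio test between two nested fits."""

    chi_square: float
    df: int
    p_value: float


def likelihood_ratio_test(full: FitResult, reduced: FitResult) -> FitComparison:
    chi2 = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    df = (full.spec.n_cov_params() + len(full.spec.fixed)
          - reduced.spec.n_cov_params() - len(reduced.spec.fixed))
    return FitComparison(chi_square=float(chi2), df=int(df),
                         p_value=float(stats.chi2.sf(chi2, max(df, 1))))


def _removable_random(spec: ModelSpec) -> list[tuple[str, str]]:
    """Random terms droppable now: maximal within their group (marginality);
    the intercept only once it is the group's last remaining term."""
    cands = []
    for g, terms in spec.random.items():
        for t in terms:
            if t == "1" and len(terms) > 1:
                continue
            if any(term_contains(other, t) for other in terms if other != t):
                continue
            cands.append((g, t))
    return cands


def _removable_fixed(spec: ModelSpec) -> list[str]:
    cands = []
    random_terms = {t for ts in spec.random.values() for t in ts}
    for t in spec.fixed:
        if t == "1":
            continue
        if any(term_contains(other, t) for other in spec.fixed if other != t):
            continue
        if t in random_terms:
            continue  # keep fixed terms that still have random slopes
        cands.append(t)
    return cands


def backward_eliminate(spec: ModelSpec, data: pd.DataFrame,
                       alpha_random: float = 0.1,
                       alpha_fixed: float = 0.05,
                       ) -> tuple[ModelSpec, list[dict], FitComparison]:
    """Backward stepwise elimination of random, then fixed, effects.

    Random terms are tested by REML likelihood-ratio tests against the
    model without the term (one covariance-parameter block at a time,
    marginality respected); the least significant term above
    ``alpha_random`` is removed and the procedure repeats.  Fixed terms
    are then pruned on Wald tests above ``alpha_fixed``, never removing a
    term contained in a retained interaction.  Returns the final spec, a
    replayable elimination log and the LRT of the full versus the final
    random structure (both with the full fixed part).
    """
    log: list[dict] = []
    full_fit = fit_mixed_model(spec, data, method="REML")
    current, current_fit = spec, full_fit

    while True:
        cands = _removable_random(current)
        if not cands:
            break
        trials = []
        for g, t in cands:
            red_spec = current.drop_random(g, t)
            red_fit = fit_mixed_model(red_spec, data, method="REML")
            lrt = likelihood_ratio_test(current_fit, red_fit)
            trials.append((lrt.p_value, g, t, red_spec, red_fit, lrt))
        trials.sort(key=lambda r: -r[0])
        p, g, t, red_spec, red_fit, lrt = trials[0]
        if p <= alpha_random:
            break
        log.append({"kind": "random", "group": g, "term": t,
                    "p": p, "chi_square": lrt.chi_square, "df": lrt.df})
        current, current_fit = red_spec, red_fit

    random_comparison = likelihood_ratio_test(full_fit, current_fit)

    while True:
        cands = _removable_fixed(current)
        if not cands:
            break
        tab = current_fit.params.set_index("term")
        pvals = [(float(tab.loc[t, "p"]), t) for t in cands]
        pvals.sort(key=lambda r: -r[0])
        p, t = pvals[0]
        if p <= alpha_fixed:
            break
        log.append({"kind": "fixed", "term": t, "p": p})
        current = current.drop_fixed(t)
        current_fit = fit_mixed_model(current, data, method="REML")

    return current, log, random_comparison


def outlier_refit(fit: FitResult, threshold: float = 2.5,
                  ) -> tuple[FitResult, float]:
    """Drop |standardized conditional residual| > threshold, refit once."""
    resid = fit.residuals() / fit.sigma
    keep = np.abs(resid) <= threshold
    frac = float(1.0 - keep.mean())
    if frac == 0.0:
        return fit, 0.0
    data = fit.data.iloc[np.flatnonzero(keep)]
    new = fit_mixed_model(fit.spec, data, method=fit.method,
                          theta0=fit.theta)
    return new, frac


def variance_explained(fit: FitResult) -> tuple[float, float]:
    """Nakagawa-style marginal and conditional R^2.

    Fixed-effect variance is the variance of the fixed linear predictor
    over the data; each random term contributes the mean over rows of
    ``z_i' Sigma_g z_i`` (exact for intercept-only terms, the standard
    generalization for slopes).
    """
    s = fit._solution
    var_fixed = float(np.var(fit._pls.X @ s["beta"]))
    var_random = 0.0
    for g, terms in fit.spec.random.items():
        cov = fit.random_cov[g].to_numpy()
        vals = np.column_stack([build_term_column(fit.data, t) for t in terms])
        # mean_i z_i' Sigma_g z_i; z_i depends only on the row's term values
        var_random += float(np.einsum("ij,jk,ik->i", vals, cov, vals).mean())
    var_resid = fit.sigma ** 2
    total = var_fixed + var_random + var_resid
    marginal = var_fixed / total
    conditional = (var_fixed + var_random) / total
    return float(marginal), float(conditional)
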