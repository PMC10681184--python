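"""Post-hoc slope and marginal-mean contrasts with Tukey adjustment.

All quantities are exact linear functions ``c' beta`` of the fixed-effect
estimates of a fitted mixed model; their standard errors come from the
fixed-effect covariance (delta method is exact here since the functions
are linear).  Families of simultaneous pairwise comparisons are adjusted
with the Tukey (studentized-range) method.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .lmm import FitResult, term_columns


def _contrast_vector(terms: tuple[str, ...], modifier: str | None,
                     cell: dict[str, float]) -> np.ndarray:
    """Linear weights over fixed terms for a cell mean or a slope.

    With ``modifier`` set, the vector represents the partial derivative of
    the linear predictor with respect to that covariate in the given cell;
    otherwise the predicted mean, with unspecified continuous covariates
    at 0 (their centered mean).
    """
    c = np.zeros(len(terms))
    for k, term in enumerate(terms):
        cols = term_columns(term)
        if modifier is not None:
            if modifier not in cols:
                continue
            others = [x for x in cols if x != modifier]
        else:
            others = list(cols)
        w = 1.0
        for x in others:
            w *= cell.get(x, 0.0)
        c[k] = w
    return c


@dataclass(frozen=True)
class ContrastResult:
    label: str
    estimate: float
    se: float
    statistic: float
    p_unadjusted: float
    p_adjusted: float
    family_size: int


def tukey_adjust(statistics, k: int, df: float = np.inf) -> np.ndarray:
    """Tukey-adjust two-sided p values for ``k`` pairwise comparisons.

    ``k`` counts the simultaneous pairwise comparisons; the corresponding
    number of means is recovered from the triangular relation m(m-1)/2 = k
    (rounded up when k is not triangular, which is conservative).  ``k = 1``
    returns the unadjusted two-sided p.
    """
    z = np.atleast_1d(np.asarray(statistics, dtype=float))
    if k < 1:
        raise ValueError("family size k must be >= 1")
    if k < len(z):
        raise ValueError("family size smaller than the number of statistics")
    nu = df if np.isfinite(df) else 1e7
    if k == 1:
        return 2.0 * stats.t.sf(np.abs(z), nu)
    m = int(np.ceil((1.0 + np.sqrt(1.0 + 8.0 * k)) / 2.0))
    return stats.studentized_range.sf(np.sqrt(2.0) * np.abs(z), m, nu)


def _pairwise(table: pd.DataFrame, vcov: np.ndarray, vectors: np.ndarray,
              family_size: int | None,
              pairs: list[tuple[int, int]] | None = None,
              ) -> list[ContrastResult]:
    if pairs is None:
        pairs = list(combinations(range(len(table)), 2))
    k = family_size if family_size is not None else len(pairs)
    out = []
    stats_ = []
    labels = []
    for i, j in pairs:
        c = vectors[i] - vectors[j]
        est = float(table["estimate"].iloc[i] - table["estimate"].iloc[j])
        se = float(np.sqrt(c @ vcov @ c))
        stats_.append(est / se if se > 0 else 0.0)
        labels.append(f"{table['label'].iloc[i]} - {table['label'].iloc[j]}")
        out.append((labels[-1], est, se))
    padj = tukey_adjust(stats_, k=k)
    punadj = 2.0 * stats.norm.sf(np.abs(stats_))
    return [ContrastResult(label=lab, estimate=est, se=se, statistic=st,
                           p_unadjusted=float(pu), p_adjusted=float(pa),
                           family_size=k)
            for (lab, est, se), st, pu, pa in zip(out, stats_, punadj, padj)]


def estimate_slopes(fit: FitResult, modifier: str,
                    by: dict[str, list[float]],
                    labels: dict[str, dict[float, str]] | None = None,
                    ) -> pd.DataFrame:
    """Slope of the linear predictor in ``modifier`` within factor cells.

    ``by`` maps effect-coded factors to the levels defining the cells,
    e.g. ``{"congruency": [-1, 1], "emotion": [-1, 1]}``.  Returns one row
    per cell with the delta-method standard error.
    """
    terms = fit.spec.fixed
    if not any(modifier in term_columns(t) for t in terms):
        raise ValueError(f"{modifier!r} does not appear in the fixed part")
    V = fit.vcov.to_numpy()
    beta = fit.fixef.to_numpy()
    rows, vectors = [], []
    cells = _expand_cells(by)
    for cell in cells:
        c = _contrast_vector(terms, modifier, cell)
        est = float(c @ beta)
        se = float(np.sqrt(c @ V @ c))
        lab = ", ".join(_cell_label(f, v, labels) for f, v in cell.items())
        rows.append({"label": lab, **cell, "estimate": est, "se": se})
        vectors.append(c)
    df = pd.DataFrame(rows)
    df.attrs["vectors"] = np.asarray(vectors)
    df.attrs["modifier"] = modifier
    return df


def slope_contrasts(fit: FitResult, slopes: pd.DataFrame,
                    family: str = "all",
                    family_size: int | None = None) -> pd.DataFrame:
    """Differences between cell slopes, Tukey-adjusted.

    ``family="all"`` takes every pairwise contrast; ``family="simple"``
    keeps only pairs of cells differing in exactly one factor (for a 2x2
    grid: the four simple-effect contrasts).
    """
    pairs = None
    if family == "simple":
        factors = [c for c in slopes.columns
                   if c not in ("label", "estimate", "se")]
        pairs = [(i, j) for i, j in combinations(range(len(slopes)), 2)
                 if sum(slopes[f].iloc[i] != slopes[f].iloc[j]
                        for f in factors) == 1]
    elif family != "all":
        raise ValueError("family must be 'all' or 'simple'")
    res = _pairwise(slopes, fit.vcov.to_numpy(), slopes.attrs["vectors"],
                    family_size, pairs=pairs)
    return pd.DataFrame([r.__dict__ for r in res])


def marginal_means_at(fit: FitResult, modifier: str, values: list[float],
                      by: dict[str, list[float]],
                      observed_range: tuple[float, float] | None = None,
                      labels: dict[str, dict[float, str]] | None = None,
                      ) -> pd.DataFrame:
    """Model-implied means at fixed covariate values per factor cell.

    Unspecified continuous covariates sit at 0 (their centered mean).  A
    warning flag is set on the result when a requested value lies outside
    the observed predictor range.
    """
    import warnings

    terms = fit.spec.fixed
    V = fit.vcov.to_numpy()
    beta = fit.fixef.to_numpy()
    rows, vectors = [], []
    for val in values:
        if observed_range is not None and not (
                observed_range[0] - 1e-9 <= val <= observed_range[1] + 1e-9):
            warnings.warn(f"{modifier} = {val} lies outside the observed "
                          f"range {observed_range}", stacklevel=2)
        for cell in _expand_cells(by):
            full_cell = {**cell, modifier: val}
            c = _contrast_vector(terms, None, full_cell)
            est = float(c @ beta)
            se = float(np.sqrt(c @ V @ c))
            lab = (f"{modifier}={val:g}, "
                   + ", ".join(_cell_label(f, v, labels)
                               for f, v in cell.items()))
            rows.append({"label": lab, modifier: val, **cell,
                         "estimate": est, "se": se})
            vectors.append(c)
    df = pd.DataFrame(rows)
    df.attrs["vectors"] = np.asarray(vectors)
    return df


def mean_contrasts(fit: FitResult, means: pd.DataFrame,
                   family_size: int | None = None) -> pd.DataFrame:
    """All pairwise contrasts between marginal means, Tukey-adjusted."""
    res = _pairwise(means, fit.vcov.to_numpy(), means.attrs["vectors"],
                    family_size)
    return pd.DataFrame([r.__dict__ for r in res])


def _expand_cells(by: dict[str, list[float]]) -> list[dict[str, float]]:
    cells = [{}]
    for factor, levels in by.items():
        cells = [{**c, factor: lv} for c in cells for lv in levels]
    return cells


def _cell_label(factor: str, value: float,
                labels: dict[str, dict[float, str]] | None) -> str:
    if labels and factor in labels and value in labels[factor]:
        return f"{factor}={labels[factor][value]}"
    return f"{factor}={value:g}"
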