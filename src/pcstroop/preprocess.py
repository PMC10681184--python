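"""Exclusion rules, inverse-RT transform and design-matrix construction.

Mirrors the analysis conventions of the task: per participant, the first
trial of the task, the first trial after the mid-task break, error trials
(incorrect or missing responses, timeouts included) and the trial
immediately following each error are excluded; RTs are inverse-transformed
(iRT = -1000/RT) to tame positive skew; two-level factors are effect-coded
in {-1, +1}; probability predictors enter on the logit scale; and all
continuous predictors are standardized on the analysis sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import H_CODE, V_CODE  # shared corner effect codes
from .design import CORNERS

#: Continuous covariates standardized for analysis.
CONTINUOUS = ("lwpc", "ispc", "prs", "pr", "pl", "trial", "preceding_irt")

_CORNER_CODE = {c: i for i, c in enumerate(CORNERS)}


def inverse_transform(rt_ms):
    """iRT = -1000/RT (RT in ms); strictly increasing, always negative."""
    rt = np.asarray(rt_ms, dtype=float)
    if np.any(rt[~np.isnan(rt)] <= 0):
        raise ValueError("reaction times must be positive")
    return -1000.0 / rt


@dataclass(frozen=True)
class ExclusionReport:
    """Per-participant and overall exclusion accounting."""

    per_participant: pd.DataFrame  # participant, n_trials, n_excluded, pct
    overall_pct: float
    mean_pct: float
    sd_pct: float


def apply_exclusions(data: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionReport]:
    """Drop first, post-break, error and post-error trials per participant.

    ``data`` must be ordered by participant then ``trial_index`` and carry
    ``accuracy`` (1 = correct; 0 covers errors and timeouts), ``rt`` (NaN
    for missing responses) and optionally ``break_position`` (the index of
    the first trial after the break).  Returns the retained rows and a
    report of exclusion percentages.
    """
    by_part = data.groupby("participant", sort=False)["trial_index"]
    if not by_part.apply(lambda s: s.is_monotonic_increasing).all():
        raise ValueError("rows must be ordered by participant and trial index")

    error = (data["accuracy"].to_numpy() != 1) | data["rt"].isna().to_numpy()
    post_error = np.zeros(len(data), dtype=bool)
    part = data["participant"].to_numpy()
    same_part = np.r_[False, part[1:] == part[:-1]]
    post_error[1:] = error[:-1]
    post_error &= same_part

    first = data["trial_index"].to_numpy() == 0
    if "break_position" in data.columns:
        post_break = (data["trial_index"].to_numpy()
                      == data["break_position"].to_numpy())
    else:
        post_break = np.zeros(len(data), dtype=bool)

    drop = error | post_error | first | post_break
    retained = data.loc[~drop].copy()

    tab = (pd.DataFrame({"participant": part, "dropped": drop})
           .groupby("participant")
           .agg(n_trials=("dropped", "size"), n_excluded=("dropped", "sum"))
           .reset_index())
    tab["pct_excluded"] = 100.0 * tab["n_excluded"] / tab["n_trials"]
    report = ExclusionReport(
        per_participant=tab,
        overall_pct=float(100.0 * drop.mean()),
        mean_pct=float(tab["pct_excluded"].mean()),
        sd_pct=float(tab["pct_excluded"].std(ddof=1)) if len(tab) > 1 else 0.0,
    )
    return retained, report


def build_design_matrix(data: pd.DataFrame,
                        retained: pd.DataFrame | None = None,
                        constants: dict[str, tuple] | None = None,
                        ) -> tuple[pd.DataFrame, int]:
    """Coded, standardized analysis table from (possibly filtered) data.

    ``data`` is the complete presented sequence (needed so the preceding
    iRT of a retained trial can come from an excluded neighbour);
    ``retained`` the output of :func:`apply_exclusions` (defaults to all
    rows).  ``constants`` optionally fixes the (mean, sd) standardization
    pairs per continuous covariate — e.g. the generator's own constants for
    round-trip checks; by default they are estimated on the analysis
    sample.  Rows whose preceding trial has no measurable iRT (missing RT)
    are dropped; their count is returned alongside the table.
    """
    if retained is None:
        retained = data
    full = data.copy()
    full["irt_raw"] = inverse_transform(full["rt"])
    prev = full.groupby("participant")["irt_raw"].shift(1)
    full["preceding_irt_raw"] = prev

    out = full.loc[retained.index].copy()
    n_missing_prev = int(out["preceding_irt_raw"].isna().sum())
    out = out.dropna(subset=["irt_raw", "preceding_irt_raw"])

    dm = pd.DataFrame(index=out.index)
    dm["irt"] = out["irt_raw"]
    con = out["congruency"].astype(str).str.startswith("congruent")
    dm["congruency"] = np.where(con, -1.0, 1.0)
    dm["emotion"] = np.where(out["emotion"].astype(str) == "sad", 1.0, -1.0)
    loc = out["location"].map(_CORNER_CODE).to_numpy()
    drc = out["direction"].map(_CORNER_CODE).to_numpy()
    dm["hpos"] = H_CODE[loc].astype(float)
    dm["vpos"] = V_CODE[loc].astype(float)
    dm["hdir"] = H_CODE[drc].astype(float)
    dm["vdir"] = V_CODE[drc].astype(float)

    raw = {
        "lwpc": out["lwpc_logit"].to_numpy(float),
        "ispc": out["ispc_logit"].to_numpy(float),
        "prs": out["prs_logit"].to_numpy(float),
        "pr": out["pr_logit"].to_numpy(float),
        "pl": out["pl_logit"].to_numpy(float),
        "trial": out["trial_index"].to_numpy(float),
        "preceding_irt": out["preceding_irt_raw"].to_numpy(float),
    }
    constants = dict(constants or {})
    for col in CONTINUOUS:
        v = raw[col]
        mu, sd = constants.get(col) or (v.mean(), v.std(ddof=0))
        if sd <= 0:
            raise ValueError(f"cannot standardize constant column {col!r}")
        dm[col] = (v - mu) / sd

    dm["participant"] = out["participant"].to_numpy()
    dm["image"] = out["prime_image"].to_numpy()
    return dm, n_missing_prev
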