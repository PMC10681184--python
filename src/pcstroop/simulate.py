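"""Generative model for synthetic spatial-Stroop behavior.

Simulates per-trial reaction times and accuracies for a sample of
participants performing the emotional-priming spatial Stroop task, on the
inverse-RT scale (iRT = -1000/RT) the analysis uses.  The fixed-effect
coefficients default to the final-model estimates of the study the package
emulates, so the full analysis chain (exclusions, transform, mixed-model
fit) can be validated by parameter recovery without any external data.

The generator and the preprocessing module share one covariate coding
(effect codes in {-1, +1}; logit-scale belief predictors standardized), so
a design matrix rebuilt from simulated data reproduces the one the data
were generated from.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .design import CORNERS, TrialList
from .hgf import trialwise_predictors  # noqa: F401  (re-exported convenience)

#: Prime image ids: 1-20 portray sad expressions, 21-40 the same actors
#: with neutral expressions.
SAD_IMAGES = tuple(range(1, 21))
NEUTRAL_IMAGES = tuple(range(21, 41))

#: Fixed part of the final analysis model, canonical colon syntax.
MODEL_TERMS = (
    "1", "trial", "preceding_irt", "prs", "pr", "pl",
    "hpos", "vpos", "hdir", "vdir",
    "congruency", "lwpc", "emotion", "ispc",
    "congruency:lwpc", "congruency:emotion", "lwpc:emotion",
    "congruency:ispc", "emotion:ispc",
    "congruency:lwpc:emotion", "congruency:emotion:ispc",
)

#: Default generating fixed effects on the iRT scale (final-model estimates).
DEFAULT_FIXED_EFFECTS = {
    "1": -2.329,
    "trial": -0.103,
    "preceding_irt": 0.086,
    "prs": -0.05,
    "pr": -0.102,
    "pl": -0.138,
    "hpos": -0.013,
    "vpos": 0.021,
    "hdir": -0.006,
    "vdir": -0.074,
    "congruency": 0.225,
    "lwpc": 0.058,
    "emotion": 0.0,
    "ispc": -0.01,
    "congruency:lwpc": 0.054,
    "congruency:emotion": -0.003,
    "lwpc:emotion": 0.013,
    "congruency:ispc": -0.005,
    "emotion:ispc": -0.007,
    "congruency:lwpc:emotion": -0.008,
    "congruency:emotion:ispc": 0.001,
}

#: Random-effect structure of the final model (participant side).
PARTICIPANT_RANDOM_TERMS = ("1", "congruency", "lwpc", "ispc",
                            "congruency:lwpc", "congruency:ispc")


@dataclass
class GenerativeParams:
    """Parameters of the behavioral generative model.

    The default variance components target the variance partitioning a
    power analysis for this design would assume: participant intercept
    ~ .1, image intercept ~ .1, participant congruency slope ~ .2 and
    residual ~ .6 of the total iRT variance (total SD ~ 0.45 on the iRT
    scale); the remaining slopes are small.  Error rates keep congruent
    accuracy at ceiling (~ .99).
    """

    fixed_effects: dict = field(default_factory=lambda: dict(DEFAULT_FIXED_EFFECTS))
    participant_terms: tuple = PARTICIPANT_RANDOM_TERMS
    participant_sd: tuple = (0.141, 0.2, 0.02, 0.02, 0.02, 0.02)
    participant_corr: np.ndarray | None = None  # defaults to identity
    image_intercept_sd: float = 0.141
    residual_sd: float = 0.346
    error_rate_congruent: float = 0.01
    error_rate_incongruent: float = 0.03
    n_participants: int = 74
    rt_bounds: tuple = (150.0, 2000.0)

    def __post_init__(self) -> None:
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be positive")
        if any(s < 0 for s in self.participant_sd) or self.image_intercept_sd < 0:
            raise ValueError("random-effect SDs must be non-negative")
        for r in (self.error_rate_congruent, self.error_rate_incongruent):
            if not 0 <= r <= 1:
                raise ValueError("error rates must lie in [0, 1]")
        if len(self.participant_sd) != len(self.participant_terms):
            raise ValueError("one SD per participant random term")
        if self.participant_corr is None:
            self.participant_corr = np.eye(len(self.participant_terms))
        corr = np.asarray(self.participant_corr, dtype=float)
        if np.linalg.eigvalsh(corr).min() < -1e-9:
            raise ValueError("correlation matrix must be positive semi-definite")
        self.participant_corr = corr

    def marginal_irt_sd(self, covariates: pd.DataFrame) -> float:
        """Marginal SD of iRT implied by the model, for a given trial list.

        Sums the fixed-predictor variance over the list, the random-effect
        variances (weighted by the mean squared covariate of each slope),
        the image and residual variances, and the carryover inflation: with
        the preceding-iRT regressor standardized by this same SD ``s``, the
        effective AR(1) coefficient is ``beta_prec / s``, giving the
        self-consistent ``s^2 = V0 + beta_prec^2``.
        """
        terms = [t for t in MODEL_TERMS if t not in ("1", "preceding_irt")]
        M = np.column_stack([
            np.prod([covariates[c].to_numpy() for c in t.split(":")], axis=0)
            for t in terms])
        beta = np.array([self.fixed_effects[t] for t in terms])
        var_fixed = float(np.var(M @ beta))
        cov = self.participant_cov()
        var_random = 0.0
        for j, t in enumerate(self.participant_terms):
            x2 = 1.0 if t == "1" else float(
                np.mean(np.prod([covariates[c].to_numpy() ** 2
                                 for c in t.split(":")], axis=0)))
            var_random += cov[j, j] * x2
        v0 = (var_fixed + var_random + self.image_intercept_sd ** 2
              + self.residual_sd ** 2)
        return float(np.sqrt(v0 + self.fixed_effects["preceding_irt"] ** 2))

    def participant_cov(self) -> np.ndarray:
        s = np.asarray(self.participant_sd, dtype=float)
        return self.participant_corr * np.outer(s, s)

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["participant_corr"] = np.asarray(self.participant_corr).tolist()
        return d


# ---------------------------------------------------------------------------
# Prime assignment
# ---------------------------------------------------------------------------

def assign_primes(trials: TrialList, seed: int) -> TrialList:
    """Fill emotion and prime-image columns of a trial list, in place.

    Emotion (sad vs. neutral) is balanced 50/50 within each block x
    congruency cell; odd cells round alternately so the imbalance never
    accumulates.  The prime image is drawn uniformly from the 20 images of
    the assigned emotion, never repeating the immediately preceding
    trial's image.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    n = len(trials)
    emotion = np.full(n, -1, dtype=int)
    odd_toggle = 0
    for b in np.unique(trials.block):
        for c in (0, 1):
            idx = np.flatnonzero((trials.block == b) & (trials.congruent == c))
            m = len(idx)
            n_sad = m // 2
            if m % 2 == 1:
                n_sad += odd_toggle
                odd_toggle = 1 - odd_toggle
            labels = np.zeros(m, dtype=int)
            labels[:n_sad] = 1
            rng.shuffle(labels)
            emotion[idx] = labels

    images = np.full(n, -1, dtype=int)
    pools = {0: np.array(NEUTRAL_IMAGES), 1: np.array(SAD_IMAGES)}
    prev = -1
    for k in range(n):
        pool = pools[emotion[k]]
        pick = int(rng.choice(pool[pool != prev]))
        images[k] = pick
        prev = pick
    trials.emotion = emotion
    trials.prime_image = images
    return trials


# ---------------------------------------------------------------------------
# Covariate coding shared with preprocessing
# ---------------------------------------------------------------------------

#: Horizontal effect code per corner (left = -1, right = +1), CORNERS order.
H_CODE = np.array([-1, 1, 1, -1])
#: Vertical effect code per corner (lower = -1, upper = +1).
V_CODE = np.array([1, 1, -1, -1])


def standardization_constants(trials: TrialList,
                              beliefs: pd.DataFrame) -> dict[str, tuple]:
    """(mean, sd) per continuous covariate, over the full trial list."""
    out = {}
    for col in ("lwpc", "ispc", "prs", "pr", "pl"):
        v = beliefs[f"{col}_logit"].to_numpy(float)
        out[col] = (float(v.mean()), float(v.std(ddof=0)))
    rank = np.arange(len(trials), dtype=float)
    out["trial"] = (float(rank.mean()), float(rank.std(ddof=0)))
    return out


def trial_covariates(trials: TrialList, beliefs: pd.DataFrame,
                     constants: dict[str, tuple]) -> pd.DataFrame:
    """Coded, standardized covariates for every trial of a list.

    Everything except ``preceding_irt`` (which depends on the simulated or
    observed responses) is a pure function of the list and its beliefs.
    """
    cov = pd.DataFrame({
        "congruency": np.where(trials.congruent == 1, -1.0, 1.0),
        "emotion": np.where(trials.emotion == 1, 1.0, -1.0),
        "hpos": H_CODE[trials.location].astype(float),
        "vpos": V_CODE[trials.location].astype(float),
        "hdir": H_CODE[trials.direction].astype(float),
        "vdir": V_CODE[trials.direction].astype(float),
    })
    for col in ("lwpc", "ispc", "prs", "pr", "pl"):
        mu, sd = constants[col]
        cov[col] = (beliefs[f"{col}_logit"].to_numpy(float) - mu) / sd
    mu, sd = constants["trial"]
    cov["trial"] = (np.arange(len(trials)) - mu) / sd
    return cov


def _term_value(cov_row: np.ndarray, term_idx: list[list[int]],
                k: int) -> float:
    v = 1.0
    for j in term_idx[k]:
        v *= cov_row[j]
    return v


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def simulate_participant(trials: TrialList, beliefs: pd.DataFrame,
                         params: GenerativeParams, participant_seed: int,
                         image_effects: dict[int, float] | None = None,
                         constants: dict[str, tuple] | None = None,
                         ) -> pd.DataFrame:
    """Simulate one participant's trial-by-trial RT and accuracy.

    Draws the participant's random-effect vector, then walks the list:
    builds the coded covariate row, adds fixed, random and image
    contributions plus the preceding-(standardized)-iRT carryover term and
    a Gaussian residual, maps iRT -> RT = -1000/iRT, clips at the RT floor
    and records responses slower than the timeout as missing.  A residual
    that would make iRT non-negative (undefined RT) is resampled and
    counted in the ``n_resampled`` attribute of the result.
    """
    if (trials.emotion < 0).any():
        raise ValueError("assign primes before simulating")
    rng = np.random.default_rng(participant_seed)
    if image_effects is None:
        image_effects = {}
    if constants is None:
        constants = standardization_constants(trials, beliefs)

    cov = trial_covariates(trials, beliefs, constants)
    terms = [t for t in MODEL_TERMS if t not in ("1", "preceding_irt")]
    M = np.column_stack([np.prod([cov[c].to_numpy() for c in t.split(":")],
                                 axis=0) for t in terms])
    beta = np.array([params.fixed_effects[t] for t in terms])
    beta0 = params.fixed_effects["1"]
    beta_prec = params.fixed_effects["preceding_irt"]

    b = rng.multivariate_normal(np.zeros(len(params.participant_terms)),
                                params.participant_cov(), method="eigh")
    rterms = [t for t in params.participant_terms if t != "1"]
    Mr = np.column_stack([np.prod([cov[c].to_numpy() for c in t.split(":")],
                                  axis=0) for t in rterms]) \
        if rterms else np.zeros((len(trials), 0))
    br = np.array([b[list(params.participant_terms).index(t)] for t in rterms])
    b0 = b[list(params.participant_terms).index("1")] \
        if "1" in params.participant_terms else 0.0

    irt_mean, irt_sd = (constants.get("preceding_irt")
                        or (beta0, params.marginal_irt_sd(cov)))
    rt_floor, rt_timeout = params.rt_bounds
    err_rate = {1: params.error_rate_congruent, 0: params.error_rate_incongruent}

    n = len(trials)
    irt = np.empty(n)
    rt = np.empty(n)
    acc = np.empty(n, dtype=int)
    n_resampled = 0
    prev_irt = rng.normal(irt_mean, irt_sd)  # marginal draw for trial 1
    for k in range(n):
        mu = (beta0 + M[k] @ beta + b0 + (Mr[k] @ br if rterms else 0.0)
              + image_effects.get(int(trials.prime_image[k]), 0.0)
              + beta_prec * (prev_irt - irt_mean) / irt_sd)
        val = mu + rng.normal(0.0, params.residual_sd)
        while val >= -1e-9:
            val = mu + rng.normal(0.0, params.residual_sd)
            n_resampled += 1
        irt[k] = val
        rt[k] = max(-1000.0 / val, rt_floor)
        acc[k] = 0 if rng.random() < err_rate[int(trials.congruent[k])] else 1
        prev_irt = irt[k]

    timeout = rt > rt_timeout
    acc[timeout] = 0
    df = trials.to_frame()
    df["rt"] = np.where(timeout, np.nan, rt)
    df["accuracy"] = acc
    df.attrs["n_resampled"] = n_resampled
    return df


def simulate_dataset(params: GenerativeParams, trials: TrialList,
                     beliefs: pd.DataFrame, master_seed: int,
                     ) -> tuple[pd.DataFrame, dict]:
    """Simulate the full crossed dataset: every participant, same list.

    All participants run the same selected trial list (as in the study);
    by-image random intercepts are drawn once and shared across
    participants.  Returns the long-format dataset and a metadata dict
    (seeds, parameters, standardization constants) for provenance.
    """
    ss = np.random.SeedSequence(master_seed)
    child = (ss.generate_state(params.n_participants + 1, dtype=np.uint64)
             % (2 ** 31)).astype(np.int64)
    rng_img = np.random.default_rng(int(child[0]))
    image_effects = {img: rng_img.normal(0.0, params.image_intercept_sd)
                     for img in (*SAD_IMAGES, *NEUTRAL_IMAGES)}
    constants = standardization_constants(trials, beliefs)
    cov = trial_covariates(trials, beliefs, constants)
    # the carryover scale, exported so the analysis can reproduce the
    # generator's standardization exactly in round-trip checks
    constants["preceding_irt"] = (params.fixed_effects["1"],
                                  params.marginal_irt_sd(cov))

    frames = []
    for i in range(params.n_participants):
        df = simulate_participant(trials, beliefs, params,
                                  participant_seed=int(child[i + 1]),
                                  image_effects=image_effects,
                                  constants=constants)
        df.insert(0, "participant", i + 1)
        frames.append(df)
    data = pd.concat(frames, ignore_index=True)

    belief_cols = [c for c in beliefs.columns if c.endswith("_logit")]
    reps = pd.concat([beliefs[belief_cols]] * params.n_participants,
                     ignore_index=True)
    data = pd.concat([data, reps], axis=1)
    data["break_position"] = trials.break_position

    meta = {
        "master_seed": master_seed,
        "participant_seeds": child[1:].tolist(),
        "image_seed": int(child[0]),
        "n_participants": params.n_participants,
        "list_seed": trials.seed,
        "break_position": trials.break_position,
        "standardization": {k: list(v) for k, v in constants.items()},
        "params": params.to_jsonable(),
    }
    return data, meta


def write_dataset(data: pd.DataFrame, meta: dict, csv_path, meta_path) -> None:
    data.to_csv(csv_path, index=False)
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=2)
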