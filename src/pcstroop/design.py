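"""Dual proportion-congruency block designs and constrained trial lists.

A spatial Stroop task presents an arrow at one of four corner locations,
pointing toward one of the same four corners; a trial is congruent when
location and direction coincide.  The proportion of congruent trials is
manipulated at two levels simultaneously: list-wide (LWPC, per block) and
item-specific (ISPC, per target location), while the response-given-stimulus
contingency (PRS) is varied so that congruency proportions and associative
contingency can be separated statistically.

This module builds the 4x4 per-block count matrices, derives the exact
proportion tables, pseudorandomizes trial order under first-order priming
constraints, generates candidate lists and selects the one whose trial-wise
ISPC and PRS belief series share the least variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

#: Canonical corner order used for both locations (rows) and directions
#: (columns) everywhere in the package.
CORNERS = ("upper-left", "upper-right", "lower-right", "lower-left")

#: Response key assigned to each direction, spatially compatible layout.
RESPONSE_KEYS = {"upper-left": "E", "upper-right": "O",
                 "lower-right": "K", "lower-left": "D"}


class DesignError(ValueError):
    """Raised when a block design or its constraints are infeasible."""


# ---------------------------------------------------------------------------
# Block design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlockDesign:
    """Six 4x4 (location x direction) trial-count matrices.

    Rows index target locations and columns target directions, both in
    :data:`CORNERS` order.  Diagonal cells are the congruent trials.
    """

    counts: np.ndarray  # shape (n_blocks, 4, 4), non-negative integers

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.ndim != 3 or counts.shape[1:] != (4, 4):
            raise DesignError("counts must have shape (n_blocks, 4, 4)")
        if (counts < 0).any():
            raise DesignError("trial counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def n_blocks(self) -> int:
        return self.counts.shape[0]

    @property
    def trials_per_block(self) -> np.ndarray:
        return self.counts.sum(axis=(1, 2))

    def row_sums(self) -> np.ndarray:
        """Per-block location frequencies, shape (n_blocks, 4)."""
        return self.counts.sum(axis=2)

    def lwpc(self) -> np.ndarray:
        """List-wide proportion congruent per block (trace / total)."""
        tr = np.trace(self.counts, axis1=1, axis2=2)
        return tr / self.trials_per_block

    def ispc(self) -> np.ndarray:
        """Item-specific proportion congruent, shape (n_blocks, 4)."""
        rows = self.row_sums()
        if (rows == 0).any():
            raise DesignError("zero row (location) sum in a block")
        diag = np.diagonal(self.counts, axis1=1, axis2=2)
        return diag / rows

    def prs(self) -> np.ndarray:
        """Response-given-location contingency, shape (n_blocks, 4, 4)."""
        rows = self.row_sums()
        if (rows == 0).any():
            raise DesignError("zero row (location) sum in a block")
        return self.counts / rows[:, :, None]

    def validate(self, mirror_pairs: Sequence[tuple[int, int]] = ((0, 4), (1, 3), (2, 5)),
                 check_mirrors: bool = True) -> None:
        """Check the structural invariants of the six-block task design."""
        rows = self.row_sums()
        if not (rows == rows[:, :1]).all():
            raise DesignError("each target location must be equally probable "
                              "within a block (unequal row sums)")
        if check_mirrors and self.n_blocks == 6:
            lw = self.lwpc()
            for a, b in mirror_pairs:
                if abs(lw[a] - lw[b]) > 1e-12:
                    raise DesignError(
                        f"blocks {a + 1} and {b + 1} must share the same LWPC")

    @classmethod
    def from_yaml(cls, path) -> "BlockDesign":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        blocks = payload["blocks"] if isinstance(payload, dict) else payload
        return cls(np.asarray(blocks, dtype=int))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"locations": list(CORNERS),
                            "directions": list(CORNERS),
                            "blocks": self.counts.tolist()}, fh)


def _reverse_corners(mat: np.ndarray) -> np.ndarray:
    """Relabel corners by the reversing permutation on rows and columns.

    Applying the same permutation to both axes preserves the diagonal
    (congruent cells) and the row sums while moving the ISPC profile to
    different locations.
    """
    return mat[::-1, ::-1].copy()


def default_design() -> BlockDesign:
    """The package's default six-block design.

    96 trials per block (24 per location), LWPC levels .25 / .50 / .75
    mirrored across blocks 1&5, 2&4 and 3&6, per-location ISPC values
    deliberately offset from the block LWPC, and off-diagonal counts spread
    unevenly so that the response-given-location contingency (PRS) is not
    collinear with the congruency proportions.
    """
    low = np.array([  # LWPC = .25, ISPC = (.042, .125, .375, .458)
        [1, 14, 6, 3],
        [3, 3, 12, 6],
        [4, 2, 9, 9],
        [8, 4, 1, 11],
    ])
    mid = np.array([  # LWPC = .50, ISPC = (.167, .333, .667, .833)
        [4, 12, 6, 2],
        [2, 8, 10, 4],
        [2, 1, 16, 5],
        [3, 1, 0, 20],
    ])
    high = np.array([  # LWPC = .75, ISPC = (.958, .875, .625, .542)
        [23, 1, 0, 0],
        [0, 21, 2, 1],
        [2, 1, 15, 6],
        [7, 3, 1, 13],
    ])
    blocks = [low, mid, high,
              _reverse_corners(mid), _reverse_corners(low), _reverse_corners(high)]
    design = BlockDesign(np.stack(blocks))
    design.validate()
    return design


# ---------------------------------------------------------------------------
# Count synthesis
# ---------------------------------------------------------------------------

def synthesize_block_counts(target_lwpc: float,
                            target_ispc: Sequence[float],
                            trials_per_location: int,
                            prs_spread: Sequence[float] | None = None,
                            ) -> np.ndarray:
    """Build one 4x4 count matrix realizing the requested proportions.

    The diagonal (congruent) cell of each location is
    ``round(target_ispc[loc] * trials_per_location)``; the remaining trials
    of the row are distributed over the three incongruent directions
    according to ``prs_spread`` (relative weights, default uneven ``(3, 2,
    1)`` rotated per row so the contingency profile varies across
    locations).

    Raises :class:`DesignError` when the targets cannot be realized with
    equal row sums, or when the achieved LWPC deviates from the target by
    more than one trial in the block total.
    """
    target_ispc = np.asarray(target_ispc, dtype=float)
    if target_ispc.shape != (4,):
        raise DesignError("target_ispc must have four entries")
    if not (0 <= target_lwpc <= 1) or ((target_ispc < 0) | (target_ispc > 1)).any():
        raise DesignError("proportion targets must lie in [0, 1]")
    if trials_per_location < 4:
        raise DesignError("need at least 4 trials per location")

    diag = np.rint(target_ispc * trials_per_location).astype(int)
    if (diag > trials_per_location).any():
        raise DesignError("infeasible ISPC target: congruent count exceeds row sum")

    if prs_spread is None:
        prs_spread = (3.0, 2.0, 1.0)
    spread = np.asarray(prs_spread, dtype=float)
    if spread.shape != (3,) or (spread < 0).any() or spread.sum() == 0:
        raise DesignError("prs_spread must be three non-negative weights")

    mat = np.zeros((4, 4), dtype=int)
    for loc in range(4):
        rest = trials_per_location - diag[loc]
        offdiag_cols = [c for c in range(4) if c != loc]
        w = np.roll(spread, loc)
        alloc = np.floor(rest * w / w.sum()).astype(int)
        # distribute the rounding remainder to the largest weights
        for k in np.argsort(-w)[: rest - alloc.sum()]:
            alloc[k] += 1
        mat[loc, loc] = diag[loc]
        for c, a in zip(offdiag_cols, alloc):
            mat[loc, c] = a

    total = 4 * trials_per_location
    achieved = np.trace(mat) / total
    if abs(achieved - target_lwpc) > 1.0 / total + 1e-12:
        raise DesignError(
            f"rounding cannot satisfy LWPC target {target_lwpc:.3f}: "
            f"achieved {achieved:.3f} with equal row sums")
    return mat


def design_probabilities(design: BlockDesign) -> dict[str, object]:
    """Exact LWPC / ISPC / PRS tables for a design.

    Returns a dict with ``lwpc`` (Series per block), ``ispc`` (DataFrame
    block x location) and ``prs`` (DataFrame with MultiIndex block,
    location over direction columns); all entries are exact rationals
    evaluated in floating point.
    """
    blocks = range(1, design.n_blocks + 1)
    lwpc = pd.Series(design.lwpc(), index=pd.Index(blocks, name="block"),
                     name="lwpc")
    ispc = pd.DataFrame(design.ispc(), index=lwpc.index,
                        columns=pd.Index(CORNERS, name="location"))
    prs = design.prs()
    prs_df = pd.DataFrame(
        prs.reshape(-1, 4),
        index=pd.MultiIndex.from_product([blocks, CORNERS],
                                         names=["block", "location"]),
        columns=pd.Index(CORNERS, name="direction"))
    return {"lwpc": lwpc, "ispc": ispc, "prs": prs_df}


# ---------------------------------------------------------------------------
# Trial lists
# ---------------------------------------------------------------------------

@dataclass
class TrialList:
    """An ordered six-block trial sequence.

    ``location`` and ``direction`` hold integer corner codes (indices into
    :data:`CORNERS`); ``block`` is 1-based.  ``emotion`` (0 = neutral,
    1 = sad) and ``prime_image`` (1..40) are -1 until primes are assigned.
    """

    block: np.ndarray
    location: np.ndarray
    direction: np.ndarray
    seed: int
    break_position: int = field(default=-1)
    emotion: np.ndarray = field(default=None)
    prime_image: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        n = len(self.block)
        if self.break_position < 0:
            self.break_position = n // 2
        if self.emotion is None:
            self.emotion = np.full(n, -1, dtype=int)
        if self.prime_image is None:
            self.prime_image = np.full(n, -1, dtype=int)

    def __len__(self) -> int:
        return len(self.block)

    @property
    def congruent(self) -> np.ndarray:
        return (self.location == self.direction).astype(int)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with human-readable labels."""
        corners = np.asarray(CORNERS)
        df = pd.DataFrame({
            "block": self.block,
            "trial_index": np.arange(len(self)),
            "location": corners[self.location],
            "direction": corners[self.direction],
            "congruency": np.where(self.congruent == 1, "congruent",
                                   "incongruent"),
            "response_key": [RESPONSE_KEYS[c] for c in corners[self.direction]],
        })
        if (self.emotion >= 0).all():
            df["emotion"] = np.where(self.emotion == 1, "sad", "neutral")
            df["prime_image"] = self.prime_image
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, seed: int = -1) -> "TrialList":
        code = {c: i for i, c in enumerate(CORNERS)}
        tl = cls(block=df["block"].to_numpy(int),
                 location=np.array([code[v] for v in df["location"]]),
                 direction=np.array([code[v] for v in df["direction"]]),
                 seed=seed)
        if "emotion" in df.columns:
            tl.emotion = (df["emotion"].to_numpy() == "sad").astype(int)
        if "prime_image" in df.columns:
            tl.prime_image = df["prime_image"].to_numpy(int)
        return tl


def validate_trial_list(trials: TrialList, design: BlockDesign,
                        max_congruency_run: int = 5) -> None:
    """Independent constraint validator for emitted lists.

    Checks multiset preservation against the design, the congruency
    run-length bound, and the absence of consecutive location or direction
    (hence response) repetitions.  Raises :class:`DesignError` on the first
    violation.
    """
    for b in range(design.n_blocks):
        mask = trials.block == b + 1
        observed = np.zeros((4, 4), dtype=int)
        np.add.at(observed, (trials.location[mask], trials.direction[mask]), 1)
        if not (observed == design.counts[b]).all():
            raise DesignError(f"block {b + 1}: trial multiset differs from design")
    if (trials.location[1:] == trials.location[:-1]).any():
        raise DesignError("consecutive trials share the target location")
    if (trials.direction[1:] == trials.direction[:-1]).any():
        raise DesignError("consecutive trials share the target direction")
    run, prev = 1, None
    for c in trials.congruent:
        run = run + 1 if c == prev else 1
        prev = c
        if run > max_congruency_run:
            raise DesignError(
                f"congruency run exceeds {max_congruency_run}")
    expected_blocks = np.repeat(np.arange(1, design.n_blocks + 1),
                                design.trials_per_block)
    if not (trials.block == expected_blocks).all():
        raise DesignError("blocks are not concatenated in order")


def pseudorandomize(design: BlockDesign, seed: int,
                    max_congruency_run: int = 5,
                    max_restarts: int = 500) -> TrialList:
    """Order trials under first-order priming constraints.

    Within the concatenated list (constraints also bind across block
    boundaries) the sampler enforces: at most ``max_congruency_run``
    consecutive trials of the same congruency, and no immediate repetition
    of target location or target direction.  Trials are drawn sequentially,
    uniformly over the remaining admissible (location, direction) cells
    weighted by their remaining counts; a dead end restarts the current
    block.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    loc_out: list[int] = []
    dir_out: list[int] = []
    blk_out: list[int] = []

    prev_loc = prev_dir = -1
    prev_con, run = -1, 0
    for b in range(design.n_blocks):
        start_state = (prev_loc, prev_dir, prev_con, run)
        for attempt in range(max_restarts + 1):
            prev_loc, prev_dir, prev_con, run = start_state
            counts = design.counts[b].copy()
            locs: list[int] = []
            dirs: list[int] = []
            ok = True
            for _ in range(counts.sum()):
                weights = counts.astype(float)
                if prev_loc >= 0:
                    weights[prev_loc, :] = 0.0
                if prev_dir >= 0:
                    weights[:, prev_dir] = 0.0
                if run >= max_congruency_run:
                    if prev_con == 1:
                        weights[np.diag_indices(4)] = 0.0
                    else:
                        weights *= np.eye(4)
                total = weights.sum()
                if total == 0.0:
                    ok = False
                    break
                flat = rng.choice(16, p=weights.ravel() / total)
                loc, dr = divmod(flat, 4)
                counts[loc, dr] -= 1
                locs.append(loc)
                dirs.append(dr)
                con = int(loc == dr)
                run = run + 1 if con == prev_con else 1
                prev_con, prev_loc, prev_dir = con, loc, dr
            if ok:
                break
        else:
            raise DesignError(
                f"block {b + 1}: could not satisfy ordering constraints "
                f"after {max_restarts} restarts (run length / repetition)")
        loc_out.extend(locs)
        dir_out.extend(dirs)
        blk_out.extend([b + 1] * len(locs))

    return TrialList(block=np.asarray(blk_out), location=np.asarray(loc_out),
                     direction=np.asarray(dir_out), seed=seed)


def candidate_seeds(master_seed: int, n: int) -> np.ndarray:
    """Derive ``n`` distinct child seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return (ss.generate_state(n, dtype=np.uint64) % (2 ** 31)).astype(np.int64)


def generate_candidates(design: BlockDesign, n: int = 1000,
                        seed: int = 0,
                        max_congruency_run: int = 5) -> list[TrialList]:
    """Generate ``n`` constraint-satisfying candidate lists.

    Child seeds are derived deterministically from the master seed, so the
    whole collection is reproducible.
    """
    if n < 1:
        raise DesignError("need at least one candidate")
    return [pseudorandomize(design, int(s), max_congruency_run)
            for s in candidate_seeds(seed, n)]


# ---------------------------------------------------------------------------
# List selection
# ---------------------------------------------------------------------------

def shared_variance(x: Iterable[float], y: Iterable[float]) -> float:
    """Squared Pearson correlation between two equal-length series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length 1-d series of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("shared variance undefined for a constant series")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


@dataclass(frozen=True)
class SelectionReport:
    """Summary of the minimum-shared-variance list selection."""

    n_candidates: int
    selected_index: int
    shared_variance_ispc_prs: float
    shared_variance_lwpc_prs: float
    shared_variance_lwpc_ispc: float


def select_trial_list(candidates: Sequence[TrialList],
                      belief_tables: Sequence[pd.DataFrame],
                      ) -> tuple[TrialList, SelectionReport]:
    """Pick the candidate whose trial-wise ISPC and PRS correlate least.

    ``belief_tables`` must align one-to-one with ``candidates`` and carry
    the logit-scale predictor columns produced by the belief tracker.  Ties
    break toward the lowest candidate index.
    """
    if len(candidates) == 0:
        raise ValueError("empty candidate set")
    if len(belief_tables) != len(candidates):
        raise ValueError("need exactly one belief table per candidate")
    scores = np.array([
        shared_variance(tab["ispc_logit"], tab["prs_logit"])
        for tab in belief_tables])
    best = int(np.argmin(scores))  # argmin takes the first minimum
    tab = belief_tables[best]
    report = SelectionReport(
        n_candidates=len(candidates),
        selected_index=best,
        shared_variance_ispc_prs=float(scores[best]),
        shared_variance_lwpc_prs=shared_variance(tab["lwpc_logit"],
                                                 tab["prs_logit"]),
        shared_variance_lwpc_ispc=shared_variance(tab["lwpc_logit"],
                                                  tab["ispc_logit"]),
    )
    return candidates[best], report
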