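"""Iterative hard-negative mining.

During training, non-fracture ROIs whose *fused* score exceeds a mining
threshold — convincing false alarms — are folded into the training pool:

    N_h = { ROI_i : S_i > tau_mine  and  y_i = 0 },    D' = P u N0 u N_h.

The pool keeps a *candidate reservoir* of negatives that are known to the
training split but not yet part of D' (in deployment these are the false
alarms a detector keeps producing, e.g. growth plates and overlapping
cortical edges).  Each mining round scores the reservoir with the current
model, moves the over-threshold negatives into N_h, and leaves the rest for
later epochs — a curriculum that progressively expands the training set
with the confusable cases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

from .roidata import RoiRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MiningConfig:
    """Mining behaviour: threshold, cadence (epochs between rounds, default
    every epoch), duplicate policy and an optional cap on pool growth."""

    tau_mine: float = 0.5
    cadence_epochs: int = 1
    allow_duplicates: bool = False
    max_pool_growth: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.tau_mine < 1.0:
            raise ValueError("tau_mine must be in (0, 1)")
        if self.cadence_epochs < 1:
            raise ValueError("cadence_epochs must be >= 1")


@dataclass
class MiningPool:
    """Training multiset D' = P u N0 u N_h plus the candidate reservoir."""

    P: list[RoiRecord] = field(default_factory=list)
    N0: list[RoiRecord] = field(default_factory=list)
    N_h: list[RoiRecord] = field(default_factory=list)
    reservoir: list[RoiRecord] = field(default_factory=list)
    allow_duplicates: bool = False
    max_pool_growth: Optional[int] = None

    def __post_init__(self) -> None:
        if any(r.y != 1 for r in self.P):
            raise ValueError("P must contain only positive records")
        if any(r.y != 0 for r in self.N0) or any(r.y != 0 for r in self.N_h):
            raise ValueError("N0 and N_h must contain only negative records")

    @classmethod
    def from_records(
        cls,
        records: Sequence[RoiRecord],
        reservoir: Sequence[RoiRecord] = (),
        **kwargs,
    ) -> "MiningPool":
        return cls(
            P=[r for r in records if r.y == 1],
            N0=[r for r in records if r.y == 0],
            reservoir=list(reservoir),
            **kwargs,
        )

    def records(self) -> list[RoiRecord]:
        """The current training multiset D'."""
        return [*self.P, *self.N0, *self.N_h]

    def all_known_records(self) -> list[RoiRecord]:
        return [*self.P, *self.N0, *self.N_h, *self.reservoir]

    def sizes(self) -> tuple[int, int, int]:
        return (len(self.P), len(self.N0), len(self.N_h))

    def __len__(self) -> int:
        return len(self.P) + len(self.N0) + len(self.N_h)


def mine_hard_negatives(
    records: Sequence[RoiRecord],
    fused_scores: Sequence[float],
    tau_mine: float,
) -> list[RoiRecord]:
    """Exactly { records[i] : S_i > tau_mine and y_i = 0 } (strict
    inequality), re-tagged ``mined_neg`` and de-duplicated by
    (source image, integer-rounded box)."""
    if len(records) != len(fused_scores):
        raise ValueError("records and fused_scores must be aligned")
    mined: list[RoiRecord] = []
    seen: set = set()
    for r, score in zip(records, fused_scores):
        if r.y == 0 and score > tau_mine:
            key = r.key()
            if key in seen:
                continue
            seen.add(key)
            mined.append(replace(r, provenance="mined_neg"))
    return mined


def merge_pool(pool: MiningPool, new_negatives: Sequence[RoiRecord]) -> MiningPool:
    """Fold freshly mined negatives into N_h.

    Already-mined records (by de-duplication key) are skipped; when
    duplicates are disallowed, records already present in N0 are skipped
    too.  Growth is capped at ``max_pool_growth`` when set.  Mined records
    are removed from the reservoir.  A record with y=1 is an invariant
    violation and raises.
    """
    if any(r.y != 0 for r in new_negatives):
        raise ValueError("mined negatives must all have y=0")
    existing = {r.key() for r in pool.N_h}
    if not pool.allow_duplicates:
        existing |= {r.key() for r in pool.N0}
    added: list[RoiRecord] = []
    for r in new_negatives:
        key = r.key()
        if key in existing:
            continue
        if (
            pool.max_pool_growth is not None
            and len(pool.N_h) + len(added) >= pool.max_pool_growth
        ):
            logger.info("mining pool growth cap reached (%d)", pool.max_pool_growth)
            break
        existing.add(key)
        added.append(replace(r, provenance="mined_neg"))
    added_keys = {r.key() for r in added}
    return MiningPool(
        P=pool.P,
        N0=pool.N0,
        N_h=[*pool.N_h, *added],
        reservoir=[r for r in pool.reservoir if r.key() not in added_keys],
        allow_duplicates=pool.allow_duplicates,
        max_pool_growth=pool.max_pool_growth,
    )


def select_tau_mine(
    val_records: Sequence[RoiRecord],
    val_fused_scores: Sequence[float],
    precision_floor: float = 0.8,
) -> float:
    """Validation-set mining threshold controlling hard-negative precision.

    Candidates are 0, 1 and the midpoints between consecutive distinct
    sorted fused scores.  For each candidate t the above-threshold set
    {i : S_i > t} is examined; its positive fraction is the *contamination*
    (an empty set counts as contamination 0).  The smallest candidate whose
    contamination is at most ``1 - precision_floor`` is returned; if none
    qualifies, the median fused score is returned with a logged warning.
    """
    y = np.array([r.y for r in val_records])
    s = np.asarray(val_fused_scores, dtype=float)
    if len(y) == 0 or len(y) != len(s):
        raise ValueError("validation records and scores must be aligned, non-empty")
    if len(np.unique(y)) < 2:
        raise ValueError("validation set must contain both labels")
    uniq = np.unique(s)
    candidates = np.concatenate(([0.0], (uniq[:-1] + uniq[1:]) / 2.0, [1.0]))
    for t in candidates:
        above = s > t
        n_above = int(above.sum())
        contamination = float(y[above].mean()) if n_above else 0.0
        if contamination <= 1.0 - precision_floor:
            return float(t)
    logger.warning(
        "no mining threshold satisfies precision floor %.3f; falling back to "
        "the median fused score",
        precision_floor,
    )
    return float(np.median(s))


def make_mining_hook(
    fuse_fn: Callable[[np.ndarray, np.ndarray], np.ndarray],
    tau_mine: float,
    cadence_epochs: int = 1,
    predict_fn: Optional[Callable] = None,
) -> Callable:
    """Build the per-epoch hook used by :func:`roiadj.adjnet.train`.

    Every ``cadence_epochs`` epochs the hook scores the pool's reservoir
    with the current model, fuses with the stored detector confidences via
    ``fuse_fn(y_hat, s)`` and merges the over-threshold negatives.
    """
    from .adjnet import predict_proba

    scorer = predict_fn or predict_proba

    def hook(model, epoch: int, pool: MiningPool) -> MiningPool:
        if (epoch + 1) % cadence_epochs != 0 or not pool.reservoir:
            return pool
        y_hat = scorer(model, pool.reservoir)
        s = np.array([r.s for r in pool.reservoir])
        fused = fuse_fn(np.asarray(y_hat), s)
        mined = mine_hard_negatives(pool.reservoir, fused, tau_mine)
        return merge_pool(pool, mined)

    return hook
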