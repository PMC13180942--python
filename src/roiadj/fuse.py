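"""Confidence fusion, operating-point selection, calibration and paired
statistics.

The fused score of an ROI is the convex combination

    S = alpha * y_hat + (1 - alpha) * s,        alpha in [0, 1],

of the adjudicator probability ``y_hat`` and the raw detector confidence
``s``.  ``alpha`` and the decision threshold ``tau`` (rule: S >= tau =>
fracture) are selected on a validation split only, by exhaustive scans that
maximize F1.  Calibration is summarized by the expected calibration error
over equal-width bins and the Brier score; uncertainty by seeded bootstrap
percentile intervals; paired model comparisons by the Wilcoxon signed-rank
test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.stats import wilcoxon as _scipy_wilcoxon

from .metrics import confusion_from_predictions, classification_metrics

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.6  # reported default convex weight


@dataclass(frozen=True)
class FusionConfig:
    alpha: float = DEFAULT_ALPHA
    tau: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if not 0.0 < self.tau < 1.0:
            raise ValueError("tau must be in (0, 1)")


def fuse_scores(y_hat, s, alpha: float = DEFAULT_ALPHA):
    """S = alpha*y_hat + (1-alpha)*s (elementwise; scalars or arrays)."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    y_hat = np.asarray(y_hat, dtype=float)
    s = np.asarray(s, dtype=float)
    if np.any((y_hat < 0) | (y_hat > 1)) or np.any((s < 0) | (s > 1)):
        raise ValueError("y_hat and s must lie in [0, 1]")
    out = alpha * y_hat + (1.0 - alpha) * s
    return float(out) if out.ndim == 0 else out


def _f1_at(scores: np.ndarray, labels: np.ndarray, tau: float) -> float:
    return classification_metrics(
        confusion_from_predictions(labels, scores >= tau)
    )["f1"]


def threshold_candidates(scores: np.ndarray) -> np.ndarray:
    """0, 1 and the midpoints between consecutive distinct sorted scores."""
    uniq = np.unique(np.asarray(scores, dtype=float))
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    return np.concatenate(([0.0], mids, [1.0]))


def select_threshold(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[float, float]:
    """The threshold maximizing F1 of the rule (S >= tau -> positive).

    Scans 0, 1 and all midpoints between consecutive distinct scores; ties
    are broken toward the smallest tau (favoring recall).  Returns
    (tau, F1 at tau).  An all-positive input trivially yields (0, 1.0)
    (accept everything); an input without positives is an error.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(y) == 0 or not np.any(y == 1):
        raise ValueError("select_threshold requires at least one positive")
    if np.all(y == 1):
        return 0.0, 1.0
    best_tau, best_f1 = 0.0, -1.0
    for t in threshold_candidates(s):
        f1 = _f1_at(s, y, t)
        if f1 > best_f1:  # strict: ties keep the smaller tau
            best_tau, best_f1 = float(t), float(f1)
    return best_tau, best_f1


def select_alpha(
    y_hat_list: Sequence[float],
    s_list: Sequence[float],
    labels: Sequence[int],
    grid_step: float = 0.05,
) -> tuple[float, float, float]:
    """Joint validation scan of (alpha, tau).

    Scans alpha over {0, grid_step, ..., 1}; for each alpha selects tau via
    :func:`select_threshold` and keeps the pair with maximal F1.  F1 ties
    prefer alpha = 0.6 (the reported default), then the smaller alpha.
    Returns (alpha, tau, F1).
    """
    if not 0.0 < grid_step <= 0.5:
        raise ValueError("grid_step must be in (0, 0.5]")
    y_hat = np.asarray(y_hat_list, dtype=float)
    s = np.asarray(s_list, dtype=float)
    y = np.asarray(labels, dtype=int)
    if not (len(y_hat) == len(s) == len(y)):
        raise ValueError("inputs must be aligned")
    n_steps = int(round(1.0 / grid_step))
    alphas = np.round(np.arange(n_steps + 1) * grid_step, 12)
    alphas[-1] = 1.0

    def _pref(alpha: float) -> tuple:
        # sort key for ties: prefer 0.6 first, then smaller alpha
        return (abs(alpha - DEFAULT_ALPHA) > 1e-12, alpha)

    best = None  # (f1, pref, alpha, tau)
    for a in alphas:
        tau, f1 = select_threshold(fuse_scores(y_hat, s, float(a)), y)
        cand = (-f1, _pref(float(a)), float(a), tau)
        if best is None or cand < best:
            best = cand
    _, _, alpha, tau = best
    return alpha, tau, -best[0]


# ---------------------------------------------------------------------------
# calibration


@dataclass(frozen=True)
class CalibrationReport:
    ece: float
    brier: float
    bin_edges: tuple[tuple[float, float], ...]
    bin_counts: tuple[int, ...]
    bin_confidence: tuple[float, ...]  # nan for empty bins
    bin_pos_rate: tuple[float, ...]  # nan for empty bins


def _bin_index(scores: np.ndarray, n_bins: int) -> np.ndarray:
    # equal-width bins on [0, 1]; the last bin is right-closed
    idx = np.floor(scores * n_bins).astype(int)
    return np.clip(idx, 0, n_bins - 1)


def ece(scores: Sequence[float], labels: Sequence[int], n_bins: int = 10) -> float:
    """Expected calibration error over equal-width bins.

    ECE = sum_b (n_b / N) * |mean confidence_b - positive rate_b| over the
    non-empty bins (empty bins carry zero weight).
    """
    return calibration_report(scores, labels, n_bins).ece


def brier(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Mean squared error between score and binary outcome."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if s.size == 0:
        raise ValueError("brier requires non-empty input")
    return float(np.mean((s - y) ** 2))


def calibration_report(
    scores: Sequence[float], labels: Sequence[int], n_bins: int = 10
) -> CalibrationReport:
    """Reliability-diagram data plus ECE and Brier in one pass."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if s.size == 0:
        raise ValueError("calibration requires non-empty input")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if np.any((s < 0) | (s > 1)):
        raise ValueError("scores must lie in [0, 1]")
    idx = _bin_index(s, n_bins)
    counts, confs, rates = [], [], []
    total_gap = 0.0
    for b in range(n_bins):
        mask = idx == b
        n_b = int(mask.sum())
        counts.append(n_b)
        if n_b:
            conf = float(s[mask].mean())
            rate = float(y[mask].mean())
            total_gap += n_b / s.size * abs(conf - rate)
        else:
            conf, rate = float("nan"), float("nan")
        confs.append(conf)
        rates.append(rate)
    edges = tuple((b / n_bins, (b + 1) / n_bins) for b in range(n_bins))
    return CalibrationReport(
        ece=float(total_gap),
        brier=brier(s, y),
        bin_edges=edges,
        bin_counts=tuple(counts),
        bin_confidence=tuple(confs),
        bin_pos_rate=tuple(rates),
    )


# ---------------------------------------------------------------------------
# uncertainty and paired comparison


def bootstrap_ci(
    metric_fn: Callable[[np.ndarray, np.ndarray], float],
    scores: Sequence[float],
    labels: Sequence[int],
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Seeded percentile bootstrap interval of ``metric_fn(scores, labels)``.

    Resamples with replacement at the original size; a resample on which the
    metric is undefined (e.g. a single label present) is redrawn, and the
    number of redraws is logged.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    n = len(s)
    values = np.empty(n_boot)
    redraws = 0
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            try:
                values[b] = metric_fn(s[idx], y[idx])
                break
            except ValueError:
                redraws += 1
                if redraws > 100 * n_boot:
                    raise RuntimeError("bootstrap: metric undefined on nearly all resamples")
    if redraws:
        logger.info("bootstrap_ci redrew %d degenerate resamples", redraws)
    lo = (1.0 - level) / 2.0
    return (
        float(np.quantile(values, lo)),
        float(np.quantile(values, 1.0 - lo)),
    )


def write_score_table(path, roi_ids, s, y_hat, fused, y) -> None:
    """Persist per-ROI scores as CSV (roi_id, s, y_hat, S, y)."""
    import pandas as pd

    pd.DataFrame(
        {"roi_id": roi_ids, "s": s, "y_hat": y_hat, "S": fused, "y": y}
    ).to_csv(path, index=False)


def read_score_table(path):
    import pandas as pd

    return pd.read_csv(path, dtype={"roi_id": str})


def write_reliability_csv(report: CalibrationReport, path) -> None:
    """Reliability-diagram data (bin edges, counts, confidence, positive
    rate) for plotting."""
    import pandas as pd

    pd.DataFrame(
        {
            "bin_low": [e[0] for e in report.bin_edges],
            "bin_high": [e[1] for e in report.bin_edges],
            "count": report.bin_counts,
            "mean_confidence": report.bin_confidence,
            "positive_rate": report.bin_pos_rate,
        }
    ).to_csv(path, index=False)


def wilcoxon_paired(metric_a: Sequence[float], metric_b: Sequence[float]) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Exact null distribution for n <= 25 (no ties in |differences|), normal
    approximation with tie correction otherwise.  All-zero differences are
    undefined and raise.
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    if np.all(d == 0):
        raise ValueError("wilcoxon undefined: all paired differences are zero")
    nz = d[d != 0]
    exact_ok = len(nz) <= 25 and len(np.unique(np.abs(nz))) == len(nz)
    method = "exact" if exact_ok else "approx"
    res = _scipy_wilcoxon(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)
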