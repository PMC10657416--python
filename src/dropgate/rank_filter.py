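"""Stage 1: barcode-rank thresholding.

Locates the transition from the cell cliff to the ambient plateau on the
log-log barcode rank curve. The curve is smoothed with a rolling mean
(Rice-rule bin), continuous piecewise-linear models with 2-5 breakpoints
are fitted, the most parsimonious model within 1.5x of the best RMSE is
kept, and the breakpoint with the most negative left-to-right angle (the
steep-negative -> flat transition) sets the rank threshold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .matrix_io import CountMatrix
from .robust import PiecewiseFit, knee_point, rolling_mean, segmented_fit_path

logger = logging.getLogger("dropgate")

__all__ = ["RankFitResult", "rank_threshold", "apply_rank_filter", "rice_bin"]

MAX_FIT_POINTS = 1500  # smoothed curve is subsampled to this many points
WEAK_KNEE_ANGLE_DEG = -1.0  # most-negative angle above this flags a weak knee


def rice_bin(n: int) -> int:
    """Rice-rule bin size b = ceil(2 * n^(1/3))."""
    return math.ceil(2 * n ** (1 / 3))


@dataclass
class RankFitResult:
    smoothing_bin: int
    fits: dict[int, PiecewiseFit]
    selected_k: int
    segment_angles: np.ndarray  # degrees, one per breakpoint of the selected fit
    threshold_rank: int
    n_retained: int
    order: np.ndarray  # barcode indices sorted by (total desc, id asc)
    weak_knee: bool = False
    used_fallback: bool = False


def _stable_order(totals: np.ndarray, barcode_ids: list[str] | None) -> np.ndarray:
    if barcode_ids is None:
        return np.argsort(-totals, kind="stable")
    ids = np.asarray(barcode_ids)
    return np.lexsort((ids, -totals))


def rank_threshold(
    total_umis: np.ndarray, barcode_ids: list[str] | None = None
) -> RankFitResult:
    """Find the ambient-plateau rank threshold from per-barcode totals.

    Barcodes are sorted by total descending (ties broken by barcode id for
    determinism); log(total) vs log(rank) is smoothed with the Rice-rule
    rolling mean, fitted with 2-5 breakpoints, and the smallest k whose
    RMSE is within 1.5x of the minimum is selected. At each breakpoint the
    angle atan(slope_left) - atan(slope_right) is computed in degrees; the
    most negative angle marks the transition into the ambient plateau and
    threshold_rank = floor(exp(breakpoint x)). Barcodes of rank <=
    threshold_rank pass stage 1.
    """
    totals = np.asarray(total_umis, dtype=float)
    if barcode_ids is not None and len(barcode_ids) != totals.size:
        raise ValueError("barcode_ids length mismatch")
    positive = totals > 0
    if positive.sum() < 100:
        raise ValueError(
            "fewer than 100 barcodes with positive totals; set a rank threshold manually"
        )
    if np.ptp(totals[positive]) == 0:
        raise ValueError("all totals equal; no rank structure to fit")

    order = _stable_order(totals, barcode_ids)
    order = order[totals[order] > 0]
    sorted_totals = totals[order]
    n = sorted_totals.size
    bin_ = rice_bin(n)
    log_rank = np.log(np.arange(1, n + 1, dtype=float))
    log_total = np.log(sorted_totals)
    # both axes are smoothed with the same window, so a pure power law stays
    # exactly linear and the unequal log-rank spacing introduces no curvature
    smooth_x = rolling_mean(log_rank, bin_)
    smooth_y = rolling_mean(log_total, bin_)

    idx = np.arange(n)
    if idx.size > MAX_FIT_POINTS:
        idx = idx[np.unique(np.linspace(0, idx.size - 1, MAX_FIT_POINTS).round().astype(int))]
    x, y = smooth_x[idx], smooth_y[idx]

    fits: dict[int, PiecewiseFit] = {}
    try:
        path = segmented_fit_path(x, y, kmax=5)
        fits = {k: path[k] for k in range(2, 6)}
    except ValueError:
        pass

    if fits:
        rmses = {k: fits[k].rmse for k in fits}
        min_rmse = min(rmses.values())
        selected_k = min(k for k in sorted(fits) if rmses[k] <= 1.5 * min_rmse)
        fit = fits[selected_k]
        angles = np.degrees(
            np.arctan(fit.segment_slopes[:-1]) - np.arctan(fit.segment_slopes[1:])
        )
        # a rank curve is non-increasing: transitions into a rising segment
        # are smoothing artifacts, not the ambient plateau
        eligible = fit.segment_slopes[1:] <= 1e-9
        if eligible.any():
            cand = np.where(eligible, angles, np.inf)
            best = int(np.argmin(cand))
        else:
            best = int(np.argmin(angles))
        weak = bool(angles[best] > WEAK_KNEE_ANGLE_DEG)
        if weak:
            logger.warning("weak knee: most negative segment angle %.3f deg", angles[best])
        threshold_rank = int(np.floor(np.exp(fit.breakpoints_x[best])))
        used_fallback = False
    else:
        # too few points for segmented fits: knee of the raw log-log curve
        logger.warning("segmented fits failed; falling back to knee_point on raw curve")
        knee = knee_point(log_rank, log_total)
        selected_k = 0
        angles = np.array([])
        threshold_rank = knee.index + 1
        weak = knee.degenerate
        used_fallback = True

    threshold_rank = int(np.clip(threshold_rank, 1, n))
    return RankFitResult(
        smoothing_bin=bin_,
        fits=fits,
        selected_k=selected_k,
        segment_angles=angles,
        threshold_rank=threshold_rank,
        n_retained=threshold_rank,
        order=order,
        weak_knee=weak,
        used_fallback=used_fallback,
    )


def apply_rank_filter(counts: CountMatrix, fit: RankFitResult) -> CountMatrix:
    """Subset to the barcodes of rank <= threshold_rank.

    The retained set is exactly a prefix of the (total desc, id asc)
    ordering, so ties at the threshold total are resolved deterministically
    and the retained count equals threshold_rank.
    """
    keep = fit.order[: fit.threshold_rank]
    return counts.subset_barcodes(np.sort(keep))
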