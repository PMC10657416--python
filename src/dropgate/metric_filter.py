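"""Stage 2: quality-metric filtering with data-adaptive thresholds.

Per-barcode metrics (total UMIs, detected features, mitochondrial /
ribosomal / coding fractions) are filtered sequentially:

1. mitochondrial fraction, thresholded at the knee of the
   high-coverage-barcode survival curve (fallback: a one-breakpoint fit of
   log detected features on mito fraction, capped at 0.3);
2. coding (optionally exonic) fraction, median +/- 3*Sn;
3. the depth-complexity relationship, residuals of a three-breakpoint fit
   of log detected features on log total UMIs, median +/- 5*Sn.

Each filter runs on the survivors of the previous one so every failing
barcode gets an unambiguous fail_reason.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix_io import CountMatrix, GeneClassAnnotation
from .robust import gaussian_mixture_2, knee_point, segmented_fit, sn_scale

logger = logging.getLogger("dropgate")

__all__ = [
    "compute_qc_metrics",
    "MitoThresholdResult",
    "mito_threshold",
    "coding_fraction_filter",
    "depth_complexity_filter",
    "run_stage2",
]


def compute_qc_metrics(counts: CountMatrix, ann: GeneClassAnnotation) -> pd.DataFrame:
    """Per-barcode totals, detected-feature counts and gene-class fractions.

    Fractions are class UMIs / total UMIs. Returns a DataFrame indexed by
    barcode id with pass flags initialised for downstream stages.
    """
    if len(ann.is_mito) != counts.n_genes:
        raise ValueError("annotation length does not match gene count")
    if ann.detected and not any(ann.detected.values()):
        raise ValueError("annotation has no detected gene class")
    totals = counts.barcode_totals().astype(np.int64)
    if (totals == 0).any():
        raise ValueError("zero-total barcodes present; drop them at load")
    n_features = counts.feature_counts_per_barcode().astype(np.int64)
    csr = counts.counts.tocsr()

    def class_sum(mask: np.ndarray) -> np.ndarray:
        if not mask.any():
            return np.zeros(counts.n_barcodes)
        return np.asarray(csr[np.flatnonzero(mask)].sum(axis=0)).ravel()

    qc = pd.DataFrame(
        {
            "total_umis": totals,
            "n_features": n_features,
            "frac_mito": class_sum(ann.is_mito) / totals,
            "frac_ribo": class_sum(ann.is_ribo) / totals,
            "frac_coding": class_sum(ann.is_coding) / totals,
        },
        index=pd.Index(counts.barcode_ids, name="barcode_id"),
    )
    if ann.is_exonic is not None:
        # exon/intron status is alignment-level information; it enters only as
        # a user-supplied per-gene annotation
        qc["frac_exonic"] = class_sum(np.asarray(ann.is_exonic)) / totals
    order = np.lexsort((np.asarray(counts.barcode_ids), -totals))
    rank = np.empty(counts.n_barcodes, dtype=np.int64)
    rank[order] = np.arange(1, counts.n_barcodes + 1)
    qc["rank"] = rank
    qc["pass_stage1"] = True
    qc["pass_stage2"] = False
    qc["pass_stage3"] = False
    qc["fail_reason"] = None
    return qc


@dataclass
class MitoThresholdResult:
    threshold: float
    high_cov_component_mean: float
    curve_thresholds: np.ndarray
    curve_counts: np.ndarray
    used_fallback: bool
    high_cov_mask: np.ndarray | None = None


def mito_threshold(qc: pd.DataFrame, seed: int = 0) -> MitoThresholdResult:
    """Data-adaptive mitochondrial-fraction threshold.

    A two-component normal mixture on log detected features defines
    high-coverage barcodes (posterior > 0.5 for the higher-mean
    component). Candidate thresholds run from their median mito fraction
    to 1 in steps of 0.001; the threshold is the knee of (threshold,
    number of high-coverage barcodes passing). A knee above 0.3 is not
    biologically plausible; in that case a one-breakpoint fit of log
    detected features on mito fraction supplies the threshold, capped at
    0.3.
    """
    if len(qc) < 100:
        raise ValueError("mito_threshold requires >= 100 barcodes")
    logF = np.log(qc["n_features"].to_numpy(dtype=float))
    mito = qc["frac_mito"].to_numpy(dtype=float)
    try:
        mix = gaussian_mixture_2(logF, seed)
        collapsed = mix.collapsed
    except ValueError:
        collapsed = True
        mix = None
    if collapsed or mix is None:
        logger.warning("mixture collapse on log detected features; using all barcodes as high-coverage")
        high = np.ones(len(qc), dtype=bool)
        hc_mean = float(np.mean(logF))
    else:
        high = mix.posteriors[:, 1] > 0.5
        if not high.any():
            high = np.ones(len(qc), dtype=bool)
        hc_mean = float(mix.means[1])

    med = float(np.median(mito[high]))
    grid = np.arange(med, 1.0 + 1e-12, 0.001)
    if grid.size < 3:
        grid = np.array([med, med + 0.001, med + 0.002])
    counts_curve = np.array([(mito[high] <= t).sum() for t in grid])
    knee = knee_point(grid, counts_curve.astype(float))
    threshold = float(grid[0] if knee.degenerate else grid[knee.index])
    used_fallback = False
    if threshold > 0.3:
        used_fallback = True
        order = np.argsort(mito, kind="stable")
        x, y = mito[order], logF[order]
        try:
            fit = segmented_fit(x, y, k=1)
            threshold = float(min(fit.breakpoints_x[0], 0.3))
        except ValueError:
            logger.warning("fallback segmented fit failed; capping mito threshold at 0.3")
            threshold = 0.3
    return MitoThresholdResult(
        threshold=threshold,
        high_cov_component_mean=hc_mean,
        curve_thresholds=grid,
        curve_counts=counts_curve,
        used_fallback=used_fallback,
        high_cov_mask=high,
    )


def coding_fraction_filter(fractions: np.ndarray) -> np.ndarray:
    """Outlier mask for a fraction metric: |f - median| > 3 * Sn.

    Returns the boolean FAIL mask. Sn = 0 (constant fractions) fails
    nobody.
    """
    f = np.asarray(fractions, dtype=float)
    if f.size < 3:
        raise ValueError("coding_fraction_filter requires >= 3 barcodes")
    sn = sn_scale(f)
    if sn == 0:
        return np.zeros(f.size, dtype=bool)
    med = np.median(f)
    return np.abs(f - med) > 3 * sn


def depth_complexity_filter(qc: pd.DataFrame) -> np.ndarray:
    """Outlier mask on the depth-complexity relationship.

    Fits log detected features on log total UMIs with three breakpoints;
    barcodes whose residual deviates from the median residual by more than
    5 * Sn fail. Returns the boolean FAIL mask; a failed fit fails nobody.
    """
    if len(qc) < 50:
        raise ValueError("depth_complexity_filter requires >= 50 barcodes")
    logU = np.log(qc["total_umis"].to_numpy(dtype=float))
    logF = np.log(qc["n_features"].to_numpy(dtype=float))
    order = np.argsort(logU, kind="stable")
    min_points = max(5, int(0.02 * len(qc)))  # a trend fit, not an interpolator
    try:
        fit = segmented_fit(logU[order], logF[order], k=3, min_points=min_points)
    except ValueError as exc:
        logger.warning("depth-complexity fit failed (%s); no barcode fails", exc)
        return np.zeros(len(qc), dtype=bool)
    resid = logF - fit.predict(logU)
    sn = sn_scale(resid)
    med = np.median(resid)
    # absolute floor so an exactly piecewise-linear relationship (residuals
    # at numerical noise level) fails nobody
    return np.abs(resid - med) > max(5 * sn, 1e-8)


def run_stage2(
    qc: pd.DataFrame,
    seed: int = 0,
    use_exonic: bool = False,
    skip_coding: bool = False,
) -> tuple[pd.DataFrame, MitoThresholdResult]:
    """Apply the stage-2 filters sequentially (mito -> coding [-> exonic] -> residual).

    Each filter runs on the survivors of the previous one; failing
    barcodes get pass_stage2 = False and a fail_reason. Returns the
    updated table and the chosen mito threshold.
    """
    qc = qc.copy()
    alive = qc["pass_stage1"].to_numpy(copy=True)

    sub = qc.loc[alive]
    mres = mito_threshold(sub, seed=seed)
    fail = sub["frac_mito"].to_numpy() > mres.threshold
    _mark_fail(qc, sub.index[fail], "mito")
    alive &= ~qc.index.isin(sub.index[fail])

    if not skip_coding:
        sub = qc.loc[alive]
        fail = coding_fraction_filter(sub["frac_coding"].to_numpy())
        _mark_fail(qc, sub.index[fail], "coding")
        alive &= ~qc.index.isin(sub.index[fail])

    if use_exonic and "frac_exonic" in qc.columns:
        sub = qc.loc[alive]
        fail = coding_fraction_filter(sub["frac_exonic"].to_numpy())
        _mark_fail(qc, sub.index[fail], "exonic")
        alive &= ~qc.index.isin(sub.index[fail])

    sub = qc.loc[alive]
    fail = depth_complexity_filter(sub)
    _mark_fail(qc, sub.index[fail], "residual")
    alive &= ~qc.index.isin(sub.index[fail])

    qc["pass_stage2"] = alive & qc["pass_stage1"]
    return qc, mres


def _mark_fail(qc: pd.DataFrame, idx, reason: str) -> None:
    qc.loc[idx, "fail_reason"] = reason
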