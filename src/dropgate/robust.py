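"""Shared statistical primitives.

Robust scale (Sn), rolling means, continuous segmented (piecewise-linear)
least squares, unit-invariant knee detection, a two-component univariate
Gaussian mixture, and Matthews correlation. These are the numerical
workhorses behind every filtering stage; they are deterministic for fixed
inputs (and seed, where one is taken).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "sn_scale",
    "rolling_mean",
    "PiecewiseFit",
    "segmented_fit",
    "segmented_fit_path",
    "KneeResult",
    "knee_point",
    "Mixture2",
    "gaussian_mixture_2",
    "matthews_corr",
]

SN_CONSTANT = 1.1926  # asymptotic consistency constant for Gaussian data


def sn_scale(x: np.ndarray) -> float:
    """Rousseeuw–Croux Sn robust scale estimate.

    Sn = 1.1926 * lomed_i ( himed_{j != i} |x_i - x_j| ), where himed of m
    values is the floor(m/2)+1-th order statistic and lomed of n values is
    the floor((n+1)/2)-th. Returns 0 for constant input.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("sn_scale requires a 1-D vector of length >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("sn_scale requires finite values")
    n = x.size
    # high median over the n-1 values j != i  ->  0-based index (n-1)//2
    hi_idx = (n - 1) // 2
    inner = np.empty(n)
    # chunk the O(n^2) pairwise distances to bound memory
    chunk = max(1, int(4e6) // n)
    for start in range(0, n, chunk):
        stop = min(n, start + chunk)
        d = np.abs(x[start:stop, None] - x[None, :])
        rows = np.arange(stop - start)
        d[rows, np.arange(start, stop)] = np.inf  # exclude j == i
        inner[start:stop] = np.partition(d, hi_idx, axis=1)[:, hi_idx]
    # low median over n values -> 0-based index (n+1)//2 - 1 == (n-1)//2
    lo_idx = (n - 1) // 2
    return float(SN_CONSTANT * np.partition(inner, lo_idx)[lo_idx])


def rolling_mean(y: np.ndarray, bin: int) -> np.ndarray:
    """Centred moving average with shrunken edge windows.

    The window at position i covers [i - (bin-1)//2, i + bin//2], clipped to
    the vector, so the output has the same length as the input.
    """
    y = np.asarray(y, dtype=float)
    if bin < 1:
        raise ValueError("bin must be >= 1")
    if bin > y.size:
        raise ValueError("bin larger than input length")
    idx = np.arange(y.size)
    lo = np.maximum(0, idx - (bin - 1) // 2)
    hi = np.minimum(y.size, idx + bin // 2 + 1)
    cs = np.concatenate([[0.0], np.cumsum(y)])
    return (cs[hi] - cs[lo]) / (hi - lo)


@dataclass
class PiecewiseFit:
    """Continuous piecewise-linear least-squares fit.

    The fitted function is f(x) = a + b*x + sum_j c_j * max(x - t_j, 0),
    which is continuous at every breakpoint by construction. Per-segment
    slopes/intercepts are derived from (a, b, c) and the breakpoints.
    """

    breakpoints_x: np.ndarray
    segment_slopes: np.ndarray
    segment_intercepts: np.ndarray
    rmse: float

    @property
    def n_breakpoints(self) -> int:
        return len(self.breakpoints_x)

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        seg = np.searchsorted(self.breakpoints_x, x, side="right")
        return self.segment_intercepts[seg] + self.segment_slopes[seg] * x


def _hinge_basis(x: np.ndarray, bps: np.ndarray) -> np.ndarray:
    cols = [np.ones_like(x), x]
    for t in bps:
        cols.append(np.maximum(x - t, 0.0))
    return np.column_stack(cols)


def _fit_at(x: np.ndarray, y: np.ndarray, bps: np.ndarray) -> tuple[np.ndarray, float]:
    B = _hinge_basis(x, bps)
    beta, *_ = np.linalg.lstsq(B, y, rcond=None)
    resid = y - B @ beta
    return beta, float(np.sqrt(np.mean(resid**2)))


def _to_fit(x: np.ndarray, y: np.ndarray, bps: np.ndarray) -> PiecewiseFit:
    bps = np.sort(np.asarray(bps, dtype=float))
    beta, rmse = _fit_at(x, y, bps)
    a, b, c = beta[0], beta[1], beta[2:]
    slopes = b + np.concatenate([[0.0], np.cumsum(c)])
    intercepts = a - np.concatenate([[0.0], np.cumsum(c * bps)])
    return PiecewiseFit(bps, slopes, intercepts, rmse)


def _candidate_grid(x: np.ndarray, max_candidates: int = 200) -> np.ndarray:
    ux = np.unique(x)
    interior = ux[1:-1]
    if interior.size > max_candidates:
        take = np.linspace(0, interior.size - 1, max_candidates).round().astype(int)
        interior = interior[np.unique(take)]
    return interior


def _segments_valid(x: np.ndarray, bps: np.ndarray, min_points: int) -> bool:
    """Every segment delimited by the breakpoints holds >= min_points data points."""
    edges = np.searchsorted(x, np.sort(bps))
    counts = np.diff(np.concatenate([[0], edges, [x.size]]))
    return bool(np.all(counts >= min_points))


def _coordinate_descent(
    x: np.ndarray,
    y: np.ndarray,
    bps: np.ndarray,
    candidates: np.ndarray,
    min_points: int = 2,
    max_sweeps: int = 8,
) -> tuple[np.ndarray, float]:
    bps = np.sort(np.asarray(bps, dtype=float))
    _, best = _fit_at(x, y, bps)
    for _ in range(max_sweeps):
        moved = False
        for j in range(len(bps)):
            lo = bps[j - 1] if j > 0 else -np.inf
            hi = bps[j + 1] if j + 1 < len(bps) else np.inf
            opts = candidates[(candidates > lo) & (candidates < hi)]
            if opts.size == 0:
                continue
            for t in opts:
                if t == bps[j]:
                    continue
                trial = bps.copy()
                trial[j] = t
                if not _segments_valid(x, trial, min_points):
                    continue
                _, rmse = _fit_at(x, y, trial)
                if rmse < best - 1e-15:
                    best = rmse
                    bps = trial
                    moved = True
        if not moved:
            break
    return bps, best


def _local_refine(
    x: np.ndarray,
    y: np.ndarray,
    bps: np.ndarray,
    candidates: np.ndarray,
    min_points: int = 2,
) -> tuple[np.ndarray, float]:
    """Continuous refinement of each breakpoint between its neighbouring
    grid candidates (golden-section), one coordinate at a time."""
    from scipy.optimize import minimize_scalar

    bps = np.sort(np.asarray(bps, dtype=float))
    _, best = _fit_at(x, y, bps)
    step = np.median(np.diff(candidates)) if candidates.size > 1 else np.ptp(x) / 100
    for _ in range(12):
        moved = False
        for j in range(len(bps)):
            lo = max(bps[j] - step, bps[j - 1] if j > 0 else x[0])
            hi = min(bps[j] + step, bps[j + 1] if j + 1 < len(bps) else x[-1])
            if hi <= lo:
                continue

            def obj(t, j=j):
                trial = bps.copy()
                trial[j] = t
                if not _segments_valid(x, trial, min_points):
                    return 1e30  # finite so golden-section arithmetic stays defined
                return _fit_at(x, y, trial)[1]

            res = minimize_scalar(obj, bounds=(lo, hi), method="bounded",
                                  options={"xatol": 1e-10})
            if res.fun < best - 1e-15:
                best = float(res.fun)
                bps[j] = float(res.x)
                moved = True
        if not moved:
            break
    return bps, best


def segmented_fit_path(
    x: np.ndarray, y: np.ndarray, kmax: int, min_points: int = 2
) -> dict[int, PiecewiseFit]:
    """Fit continuous piecewise-linear models with 1..kmax breakpoints.

    Breakpoints are optimised over a grid of <=200 observed x values by
    coordinate descent, seeded both from evenly spaced quantile positions
    and from the best (k-1)-breakpoint solution with one inserted
    breakpoint. The insertion seeding makes RMSE non-increasing in k.
    Deterministic for fixed input.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if np.any(np.diff(x) < 0):
        raise ValueError("x must be ascending")
    if np.ptp(x) == 0:
        raise ValueError("degenerate x: all values equal")
    if kmax < 1:
        raise ValueError("kmax must be >= 1")
    if x.size < 2 * (kmax + 2):
        raise ValueError(f"need at least {2 * (kmax + 2)} points for k={kmax}")

    candidates = _candidate_grid(x)
    if candidates.size == 0:
        raise ValueError("not enough distinct x values for breakpoints")

    fits: dict[int, PiecewiseFit] = {}
    prev_bps: np.ndarray | None = None
    for k in range(1, kmax + 1):
        inits: list[np.ndarray] = []
        # evenly spaced candidate positions
        pos = np.linspace(0, candidates.size - 1, k + 2).round().astype(int)[1:-1]
        inits.append(candidates[np.unique(pos)] if len(np.unique(pos)) == k else candidates[pos])
        if prev_bps is not None:
            # insert the single best extra breakpoint into the previous solution
            best_ins, best_rmse = None, np.inf
            for t in candidates:
                if np.any(np.isclose(prev_bps, t)):
                    continue
                trial = np.sort(np.append(prev_bps, t))
                if not _segments_valid(x, trial, min_points):
                    continue
                _, rmse = _fit_at(x, y, trial)
                if rmse < best_rmse:
                    best_rmse, best_ins = rmse, trial
            if best_ins is not None:
                inits.append(best_ins)
        best_bps, best_rmse = None, np.inf
        for init in inits:
            if len(np.unique(init)) != k:
                continue
            bps, rmse = _coordinate_descent(x, y, init, candidates, min_points)
            if rmse < best_rmse:
                best_rmse, best_bps = rmse, bps
        if best_bps is None:  # degenerate grid; fall back to the sole option
            best_bps = candidates[np.linspace(0, candidates.size - 1, k + 2).round().astype(int)[1:-1]]
        best_bps, _ = _local_refine(x, y, best_bps, candidates, min_points)
        fits[k] = _to_fit(x, y, best_bps)
        prev_bps = fits[k].breakpoints_x
    return fits


def segmented_fit(
    x: np.ndarray, y: np.ndarray, k: int, min_points: int = 2
) -> PiecewiseFit:
    """Continuous piecewise-linear least squares with exactly k breakpoints.

    ``min_points`` forces every segment to contain at least that many data
    points, which keeps the fit from spending breakpoints on isolated
    outliers; the default (2) only rules out empty segments.
    """
    return segmented_fit_path(x, y, k, min_points)[k]


@dataclass
class KneeResult:
    index: int
    distance: float
    degenerate: bool


def knee_point(x: np.ndarray, y: np.ndarray) -> KneeResult:
    """Unit-invariant knee of a curve.

    Both axes are min–max scaled to [0, 1]; the knee is the point with the
    largest perpendicular distance to the chord joining the endpoints.
    Ties break to the smallest index. An (almost) collinear curve returns
    the first interior index with the degenerate flag set.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.shape != y.shape:
        raise ValueError("knee_point requires equal-length vectors of length >= 3")
    if np.any(np.diff(x) < 0):
        raise ValueError("x must be ascending")
    xr, yr = np.ptp(x), np.ptp(y)
    if xr == 0 or yr == 0:
        return KneeResult(1, 0.0, True)
    xs = (x - x[0]) / xr
    ys = (y - y.min()) / yr
    dx, dy = xs[-1] - xs[0], ys[-1] - ys[0]
    norm = np.hypot(dx, dy)
    dist = np.abs(dx * (ys[0] - ys) - (xs[0] - xs) * dy) / norm
    i = int(np.argmax(dist))
    if dist[i] < 1e-9:
        return KneeResult(1, float(dist[i]), True)
    return KneeResult(i, float(dist[i]), False)


@dataclass
class Mixture2:
    means: np.ndarray  # ordered ascending
    sds: np.ndarray
    weights: np.ndarray
    posteriors: np.ndarray  # n x 2, rows sum to 1
    loglik: float
    converged: bool

    @property
    def collapsed(self) -> bool:
        return bool(abs(self.means[1] - self.means[0]) < 1e-6 or self.weights.min() < 1e-3)


def _kmeans_1d(x: np.ndarray, iters: int = 50) -> np.ndarray:
    c = np.array([np.quantile(x, 0.25), np.quantile(x, 0.75)])
    if c[0] == c[1]:
        c = c + np.array([-1e-6, 1e-6])
    for _ in range(iters):
        lab = np.abs(x[:, None] - c[None, :]).argmin(axis=1)
        new = np.array([x[lab == j].mean() if np.any(lab == j) else c[j] for j in (0, 1)])
        if np.allclose(new, c):
            break
        c = new
    return c


def gaussian_mixture_2(
    x: np.ndarray, seed: int | np.random.Generator = 0
) -> Mixture2:
    """EM fit of a two-component univariate normal mixture.

    Five restarts (k-means centres, then jittered), tolerance 1e-8 on the
    log-likelihood, at most 1000 iterations. Components are ordered by
    mean; a collapse guard keeps each sd >= 1e-4 * sd(x).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 10:
        raise ValueError("gaussian_mixture_2 requires length >= 10")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sd_all = max(float(np.std(x)), 1e-12)
    min_sd = 1e-4 * sd_all
    base = _kmeans_1d(x)

    best: Mixture2 | None = None
    for restart in range(5):
        mu = base.copy()
        if restart > 0:
            mu = mu + rng.normal(0, 0.5 * sd_all, 2)
        sg = np.array([sd_all, sd_all])
        w = np.array([0.5, 0.5])
        ll_old = -np.inf
        converged = False
        resp = np.full((x.size, 2), 0.5)
        for _ in range(1000):
            # E step in log space for stability
            logp = (
                -0.5 * ((x[:, None] - mu[None, :]) / sg[None, :]) ** 2
                - np.log(sg[None, :])
                - 0.5 * np.log(2 * np.pi)
                + np.log(w[None, :])
            )
            m = logp.max(axis=1, keepdims=True)
            p = np.exp(logp - m)
            tot = p.sum(axis=1, keepdims=True)
            resp = p / tot
            ll = float(np.sum(m.ravel() + np.log(tot.ravel())))
            nk = resp.sum(axis=0)
            w = nk / x.size
            mu = (resp * x[:, None]).sum(axis=0) / np.maximum(nk, 1e-12)
            var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / np.maximum(nk, 1e-12)
            sg = np.maximum(np.sqrt(var), min_sd)
            if abs(ll - ll_old) < 1e-8:
                converged = True
                break
            ll_old = ll
        order = np.argsort(mu)
        fit = Mixture2(mu[order], sg[order], w[order], resp[:, order], ll, converged)
        if best is None or fit.loglik > best.loglik:
            best = fit
    assert best is not None
    return best


def matthews_corr(truth: np.ndarray, pred: np.ndarray) -> float:
    """Matthews correlation coefficient of two binary vectors.

    Returns 0 when any row or column marginal of the confusion table is
    zero (the undefined case).
    """
    truth = np.asarray(truth).astype(bool)
    pred = np.asarray(pred).astype(bool)
    if truth.size == 0:
        raise ValueError("empty input")
    if truth.shape != pred.shape:
        raise ValueError("length mismatch")
    tp = float(np.sum(truth & pred))
    tn = float(np.sum(~truth & ~pred))
    fp = float(np.sum(~truth & pred))
    fn = float(np.sum(truth & ~pred))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom)
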