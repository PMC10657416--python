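"""Stage 3: expression-based cluster validation.

Barcodes surviving the metric filters are clustered twice on an SVD
embedding of highly variable genes — once at low resolution (shallow) and
once at the highest resolution whose smallest cluster still holds at least
five barcodes (deep). Each deep cluster is tested for differential
expression against all barcodes outside its shallow cluster; clusters
without specific, significant markers (or with outlying mitochondrial or
ribosomal content) fail, and their barcodes fail stage 3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import svds
from scipy.stats import false_discovery_control, mannwhitneyu
from sklearn.neighbors import NearestNeighbors

from .matrix_io import CountMatrix
from .robust import sn_scale

logger = logging.getLogger("dropgate")

__all__ = [
    "select_hvgs",
    "embed",
    "ClusterFrame",
    "cluster_shallow_deep",
    "ClusterDEResult",
    "cluster_de",
    "evaluate_clusters",
    "run_stage3",
]

MIN_DEEP_CLUSTER = 5
SHALLOW_RESOLUTION = 0.1
DEEP_RESOLUTIONS = np.round(np.arange(0.2, 5.0 + 1e-9, 0.2), 10)
KNN_K = 20
SNN_PRUNE = 1 / 15
FDR_CUTOFF = 0.05


def select_hvgs(counts: CountMatrix, n: int = 5000) -> np.ndarray:
    """Rank genes by binomial deviance under a constant-proportion null.

    D_g = 2 * sum_i [ y_ig ln(y_ig / (n_i pi_g))
                      + (n_i - y_ig) ln((n_i - y_ig) / (n_i - n_i pi_g)) ],
    with pi_g the pooled proportion and 0 ln 0 = 0. Genes expressed at the
    same proportion everywhere have deviance ~0; the top ``n`` expressed
    genes are returned (all expressed genes if fewer).
    """
    csr = counts.counts.tocsr().astype(np.float64)
    depths = counts.barcode_totals().astype(np.float64)
    total = depths.sum()
    if total == 0:
        raise ValueError("all-zero count matrix")
    gene_sums = np.asarray(csr.sum(axis=1)).ravel()
    pi = gene_sums / total
    expressed = np.flatnonzero(gene_sums > 0)

    deviance = np.zeros(counts.n_genes)
    chunk = max(1, int(2e7) // max(counts.n_barcodes, 1))
    for start in range(0, expressed.size, chunk):
        genes = expressed[start : start + chunk]
        Y = np.asarray(csr[genes].todense())
        P = pi[genes][:, None]
        mu = depths[None, :] * P
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = np.where(Y > 0, Y * np.log(Y / mu), 0.0)
            rem = depths[None, :] - Y
            t2 = np.where(rem > 0, rem * np.log(rem / (depths[None, :] - mu)), 0.0)
        deviance[genes] = 2.0 * (t1 + t2).sum(axis=1)
    deviance = np.maximum(deviance, 0.0)

    k = min(n, expressed.size)
    ranked = expressed[np.argsort(-deviance[expressed], kind="stable")]
    return ranked[:k]


def lognormalize(counts: CountMatrix, genes: np.ndarray | None = None) -> np.ndarray:
    """Depth-normalise to the median depth, then log1p (dense, genes x barcodes)."""
    depths = counts.barcode_totals().astype(float)
    scale = np.median(depths) / depths
    sub = counts.counts if genes is None else counts.counts[genes]
    X = np.asarray(sub.todense(), dtype=float) * scale[None, :]
    return np.log1p(X)


def embed(
    counts: CountMatrix,
    hvgs: np.ndarray,
    n_components: int = 30,
    seed: int = 0,
) -> np.ndarray:
    """SVD embedding of normalised, log-transformed, standardised counts.

    Per-gene z-scores are clipped at |z| = 10 before a truncated SVD; the
    returned matrix is barcodes x components (U * S), with deterministic
    singular-vector signs for a fixed seed.
    """
    n_bc = counts.n_barcodes
    if n_bc < 2:
        raise ValueError("need at least 2 barcodes to embed")
    if n_bc <= n_components:
        n_components = max(1, n_bc - 1)
        logger.warning("fewer barcodes than components; reducing to %d", n_components)
    X = lognormalize(counts, hvgs)  # genes x barcodes
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = np.clip((X - mu) / sd, -10, 10).T  # barcodes x genes
    rng = np.random.default_rng(seed)
    v0 = rng.standard_normal(min(Z.shape))
    k = min(n_components, min(Z.shape) - 1)
    U, S, Vt = svds(Z, k=k, v0=v0)
    order = np.argsort(-S)
    U, S, Vt = U[:, order], S[order], Vt[order]
    # deterministic sign: largest-|loading| entry of each right vector positive
    for j in range(k):
        pivot = np.argmax(np.abs(Vt[j]))
        if Vt[j, pivot] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    return U * S[None, :]


@dataclass
class ClusterFrame:
    shallow_label: np.ndarray
    deep_label: np.ndarray
    deep_resolution: float
    shallow_of_deep: dict[int, int]
    embedding: np.ndarray


def _snn_graph(embedding: np.ndarray, k: int = KNN_K, prune: float = SNN_PRUNE) -> ig.Graph:
    n = embedding.shape[0]
    k_eff = min(k, n)
    nn = NearestNeighbors(n_neighbors=k_eff).fit(embedding)
    _, idx = nn.kneighbors(embedding)  # includes self
    rows = np.repeat(np.arange(n), k_eff)
    B = sp.csr_matrix(
        (np.ones(n * k_eff), (rows, idx.ravel())), shape=(n, n), dtype=np.float64
    )
    inter = (B @ B.T).tocoo()
    jac = inter.data / (2 * k_eff - inter.data)
    keep = (jac >= prune) & (inter.row < inter.col)
    edges = np.column_stack([inter.row[keep], inter.col[keep]])
    weights = jac[keep]
    g = ig.Graph(n=n, edges=[tuple(e) for e in edges])
    g.es["weight"] = list(weights)
    return g


def _partition(g: ig.Graph, resolution: float, seed: int) -> np.ndarray:
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    return np.asarray(part.membership)


def _attach_isolated(labels: np.ndarray, degrees: np.ndarray, embedding: np.ndarray) -> np.ndarray:
    """Reassign graph-isolated barcodes to the cluster of the nearest connected one."""
    labels = labels.copy()
    iso = np.flatnonzero(degrees == 0)
    conn = np.flatnonzero(degrees > 0)
    if iso.size == 0 or conn.size == 0:
        return labels
    nn = NearestNeighbors(n_neighbors=1).fit(embedding[conn])
    _, j = nn.kneighbors(embedding[iso])
    labels[iso] = labels[conn[j.ravel()]]
    return labels


def _relabel(labels: np.ndarray) -> np.ndarray:
    """Consecutive integer labels ordered by cluster size (desc), first index as tie-break."""
    uniq, first, counts_ = np.unique(labels, return_index=True, return_counts=True)
    order = np.lexsort((first, -counts_))
    mapping = {int(uniq[o]): i for i, o in enumerate(order)}
    return np.array([mapping[int(l)] for l in labels])


def cluster_shallow_deep(embedding: np.ndarray, seed: int = 0) -> ClusterFrame:
    """Shallow (resolution 0.1) and deep modularity clustering on an SNN graph.

    Deep labels use the highest resolution in 0.2..5.0 (step 0.2) whose
    smallest cluster still has >= 5 barcodes, falling back to the shallow
    labels if none qualifies. shallow_of_deep maps each deep cluster to the
    majority shallow label of its members.
    """
    n = embedding.shape[0]
    if n < 20:
        raise ValueError("cluster_shallow_deep requires >= 20 barcodes")
    g = _snn_graph(embedding)
    degrees = np.asarray(g.degree())

    shallow = _attach_isolated(_partition(g, SHALLOW_RESOLUTION, seed), degrees, embedding)
    shallow = _relabel(shallow)

    deep, deep_res = None, SHALLOW_RESOLUTION
    for res in DEEP_RESOLUTIONS:
        lab = _attach_isolated(_partition(g, float(res), seed), degrees, embedding)
        sizes = np.bincount(_relabel(lab))
        if sizes.min() >= MIN_DEEP_CLUSTER:
            deep, deep_res = _relabel(lab), float(res)
    if deep is None:
        logger.warning("no deep resolution kept clusters >= %d; using shallow labels", MIN_DEEP_CLUSTER)
        deep, deep_res = shallow.copy(), SHALLOW_RESOLUTION

    shallow_of_deep: dict[int, int] = {}
    for d in np.unique(deep):
        members = shallow[deep == d]
        vals, cnts = np.unique(members, return_counts=True)
        shallow_of_deep[int(d)] = int(vals[np.argmax(cnts)])
    return ClusterFrame(shallow, deep, deep_res, shallow_of_deep, embedding)


@dataclass
class ClusterDEResult:
    deep_label: int
    gene_idx: np.ndarray
    auc: np.ndarray
    log_fold_change: np.ndarray
    pct_in: np.ndarray
    pct_out: np.ndarray
    fdr: np.ndarray
    top_markers: list[int] = field(default_factory=list)
    min_fdr: float = 1.0
    avg_delta_pct: float = 0.0
    n_tested: int = 0
    n_significant: int = 0
    passed: bool = True
    fail_reason: str | None = None


def cluster_de(
    counts: CountMatrix,
    frame: ClusterFrame,
    deep_label: int,
    lognorm: np.ndarray | None = None,
) -> ClusterDEResult:
    """Wilcoxon rank-sum DE of one deep cluster vs barcodes outside its shallow cluster.

    Tests every gene with a nonzero count in the union of cluster and
    background; reports AUC, log fold change of normalised means, percent
    of barcodes expressing (nonzero count) in/out, and BH FDR. The top 10
    markers are ordered by (FDR asc, AUC desc) among positively enriched
    genes. An empty background yields an automatic pass ("no_background").
    """
    in_mask = frame.deep_label == deep_label
    n_in = int(in_mask.sum())
    if n_in < MIN_DEEP_CLUSTER:
        raise ValueError(f"deep cluster {deep_label} has {n_in} < {MIN_DEEP_CLUSTER} barcodes")
    bg_mask = frame.shallow_label != frame.shallow_of_deep[int(deep_label)]
    if not bg_mask.any():
        return ClusterDEResult(
            deep_label=deep_label,
            gene_idx=np.array([], int),
            auc=np.array([]), log_fold_change=np.array([]),
            pct_in=np.array([]), pct_out=np.array([]), fdr=np.array([]),
            passed=True, fail_reason="no_background",
        )
    if lognorm is None:
        lognorm = lognormalize(counts)
    csr = counts.counts.tocsr()
    union = in_mask | bg_mask
    nz = np.asarray((csr[:, np.flatnonzero(union)] > 0).sum(axis=1)).ravel()
    tested = np.flatnonzero(nz > 0)

    Xin = lognorm[np.ix_(tested, np.flatnonzero(in_mask))]
    Xout = lognorm[np.ix_(tested, np.flatnonzero(bg_mask))]
    n_out = Xout.shape[1]
    U, p = mannwhitneyu(Xin, Xout, axis=1, alternative="two-sided", method="asymptotic")
    auc = U / (n_in * n_out)
    lfc = Xin.mean(axis=1) - Xout.mean(axis=1)
    cin = np.asarray((csr[np.ix_(tested, np.flatnonzero(in_mask))] > 0).sum(axis=1)).ravel()
    cout = np.asarray((csr[np.ix_(tested, np.flatnonzero(bg_mask))] > 0).sum(axis=1)).ravel()
    pct_in = 100.0 * cin / n_in
    pct_out = 100.0 * cout / n_out
    fdr = false_discovery_control(np.clip(p, 0, 1), method="bh")
    sig = (fdr <= FDR_CUTOFF) & (lfc > 0)

    enriched = np.flatnonzero(lfc > 0)
    order = enriched[np.lexsort((-auc[enriched], fdr[enriched]))]
    top = order[:10]
    min_fdr = float(fdr[order[0]]) if order.size else 1.0
    avg_delta = float(np.mean(pct_in[top] - pct_out[top])) if top.size else 0.0

    return ClusterDEResult(
        deep_label=deep_label,
        gene_idx=tested,
        auc=auc,
        log_fold_change=lfc,
        pct_in=pct_in,
        pct_out=pct_out,
        fdr=fdr,
        top_markers=[int(tested[i]) for i in top],
        min_fdr=min_fdr,
        avg_delta_pct=avg_delta,
        n_tested=int(tested.size),
        n_significant=int(sig.sum()),
    )


def evaluate_clusters(
    results: list[ClusterDEResult],
    qc: pd.DataFrame,
    frame: ClusterFrame,
) -> dict[int, tuple[bool, str | None]]:
    """Per-deep-cluster pass/fail from the marker and significance rules.

    A cluster fails if any of:
      (a) a top-10 marker is expressed in at least 1 percentage point
          fewer of its barcodes than of the background;
      (b) top-10 averages: pct_in <= 30, pct_out >= 70, or
          (pct_in - pct_out) < 20 percentage points;
      (c) fewer than 1% of tested genes are significant;
      (d) -log10(min FDR) falls below a data-adaptive threshold regressed
          on the average marker pct difference (robust margin, with an
          absolute FDR floor of 0.05);
      (e) mean mito or ribo fraction exceeds the across-cluster median by
          more than 3 * Sn of the across-cluster means.
    Rules (d) and (e) need an across-cluster distribution and are skipped
    for a single deep cluster.
    """
    verdict: dict[int, tuple[bool, str | None]] = {}
    for res in results:
        d = int(res.deep_label)
        if res.fail_reason == "no_background":
            verdict[d] = (True, None)
            continue
        if res.top_markers:
            marker_pos = [np.flatnonzero(res.gene_idx == g)[0] for g in res.top_markers]
            pin = res.pct_in[marker_pos]
            pout = res.pct_out[marker_pos]
            if np.any(pin <= pout - 1.0):
                verdict[d] = (False, "cluster_marker")
                continue
            if pin.mean() <= 30.0 or pout.mean() >= 70.0 or (pin - pout).mean() < 20.0:
                verdict[d] = (False, "cluster_marker")
                continue
        else:
            verdict[d] = (False, "cluster_marker")
            continue
        if res.n_tested == 0 or res.n_significant < 0.01 * res.n_tested:
            verdict[d] = (False, "cluster_significance")
            continue
        verdict[d] = (True, None)

    evaluable = [r for r in results if r.fail_reason != "no_background"]
    if len(evaluable) >= 2:
        # rule (d): adaptive min-FDR significance threshold
        y = np.array([-np.log10(max(r.min_fdr, 1e-300)) for r in evaluable])
        x = np.array([r.avg_delta_pct for r in evaluable])
        if np.ptp(x) > 0:
            slope, inter = np.polyfit(x, y, 1)
            resid = y - (slope * x + inter)
            sn = sn_scale(resid) if resid.size >= 2 else 0.0
            floor = -np.log10(FDR_CUTOFF)
            for r, yi, xi, ri in zip(evaluable, y, x, resid):
                d = int(r.deep_label)
                if not verdict[d][0]:
                    continue
                thr = max(floor, (slope * xi + inter) - 2 * sn)
                if yi < thr:
                    verdict[d] = (False, "cluster_significance")
        # rule (e): outlying mito / ribo content
        mito = qc["frac_mito"].to_numpy(dtype=float)
        ribo = qc["frac_ribo"].to_numpy(dtype=float)
        for metric, vals in (("mito", mito), ("ribo", ribo)):
            means = {}
            for r in evaluable:
                members = frame.deep_label == r.deep_label
                means[int(r.deep_label)] = float(vals[members].mean())
            arr = np.array(list(means.values()))
            med = np.median(arr)
            sn = sn_scale(arr)
            if sn == 0:
                continue
            for d, m in means.items():
                if verdict[d][0] and m > med + 3 * sn:
                    verdict[d] = (False, "cluster_fraction")
    else:
        logger.info("single deep cluster: skipping adaptive significance and fraction rules")
    return verdict


def run_stage3(
    counts: CountMatrix,
    qc: pd.DataFrame,
    seed: int = 0,
    n_hvgs: int = 5000,
    n_components: int = 30,
) -> tuple[pd.DataFrame, ClusterFrame, list[ClusterDEResult]]:
    """Cluster stage-2 survivors and fail barcodes of invalid clusters."""
    qc = qc.copy()
    alive = qc["pass_stage2"].to_numpy()
    keep_ids = qc.index[alive]
    pos = {b: i for i, b in enumerate(counts.barcode_ids)}
    idx = np.array([pos[b] for b in keep_ids])
    sub = counts.subset_barcodes(idx)

    hvgs = select_hvgs(sub, n_hvgs)
    embedding = embed(sub, hvgs, n_components=n_components, seed=seed)
    frame = cluster_shallow_deep(embedding, seed=seed)
    lognorm = lognormalize(sub)
    results = [
        cluster_de(sub, frame, int(d), lognorm=lognorm) for d in np.unique(frame.deep_label)
    ]
    verdict = evaluate_clusters(results, qc.loc[keep_ids], frame)

    pass3 = np.zeros(len(qc), dtype=bool)
    for d, (ok, reason) in verdict.items():
        members = keep_ids[frame.deep_label == d]
        if ok:
            pass3[qc.index.isin(members)] = True
        else:
            qc.loc[members, "fail_reason"] = reason
    qc["pass_stage3"] = pass3 & qc["pass_stage2"].to_numpy()
    return qc, frame, results
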