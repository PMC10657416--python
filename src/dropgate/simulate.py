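"""Synthetic droplet datasets with known truth.

Emulates the count regimes a raw droplet experiment produces: an ambient
plateau of empty droplets, several cell populations with disjoint marker
blocks, high-mitochondrial debris, and (optionally) a planted dead-cell
population with more UMIs, a higher coding fraction, a depleted ribosomal
fraction and a dedicated death-signature gene block — the sign structure
the dead-cell score expects.

Depths are negative-binomial. Per-barcode gene-class fractions
(mitochondrial, ribosomal, non-coding) are beta-distributed, so quality
metrics have realistic spread; within each class, genes follow
Dirichlet-weighted type profiles. Everything is reproducible from the
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .matrix_io import CountMatrix, GeneClassAnnotation

__all__ = ["SimParams", "SimTruth", "simulate_dataset", "simulate_rank_curve"]

N_MARKERS_PER_TYPE = 20
N_DEATH_SIGNATURE = 50
N_MITO = 13
N_RIBO = 80


@dataclass
class SimParams:
    """Study conditions for the bundled simulation (defaults are the
    conditions every planted-truth test runs under)."""

    n_cell_types: int = 3
    cells_per_type: int = 500
    n_empty: int = 20_000
    n_debris: int = 150
    n_genes: int = 2000
    depth_cell_mean: float = 5000.0
    depth_cell_size: float = 4.0
    depth_empty_mean: float = 40.0
    depth_empty_size: float = 1.0
    frac_mito_live: tuple[float, float] = (2.0, 40.0)  # beta params, mean ~0.048
    frac_mito_debris: tuple[float, float] = (20.0, 20.0)  # mean 0.5
    frac_ribo_live: tuple[float, float] = (12.0, 48.0)  # mean 0.20 of non-mito
    frac_noncoding_live: tuple[float, float] = (8.0, 120.0)  # mean ~0.06 of non-mito
    frac_dead: float = 0.05
    dead_ribo_multiplier: float = 0.2
    dead_noncoding_multiplier: float = 0.8
    dead_depth_multiplier: float = 2.0
    ambient_mix: float = 0.05
    seed: int = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0 <= self.frac_dead < 1:
            raise ValueError("frac_dead must be in [0, 1)")
        if self.dead_ribo_multiplier >= 1:
            raise ValueError("dead_ribo_multiplier must be < 1")
        if self.dead_depth_multiplier < 1:
            raise ValueError("dead_depth_multiplier must be >= 1")
        if not 0 <= self.ambient_mix <= 1:
            raise ValueError("ambient_mix must be in [0, 1]")
        needed = N_MITO + N_RIBO + self.n_cell_types * N_MARKERS_PER_TYPE + N_DEATH_SIGNATURE + 50
        if self.n_genes < needed:
            raise ValueError(f"n_genes must be >= {needed} for the gene layout")


@dataclass
class SimTruth:
    """Per-barcode ground truth for a simulated dataset."""

    table: pd.DataFrame  # index barcode_id; columns: klass, cell_type
    planted_knee_rank: int


def _negbin(rng: np.random.Generator, mean: float, size: float, n: int) -> np.ndarray:
    p = size / (size + mean)
    return rng.negative_binomial(size, p, n)


def _gene_layout(p: SimParams) -> dict:
    """Deterministic gene index blocks: mito | ribo | markers | death | noncoding | background."""
    idx = 0
    layout = {}
    layout["mito"] = np.arange(idx, idx + N_MITO); idx += N_MITO
    layout["ribo"] = np.arange(idx, idx + N_RIBO); idx += N_RIBO
    layout["markers"] = [
        np.arange(idx + t * N_MARKERS_PER_TYPE, idx + (t + 1) * N_MARKERS_PER_TYPE)
        for t in range(p.n_cell_types)
    ]
    idx += p.n_cell_types * N_MARKERS_PER_TYPE
    layout["death"] = np.arange(idx, idx + N_DEATH_SIGNATURE); idx += N_DEATH_SIGNATURE
    n_noncoding = max(1, int(0.1 * p.n_genes))
    layout["noncoding"] = np.arange(idx, idx + n_noncoding); idx += n_noncoding
    layout["background"] = np.arange(idx, p.n_genes)
    # "rest" = coding non-mito non-ribo non-noncoding genes
    layout["rest"] = np.concatenate(layout["markers"] + [layout["death"], layout["background"]])
    return layout


def _gene_annotation(p: SimParams, layout: dict) -> tuple[list[str], list[str], GeneClassAnnotation]:
    ids = [f"SIMG{i:07d}" for i in range(p.n_genes)]
    names = [f"GENE{i}" for i in range(p.n_genes)]
    for j, g in enumerate(layout["mito"]):
        names[g] = f"MT-SIM{j + 1}"
    for j, g in enumerate(layout["ribo"]):
        names[g] = (f"RPS{j + 1}" if j % 2 == 0 else f"RPL{j + 1}")
    for t, block in enumerate(layout["markers"]):
        for j, g in enumerate(block):
            names[g] = f"MKR{t}G{j}"
    for j, g in enumerate(layout["death"]):
        names[g] = f"DTH{j}"
    for j, g in enumerate(layout["noncoding"]):
        names[g] = f"LINC{j + 1:05d}"
    is_mito = np.zeros(p.n_genes, bool); is_mito[layout["mito"]] = True
    is_ribo = np.zeros(p.n_genes, bool); is_ribo[layout["ribo"]] = True
    is_coding = np.ones(p.n_genes, bool); is_coding[layout["noncoding"]] = False
    ann = GeneClassAnnotation(
        is_mito=is_mito, is_ribo=is_ribo, is_coding=is_coding,
        organism="custom", id_scheme="symbol",
        detected={"mito": True, "ribo": True, "coding": True},
    )
    return ids, names, ann


def _rest_profiles(p: SimParams, layout: dict, rng: np.random.Generator) -> np.ndarray:
    """Per-type expression profile over the 'rest' (coding, non-ribo) genes.

    Each type's marker block takes a dedicated ~12% share of the rest mass;
    the death-signature block is silent in live cells.
    """
    rest = layout["rest"]
    profiles = np.zeros((p.n_cell_types, rest.size))
    pos = {g: i for i, g in enumerate(rest)}
    bg_pos = np.array([pos[g] for g in layout["background"]])
    death_pos = np.array([pos[g] for g in layout["death"]])
    for t in range(p.n_cell_types):
        prof = np.zeros(rest.size)
        prof[bg_pos] = rng.gamma(2.0, 1.0, bg_pos.size)
        prof /= prof.sum()
        prof *= 0.88
        mk_pos = np.array([pos[g] for g in layout["markers"][t]])
        prof[mk_pos] = rng.dirichlet(np.full(N_MARKERS_PER_TYPE, 5.0)) * 0.12
        prof[death_pos] = 0.0
        profiles[t] = prof / prof.sum()
    return profiles


def _dead_rest_profile(profile: np.ndarray, layout: dict, rest: np.ndarray) -> np.ndarray:
    """Dead variant of a rest profile: an 8% death-signature share."""
    pos = {g: i for i, g in enumerate(rest)}
    death_pos = np.array([pos[g] for g in layout["death"]])
    prof = profile.copy() * 0.92
    prof[death_pos] = 0.08 / N_DEATH_SIGNATURE
    return prof / prof.sum()


def _block_profile(rng: np.random.Generator, size: int) -> np.ndarray:
    w = rng.gamma(5.0, 1.0, size)
    return w / w.sum()


def _draw_group(
    rng: np.random.Generator,
    depths: np.ndarray,
    class_probs: np.ndarray,  # n x 4: mito, ribo, noncoding, rest
    block_idx: list[np.ndarray],
    block_profiles: list[np.ndarray],
    n_genes: int,
) -> sp.csr_matrix:
    """Counts for one group: per-barcode class split, categorical draws within class."""
    n = depths.size
    depths = depths.astype(np.int64)
    class_counts = rng.multinomial(depths, class_probs)
    rows_all, cols_all = [], []
    for b in range(4):
        cnt = class_counts[:, b]
        total = int(cnt.sum())
        if total == 0:
            continue
        rows_all.append(np.repeat(np.arange(n), cnt))
        cols_all.append(block_idx[b][rng.choice(block_idx[b].size, total, p=block_profiles[b])])
    mat = sp.coo_matrix(
        (
            np.ones(sum(r.size for r in rows_all), dtype=np.int64),
            (np.concatenate(rows_all), np.concatenate(cols_all)),
        ),
        shape=(n, n_genes),
    )
    return mat.tocsr()


def _class_probs(
    rng: np.random.Generator,
    n: int,
    mito_beta: tuple[float, float],
    ribo_beta: tuple[float, float],
    nc_beta: tuple[float, float],
    ribo_mult: float = 1.0,
    nc_mult: float = 1.0,
) -> np.ndarray:
    """Per-barcode (mito, ribo, noncoding, rest) probabilities.

    Ribosomal and non-coding fractions are defined relative to the
    non-mitochondrial mass; multipliers rescale the dead-cell draws.
    """
    m = rng.beta(*mito_beta, n)
    r = np.clip(rng.beta(*ribo_beta, n) * ribo_mult, 0, 0.95)
    c = np.clip(rng.beta(*nc_beta, n) * nc_mult, 0, None)
    c = np.minimum(c, 0.99 - r)
    probs = np.column_stack([m, r * (1 - m), c * (1 - m), (1 - r - c) * (1 - m)])
    return probs / probs.sum(axis=1, keepdims=True)


def simulate_dataset(p: SimParams) -> tuple[CountMatrix, GeneClassAnnotation, SimTruth]:
    """Generate a full raw droplet dataset with per-barcode truth labels.

    Barcode classes: ``cell`` (one of n_cell_types populations), ``empty``
    (ambient draws at low depth), ``debris`` (cell-like with a high
    mitochondrial fraction) and ``dead_cell`` (converted from cells at
    rate ``frac_dead``: deeper, ribo-depleted, fewer non-coding UMIs, a
    death-signature block). Zero-total barcodes are dropped, mirroring the
    reader. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(p.seed)
    layout = _gene_layout(p)
    ids, names, ann = _gene_annotation(p, layout)
    rest_profiles = _rest_profiles(p, layout, rng)
    ribo_profile = _block_profile(rng, N_RIBO)
    nc_profile = _block_profile(rng, layout["noncoding"].size)
    mito_profile = _block_profile(rng, N_MITO)
    blocks_idx = [layout["mito"], layout["ribo"], layout["noncoding"], layout["rest"]]

    ambient_rest = rest_profiles.mean(axis=0)

    n_cells = p.n_cell_types * p.cells_per_type
    cell_types = np.repeat(np.arange(p.n_cell_types), p.cells_per_type)
    n_dead = int(round(p.frac_dead * n_cells))
    dead_pick = rng.choice(n_cells, size=n_dead, replace=False) if n_dead else np.array([], int)
    is_dead = np.zeros(n_cells, bool)
    is_dead[dead_pick] = True

    blocks: list[sp.csr_matrix] = []
    klass: list[str] = []
    ctype: list[int] = []

    def emit(m, depths, probs, rest_prof, label, t):
        blocks.append(
            _draw_group(rng, depths, probs, blocks_idx,
                        [mito_profile, ribo_profile, nc_profile, rest_prof], p.n_genes)
        )
        klass.extend([label] * m)
        ctype.extend([t] * m)

    for t in range(p.n_cell_types):
        rest_prof = (1 - p.ambient_mix) * rest_profiles[t] + p.ambient_mix * ambient_rest
        dead_prof = _dead_rest_profile(rest_prof, layout, layout["rest"])
        sel = cell_types == t
        m_live = int(np.sum(sel & ~is_dead))
        m_dead = int(np.sum(sel & is_dead))
        if m_live:
            depths = _negbin(rng, p.depth_cell_mean, p.depth_cell_size, m_live)
            probs = _class_probs(rng, m_live, p.frac_mito_live, p.frac_ribo_live, p.frac_noncoding_live)
            emit(m_live, depths, probs, rest_prof, "cell", t)
        if m_dead:
            depths = _negbin(rng, p.depth_cell_mean * p.dead_depth_multiplier, p.depth_cell_size, m_dead)
            probs = _class_probs(
                rng, m_dead, p.frac_mito_live, p.frac_ribo_live, p.frac_noncoding_live,
                ribo_mult=p.dead_ribo_multiplier, nc_mult=p.dead_noncoding_multiplier,
            )
            emit(m_dead, depths, probs, dead_prof, "dead_cell", t)

    if p.n_debris:
        t_debris = rng.integers(0, p.n_cell_types, p.n_debris)
        for t in range(p.n_cell_types):
            m = int(np.sum(t_debris == t))
            if m == 0:
                continue
            rest_prof = (1 - p.ambient_mix) * rest_profiles[t] + p.ambient_mix * ambient_rest
            depths = _negbin(rng, p.depth_cell_mean * 0.5, p.depth_cell_size, m)
            probs = _class_probs(rng, m, p.frac_mito_debris, p.frac_ribo_live, p.frac_noncoding_live)
            emit(m, depths, probs, rest_prof, "debris", t)

    if p.n_empty:
        depths = _negbin(rng, p.depth_empty_mean, p.depth_empty_size, p.n_empty)
        probs = _class_probs(rng, p.n_empty, p.frac_mito_live, p.frac_ribo_live, p.frac_noncoding_live)
        emit(p.n_empty, depths, probs, ambient_rest, "empty", -1)

    counts = sp.hstack([b.T for b in blocks]).tocsr()  # genes x barcodes
    n_bc = counts.shape[1]
    order = rng.permutation(n_bc)
    counts = counts[:, order]
    klass_arr = np.array(klass)[order]
    ctype_arr = np.array(ctype)[order]
    barcode_ids = [f"BC{i:07d}" for i in range(n_bc)]

    cm = CountMatrix(counts, ids, barcode_ids, names)
    truth = pd.DataFrame({"klass": klass_arr, "cell_type": ctype_arr}, index=barcode_ids)

    totals = cm.barcode_totals()
    keep = totals > 0
    cm = cm.subset_barcodes(keep)
    truth = truth.loc[np.array(barcode_ids)[keep]]

    planted_knee_rank = int(np.isin(truth["klass"], ["cell", "dead_cell", "debris"]).sum())
    return cm, ann, SimTruth(truth, planted_knee_rank)


def simulate_rank_curve(
    n_cells: int,
    n_empty: int,
    depth_cell_mean: float = 5000.0,
    depth_cell_size: float = 2.0,
    depth_empty_mean: float = 40.0,
    depth_empty_size: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, int]:
    """Per-barcode totals only (no genes), for fast rank-filter testing.

    Returns (totals, planted_knee_rank) with planted_knee_rank = n_cells.
    """
    rng = np.random.default_rng(seed)
    cells = _negbin(rng, depth_cell_mean, depth_cell_size, n_cells)
    empties = _negbin(rng, depth_empty_mean, depth_empty_size, n_empty) if n_empty else np.array([], int)
    totals = np.concatenate([cells, empties])
    rng.shuffle(totals)
    return totals, n_cells
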