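"""Count-matrix I/O and gene-class detection.

Reads the CellRanger/STARsolo raw-output convention (Matrix Market triplet
`matrix.mtx` plus `features.tsv` and `barcodes.tsv`, optionally gzipped) or
a dense TSV, into a sparse genes-by-barcodes container. Gene classes
(mitochondrial, ribosomal, protein-coding) are detected from bundled
per-organism lookup tables and symbol patterns, covering the common model
organisms and annotation schemes; user-supplied lists override detection.
"""

from __future__ import annotations

import gzip
import json
import logging
import re
from dataclasses import dataclass, field
from importlib import resources as _resources
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger("dropgate")

__all__ = [
    "CountMatrix",
    "GeneClassAnnotation",
    "FormatError",
    "GeneClassDetectionError",
    "read_counts",
    "write_counts",
    "detect_gene_classes",
    "write_report",
]


class FormatError(ValueError):
    """Malformed input file (bad header, dimension mismatch, negative entries)."""


class GeneClassDetectionError(ValueError):
    """No gene class could be detected and no user lists were supplied."""


@dataclass
class CountMatrix:
    """Sparse genes-by-barcodes UMI count matrix with identifiers."""

    counts: sp.csr_matrix
    feature_ids: list[str]
    barcode_ids: list[str]
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.nnz and self.counts.data.min() < 0:
            raise FormatError("negative entries in count matrix")
        if self.counts.shape[0] != len(self.feature_ids):
            raise FormatError(
                f"{self.counts.shape[0]} matrix rows but {len(self.feature_ids)} feature ids"
            )
        if self.counts.shape[1] != len(self.barcode_ids):
            raise FormatError(
                f"{self.counts.shape[1]} matrix columns but {len(self.barcode_ids)} barcode ids"
            )
        if self.feature_names is not None and len(self.feature_names) != len(self.feature_ids):
            raise FormatError("feature_names length does not match feature_ids")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise FormatError("feature ids are not unique")
        if len(set(self.barcode_ids)) != len(self.barcode_ids):
            raise FormatError("barcode ids are not unique")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_barcodes(self) -> int:
        return self.counts.shape[1]

    def barcode_totals(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def feature_counts_per_barcode(self) -> np.ndarray:
        """Number of detected features (nonzero genes) per barcode."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def subset_barcodes(self, index) -> "CountMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return CountMatrix(
            counts=self.counts[:, index],
            feature_ids=self.feature_ids,
            barcode_ids=[self.barcode_ids[i] for i in index],
            feature_names=self.feature_names,
        )

    def drop_zero_barcodes(self) -> "CountMatrix":
        totals = self.barcode_totals()
        keep = totals > 0
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info("dropping %d barcodes with zero total UMIs", n_drop)
            return self.subset_barcodes(keep)
        return self


@dataclass
class GeneClassAnnotation:
    """Per-gene class membership flags.

    ``detected`` records which classes were successfully assigned from the
    bundled tables/patterns (or user lists); the coding filter is skipped
    downstream when coding status could not be determined.
    """

    is_mito: np.ndarray
    is_ribo: np.ndarray
    is_coding: np.ndarray
    organism: str = "custom"
    id_scheme: str = "custom"
    is_exonic: np.ndarray | None = None
    detected: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.is_mito)
        if len(self.is_ribo) != n or len(self.is_coding) != n:
            raise ValueError("class flag vectors must all have the same length")


# ---------------------------------------------------------------------------
# bundled lookup tables


def _load_table(name: str) -> list[str]:
    text = _resources.files("dropgate.resources").joinpath(name).read_text()
    return [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]


_MITO_TABLES = {
    ("human", "symbol"): "human_mito_symbols.txt",
    ("human", "ensembl"): "human_mito_ensembl.txt",
    ("mouse", "symbol"): "mouse_mito_symbols.txt",
    ("mouse", "ensembl"): "mouse_mito_ensembl.txt",
    ("rat", "symbol"): "rat_mito_symbols.txt",
    ("zebrafish", "symbol"): "zebrafish_mito_symbols.txt",
    ("fly", "symbol"): "fly_mito_symbols.txt",
    ("worm", "symbol"): "worm_mito_symbols.txt",
}

_ENSEMBL_PREFIXES = {
    "ENSMUSG": "mouse",
    "ENSRNOG": "rat",
    "ENSDARG": "zebrafish",
    "ENSG": "human",
}

_RIBO_PATTERN = re.compile(r"^(RP[SL]\d|Rp[sl]\d|rp[sl]\d)")
_MITO_PREFIX = re.compile(r"^(MT-|mt-|Mt-|mt:)")


def detect_gene_classes(
    feature_ids: list[str],
    feature_names: list[str] | None = None,
    organism_hint: str | None = None,
    mito_genes: list[str] | None = None,
    ribo_genes: list[str] | None = None,
    coding_genes: list[str] | None = None,
) -> GeneClassAnnotation:
    """Flag mitochondrial, ribosomal and protein-coding genes.

    Detection is table- and pattern-based and deterministic: exact matches
    against bundled per-organism mito tables (ids and names), RPS/RPL-style
    prefixes for ribosomal proteins, and a bundled non-coding symbol
    pattern table whose complement defines coding genes. User-supplied
    lists override detection for their class.

    Raises :class:`GeneClassDetectionError` when nothing matches and no
    user list is given.
    """
    if not feature_ids:
        raise ValueError("empty feature list")
    ids = list(feature_ids)
    names = list(feature_names) if feature_names else ids
    n = len(ids)

    # id scheme from id shape
    id_scheme = "symbol"
    organism = organism_hint or "custom"
    for prefix, org in _ENSEMBL_PREFIXES.items():
        if sum(i.startswith(prefix) for i in ids) > n / 2:
            id_scheme = "ensembl"
            if organism_hint is None:
                organism = org
            break
    else:
        if all(i.isdigit() for i in ids[: min(n, 50)]):
            id_scheme = "entrez"
        elif any(i.startswith("FBgn") for i in ids):
            id_scheme, organism = "ensembl", organism_hint or "fly"
        elif any(i.startswith("WBGene") for i in ids):
            id_scheme, organism = "ensembl", organism_hint or "worm"

    detected: dict = {}

    # --- mitochondrial ---
    if mito_genes is not None:
        universe = set(mito_genes)
        is_mito = np.array([(i in universe) or (s in universe) for i, s in zip(ids, names)])
        detected["mito"] = bool(is_mito.any())
    else:
        best_hits = np.zeros(n, dtype=bool)
        best_key: tuple[str, str] | None = None
        for key, fname in _MITO_TABLES.items():
            if organism_hint and key[0] != organism_hint:
                continue
            table = set(_load_table(fname))
            hits = np.array([(i in table) or (s in table) for i, s in zip(ids, names)])
            if hits.sum() > best_hits.sum():
                best_hits, best_key = hits, key
        is_mito = best_hits
        if best_key is not None and organism == "custom":
            organism = best_key[0]
        if not is_mito.any():  # symbol-prefix fallback
            is_mito = np.array([bool(_MITO_PREFIX.match(s)) for s in names])
        detected["mito"] = bool(is_mito.any())

    # --- ribosomal proteins ---
    if ribo_genes is not None:
        universe = set(ribo_genes)
        is_ribo = np.array([(i in universe) or (s in universe) for i, s in zip(ids, names)])
    else:
        is_ribo = np.array([bool(_RIBO_PATTERN.match(s)) for s in names])
    detected["ribo"] = bool(is_ribo.any())

    # --- protein-coding ---
    if coding_genes is not None:
        universe = set(coding_genes)
        is_coding = np.array([(i in universe) or (s in universe) for i, s in zip(ids, names)])
        detected["coding"] = bool(is_coding.any())
    elif feature_names or id_scheme == "symbol":
        patterns = [re.compile(p) for p in _load_table("noncoding_patterns.txt")]
        is_coding = np.array([not any(p.search(s) for p in patterns) for s in names])
        # coding from symbols is only meaningful when mito/ribo anchoring worked
        detected["coding"] = bool(detected["mito"] or detected["ribo"])
        if not detected["coding"]:
            is_coding = np.zeros(n, dtype=bool)
    else:
        is_coding = np.zeros(n, dtype=bool)
        detected["coding"] = False

    if not any(detected.values()) and mito_genes is None and ribo_genes is None and coding_genes is None:
        raise GeneClassDetectionError(
            "no gene class could be detected from ids/names; supply mito_genes/"
            "ribo_genes/coding_genes lists to annotate manually"
        )

    if organism not in {"human", "mouse", "rat", "fly", "worm", "zebrafish"}:
        organism = "custom"
    return GeneClassAnnotation(
        is_mito=is_mito,
        is_ribo=is_ribo,
        is_coding=is_coding,
        organism=organism,
        id_scheme=id_scheme,
        detected=detected,
    )


# ---------------------------------------------------------------------------
# readers / writers


def _open_maybe_gz(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _find(dirpath: Path, stem_options: list[str]) -> Path:
    for stem in stem_options:
        for suffix in ("", ".gz"):
            p = dirpath / (stem + suffix)
            if p.exists():
                return p
    raise FileNotFoundError(f"none of {stem_options} found in {dirpath}")


def read_counts(
    path: str | Path,
    format: str = "mtx_triplet",
    transpose: bool | None = None,
    drop_zero: bool = True,
) -> CountMatrix:
    """Read an unfiltered count matrix.

    ``mtx_triplet`` expects the 10x raw-output layout: a directory holding
    ``matrix.mtx``, ``features.tsv`` (or ``genes.tsv``) and
    ``barcodes.tsv``, each optionally gzipped. ``dense_tsv`` expects the
    first column to be gene ids, the header row barcode ids. The matrix is
    oriented genes x barcodes internally; a transposed MTX file is detected
    by comparing dimensions with the id-list lengths unless ``transpose``
    is set explicitly. Barcodes with zero total UMIs are dropped (logged).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "mtx_triplet":
        dirpath = path if path.is_dir() else path.parent
        mtx_path = path if path.is_file() else _find(dirpath, ["matrix.mtx"])
        feat_path = _find(dirpath, ["features.tsv", "genes.tsv"])
        bc_path = _find(dirpath, ["barcodes.tsv"])
        try:
            mat = scipy.io.mmread(str(mtx_path))  # handles .gz itself
        except Exception as exc:  # noqa: BLE001 - rewrap with file context
            raise FormatError(f"malformed Matrix Market file {mtx_path}: {exc}") from exc
        feats = pd.read_csv(feat_path, sep="\t", header=None, dtype=str)
        feature_ids = feats[0].tolist()
        feature_names = feats[1].tolist() if feats.shape[1] > 1 else None
        with _open_maybe_gz(bc_path) as fh:
            barcode_ids = [ln.strip().split("\t")[0] for ln in fh if ln.strip()]
        mat = sp.csr_matrix(mat)
        if mat.nnz and mat.data.min() < 0:
            raise FormatError(f"negative entries in {mtx_path}")
        if transpose is None:
            transpose = mat.shape == (len(barcode_ids), len(feature_ids)) and (
                mat.shape[0] != len(feature_ids) or mat.shape[1] != len(barcode_ids)
            )
        if transpose:
            mat = mat.T.tocsr()
        if mat.shape != (len(feature_ids), len(barcode_ids)):
            raise FormatError(
                f"{mtx_path}: matrix is {mat.shape} but features/barcodes have "
                f"{len(feature_ids)}/{len(barcode_ids)} entries"
            )
        cm = CountMatrix(mat, feature_ids, barcode_ids, feature_names)
    elif format == "dense_tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if (df.values < 0).any():
            raise FormatError(f"negative entries in {path}")
        cm = CountMatrix(
            sp.csr_matrix(df.values),
            df.index.astype(str).tolist(),
            df.columns.astype(str).tolist(),
        )
    else:
        raise ValueError(f"unknown format {format!r}")
    return cm.drop_zero_barcodes() if drop_zero else cm


def write_counts(cm: CountMatrix, dirpath: str | Path) -> None:
    """Write the 10x raw-output triplet layout (uncompressed)."""
    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    counts = cm.counts.astype(np.int64)
    scipy.io.mmwrite(str(dirpath / "matrix.mtx"), counts.tocoo(), field="integer")
    names = cm.feature_names or cm.feature_ids
    with open(dirpath / "features.tsv", "w") as fh:
        for fid, name in zip(cm.feature_ids, names):
            fh.write(f"{fid}\t{name}\tGene Expression\n")
    with open(dirpath / "barcodes.tsv", "w") as fh:
        fh.writelines(b + "\n" for b in cm.barcode_ids)


def write_report(
    qc: pd.DataFrame,
    dead,
    outdir: str | Path,
    summary: dict | None = None,
) -> dict:
    """Emit the per-barcode TSV, the passing-barcode list and a JSON summary.

    ``dead`` is a DeadCellResult or None; when absent the JSON summary
    records ``"dead_cell_run": "not_run"``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = qc.copy()
    if dead is not None and getattr(dead, "per_barcode", None) is not None:
        table = table.join(dead.per_barcode, how="left")
    table.to_csv(outdir / "barcode_qc.tsv", sep="\t", index_label="barcode_id")

    pass_cols = [c for c in ("pass_stage3", "pass_stage2", "pass_stage1") if c in qc.columns]
    passing = qc.index[qc[pass_cols[0]]].tolist() if pass_cols else []
    with open(outdir / "passing_barcodes.txt", "w") as fh:
        fh.writelines(b + "\n" for b in passing)

    payload = dict(summary or {})
    payload.setdefault("n_passing", len(passing))
    if dead is None:
        payload["dead_cell_run"] = "not_run"
    else:
        payload["dead_cell_run"] = "success" if dead.success else "failed"
        if not dead.success and dead.halted_reason:
            payload["dead_cell_halted_reason"] = dead.halted_reason
        payload["n_dead"] = int(dead.n_dead) if dead.success else 0
    with open(outdir / "run_summary.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return payload


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
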