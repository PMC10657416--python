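"""End-to-end orchestration of the four filtering stages.

All randomness flows from a single master seed; survivor sets are strictly
nested across stages; every chosen threshold is logged and written into the
run report so a run can be reproduced from its artifacts.
"""

from __future__ import annotations

import logging
import tomllib
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._version import __version__
from .dead_cells import DeadCellResult, flag_dead
from .expression_filter import run_stage3
from .matrix_io import CountMatrix, detect_gene_classes, read_counts, write_report
from .metric_filter import compute_qc_metrics, run_stage2
from .rank_filter import apply_rank_filter, rank_threshold

logger = logging.getLogger("dropgate")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Tunables for a full run; defaults are the documented stage defaults."""

    input_path: str | None = None
    input_format: str = "mtx_triplet"  # or dense_tsv
    organism_hint: str | None = None
    modality: str = "single_cell"  # or single_nucleus
    seed: int = 0
    out_dir: str | None = None
    run_dead: bool = True
    force_dead_on_nuclei: bool = False
    use_exonic: bool = False
    n_hvgs: int = 5000
    n_components: int = 30
    dead_n_hvgs: int = 2000
    dead_n_components: int = 100

    @classmethod
    def from_toml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass
class PipelineResult:
    qc: pd.DataFrame
    dead: DeadCellResult | None
    summary: dict
    counts: CountMatrix | None = None


def run_pipeline(
    config: PipelineConfig,
    counts: CountMatrix | None = None,
    annotation=None,
) -> PipelineResult:
    """Run stages 1 -> 2 -> 3 (-> 4) and write report files.

    ``counts`` (and optionally ``annotation``) may be passed in memory;
    otherwise they are read from ``config.input_path`` and detected from
    the feature table. Stage 4 runs only for single-cell modality unless
    forced: the dead-cell score is calibrated on whole cells and is not
    advised for nuclei.
    """
    if counts is None:
        if config.input_path is None:
            raise ValueError("no input: set config.input_path or pass counts")
        counts = read_counts(config.input_path, config.input_format)
    if annotation is None:
        annotation = detect_gene_classes(
            counts.feature_ids, counts.feature_names, organism_hint=config.organism_hint
        )

    # stage 1: barcode-rank threshold
    fit = rank_threshold(counts.barcode_totals(), counts.barcode_ids)
    logger.info(
        "stage 1: k=%d threshold_rank=%d (bin=%d%s)",
        fit.selected_k, fit.threshold_rank, fit.smoothing_bin,
        ", weak knee" if fit.weak_knee else "",
    )
    stage1 = apply_rank_filter(counts, fit)

    # stage 2: quality-metric filters
    skip_coding = not annotation.detected.get("coding", True)
    if skip_coding:
        logger.warning("coding status undetected; skipping the coding-fraction filter")
    qc = compute_qc_metrics(stage1, annotation)
    qc, mres = run_stage2(qc, seed=config.seed, use_exonic=config.use_exonic, skip_coding=skip_coding)
    logger.info(
        "stage 2: mito threshold %.3f%s; %d/%d pass",
        mres.threshold, " (fallback)" if mres.used_fallback else "",
        int(qc["pass_stage2"].sum()), len(qc),
    )

    # stage 3: expression-based cluster validation
    qc, frame, de_results = run_stage3(
        stage1, qc, seed=config.seed, n_hvgs=config.n_hvgs, n_components=config.n_components
    )
    logger.info(
        "stage 3: %d deep clusters at resolution %.1f; %d/%d pass",
        len(np.unique(frame.deep_label)), frame.deep_resolution,
        int(qc["pass_stage3"].sum()), len(qc),
    )

    # stage 4: optional dead-cell flagging
    dead = None
    if config.run_dead:
        if config.modality == "single_nucleus" and not config.force_dead_on_nuclei:
            logger.warning(
                "dead-cell flagging skipped for single-nucleus input (force_dead_on_nuclei to override)"
            )
        else:
            dead = flag_dead(
                stage1, qc, seed=config.seed,
                n_hvgs=config.dead_n_hvgs, n_components=config.dead_n_components,
            )
            logger.info(
                "stage 4: %s (%d dead)",
                "success" if dead.success else f"failed ({dead.halted_reason})",
                dead.n_dead,
            )

    summary = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items() if k not in ("input_path", "out_dir")},
        "stage1": {
            "threshold_rank": fit.threshold_rank,
            "selected_k": fit.selected_k,
            "smoothing_bin": fit.smoothing_bin,
            "weak_knee": fit.weak_knee,
            "n_input_barcodes": counts.n_barcodes,
            "n_pass": int(qc["pass_stage1"].sum()),
        },
        "stage2": {
            "mito_threshold": mres.threshold,
            "mito_used_fallback": mres.used_fallback,
            "n_pass": int(qc["pass_stage2"].sum()),
        },
        "stage3": {
            "deep_resolution": frame.deep_resolution,
            "n_deep_clusters": int(len(np.unique(frame.deep_label))),
            "n_pass": int(qc["pass_stage3"].sum()),
        },
    }
    if config.out_dir is not None:
        write_report(qc, dead, config.out_dir, summary)
    return PipelineResult(qc=qc, dead=dead, summary=summary, counts=stage1)
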