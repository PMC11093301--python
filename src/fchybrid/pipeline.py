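"""End-to-end orchestration: time series -> FC records -> CV -> reports."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np

from .cohort import CohortTruth, simulate_cohort
from .connectivity import build_frequency_grid, dynamic_fc, static_fc
from .io_core import (
    Phenotype,
    PipelineConfig,
    RoiTimeSeries,
    SubjectRecord,
    ValidationError,
    read_manifest,
    read_phenotypes,
    read_time_series,
)

logger = logging.getLogger("fchybrid")

__all__ = ["compute_records", "records_from_files", "simulate_records", "config_for_truth"]


def compute_records(
    series: Sequence[RoiTimeSeries],
    phenotypes: Sequence[Phenotype],
    config: PipelineConfig,
    *,
    static_only: bool = False,
    dynamic_only: bool = False,
) -> list[SubjectRecord]:
    """Compute both FC representations for every subject with a phenotype.

    ``static_only`` / ``dynamic_only`` skip the other representation (the
    skipped tensor is zero-filled, keeping record shapes consistent).
    """
    pheno_by_id = {p.subject_id: p for p in phenotypes}
    missing = [ts.subject_id for ts in series if ts.subject_id not in pheno_by_id]
    if missing:
        raise ValidationError(f"no phenotype row for subject(s) {missing[:5]}")
    grid = build_frequency_grid(config)
    records: list[SubjectRecord] = []
    for ts in series:
        r = ts.n_roi
        if static_only:
            s = static_fc(ts).matrix
            d = np.zeros((r, r, grid.n_bands))
        elif dynamic_only:
            s = np.eye(r)
            d = dynamic_fc(ts, grid, config).tensor
        else:
            s = static_fc(ts).matrix
            d = dynamic_fc(ts, grid, config).tensor
        records.append(
            SubjectRecord(phenotype=pheno_by_id[ts.subject_id], static_fc=s, dynamic_fc=d)
        )
        logger.debug("computed FC for %s", ts.subject_id)
    return records


def records_from_files(
    manifest_path: str | Path,
    phenotype_path: str | Path,
    config: PipelineConfig,
    **kwargs,
) -> list[SubjectRecord]:
    """Read a cohort from a manifest + phenotype CSV and compute its FC records."""
    manifest = read_manifest(manifest_path)
    phenotypes = read_phenotypes(phenotype_path)
    series = [
        read_time_series(path, config, subject_id=sid)
        for sid, path in manifest.items()
    ]
    return compute_records(series, phenotypes, config, **kwargs)


def config_for_truth(truth: CohortTruth, **overrides) -> PipelineConfig:
    """A PipelineConfig whose geometry matches a synthetic cohort's truth."""
    params = dict(
        n_roi=truth.n_roi,
        tr=truth.tr,
        freq_lo=truth.freq_lo,
        freq_hi=truth.freq_hi,
    )
    params.update(overrides)
    return PipelineConfig(**params)


def simulate_records(
    truth: CohortTruth, seed: int, config: PipelineConfig | None = None
) -> tuple[list[SubjectRecord], PipelineConfig]:
    """Generate a synthetic cohort in memory and compute its FC records."""
    if config is None:
        config = config_for_truth(truth)
    series, phenotypes = simulate_cohort(truth, seed)
    return compute_records(series, phenotypes, config), config
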