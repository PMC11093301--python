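"""Domain types, configuration and file I/O shared by all pipeline stages.

The pipeline consumes ROI (region-of-interest) BOLD time series that have
already been atlas-extracted and band-pass filtered, plus a phenotype table
carrying the diagnostic label and the five Social Responsiveness Scale (SRS)
subscale scores.  Raw NIfTI preprocessing is out of scope.

Conventions
-----------
* ROI indexing is 0-based everywhere; atlas names are attached only when
  reports are rendered (see :func:`atlas_labels`).
* Time-series files hold one subject each: rows are time points, columns are
  ROIs, tab- or comma-separated.  A manifest CSV maps ``subject_id -> path``.
* Functional-connectivity tensors are stored in HDF5, one group per subject.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("fchybrid")

SRS_SUBSCALES = ("awareness", "cognition", "communication", "motivation", "mannerisms")

__all__ = [
    "SRS_SUBSCALES",
    "RoiTimeSeries",
    "Phenotype",
    "PipelineConfig",
    "SubjectRecord",
    "ValidationError",
    "DimensionError",
    "ParseError",
    "SchemaError",
    "read_time_series",
    "read_phenotypes",
    "read_manifest",
    "write_tensor_store",
    "read_tensor_store",
    "load_config",
    "atlas_labels",
]


class ValidationError(ValueError):
    """Input violates a documented invariant."""


class DimensionError(ValidationError):
    """Array dimensions disagree with the configuration or with each other."""


class ParseError(ValidationError):
    """A cell of a delimited text file could not be parsed."""


class SchemaError(ValidationError):
    """A tabular file is missing required columns."""


@dataclass(frozen=True)
class RoiTimeSeries:
    """One subject's preprocessed BOLD signals: ``data`` is T x R (time x ROI)."""

    subject_id: str
    data: np.ndarray
    sampling_interval: float  # TR, seconds

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise DimensionError(
                f"{self.subject_id}: time series must be 2-D, got {data.ndim}-D"
            )
        t, r = data.shape
        if t < 30:
            raise ValidationError(f"{self.subject_id}: need >= 30 time points, got {t}")
        if r < 2:
            raise ValidationError(f"{self.subject_id}: need >= 2 ROIs, got {r}")
        if not np.isfinite(data).all():
            raise ValidationError(f"{self.subject_id}: non-finite values in time series")
        dead = np.flatnonzero(data.max(axis=0) == data.min(axis=0))
        if dead.size:
            raise ValidationError(
                f"{self.subject_id}: constant (zero-variance) ROI column(s) {dead.tolist()}"
            )
        if self.sampling_interval <= 0:
            raise ValidationError("sampling_interval (TR) must be positive")
        object.__setattr__(self, "data", data)

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_roi(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class Phenotype:
    """Diagnostic label (ASD=1, TC=0) and the five SRS subscale scores."""

    subject_id: str
    label: int
    srs: np.ndarray  # order: awareness, cognition, communication, motivation, mannerisms
    sex: str | None = None
    age: float | None = None
    site: str | None = None

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValidationError(
                f"{self.subject_id}: label must be 0 (TC) or 1 (ASD), got {self.label!r}"
            )
        srs = np.asarray(self.srs, dtype=float).reshape(-1)
        if srs.shape != (5,):
            raise ValidationError(
                f"{self.subject_id}: SRS must have exactly 5 entries, got {srs.size}"
            )
        if not np.isfinite(srs).all():
            raise ValidationError(f"{self.subject_id}: non-finite SRS entry")
        object.__setattr__(self, "srs", srs)


@dataclass
class PipelineConfig:
    """All tunable parameters of the pipeline, with the published defaults.

    ``freq_lo``/``freq_hi`` bound the analysis band (Hz) and ``n_bands`` is the
    number of contiguous frequency segments the band is partitioned into for
    the wavelet-coherence dynamic connectivity.
    """

    n_roi: int = 116
    tr: float = 2.0  # sampling interval, seconds
    freq_lo: float = 0.01
    freq_hi: float = 0.08
    n_bands: int = 40
    band_spacing: str = "linear"  # or "log"
    morlet_omega0: float = 6.0
    smooth_time_factor: float = 1.0  # boxcar length ~ factor * scale (samples)
    smooth_scale_bins: int = 3
    pca_variance_threshold: float = 0.99
    learning_rate: float = 1e-4
    max_epochs: int = 50
    batch_size: int = 8
    dropout: float = 0.5
    leaky_slope: float = 0.01
    svm_C: float = 1.0
    n_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValidationError("tr must be positive")
        if not (0 < self.freq_lo < self.freq_hi):
            raise ValidationError("require 0 < freq_lo < freq_hi")
        if self.n_bands < 2:
            raise ValidationError("n_bands must be >= 2")
        if not (0 < self.pca_variance_threshold <= 1):
            raise ValidationError("pca_variance_threshold must be in (0, 1]")
        if self.n_folds < 2:
            raise ValidationError("n_folds must be >= 2")
        if self.band_spacing not in ("linear", "log"):
            raise ValidationError("band_spacing must be 'linear' or 'log'")


@dataclass(frozen=True)
class SubjectRecord:
    """Per-subject bundle consumed by training: phenotype + both FC representations."""

    phenotype: Phenotype
    static_fc: np.ndarray  # R x R
    dynamic_fc: np.ndarray  # R x R x Q

    def __post_init__(self) -> None:
        s = np.asarray(self.static_fc, dtype=float)
        d = np.asarray(self.dynamic_fc, dtype=float)
        if s.ndim != 2 or s.shape[0] != s.shape[1]:
            raise DimensionError("static_fc must be square R x R")
        if d.ndim != 3 or d.shape[0] != d.shape[1]:
            raise DimensionError("dynamic_fc must be R x R x Q")
        if d.shape[0] != s.shape[0]:
            raise DimensionError(
                f"static_fc R={s.shape[0]} but dynamic_fc R={d.shape[0]} "
                f"for subject {self.subject_id}"
            )
        object.__setattr__(self, "static_fc", s)
        object.__setattr__(self, "dynamic_fc", d)

    @property
    def subject_id(self) -> str:
        return self.phenotype.subject_id


def read_time_series(path: str | Path, config: PipelineConfig,
                     subject_id: str | None = None) -> RoiTimeSeries:
    """Read one subject's delimited time-series file (rows=time, cols=ROIs).

    The column count must equal ``config.n_roi``; any non-numeric cell or
    constant column is rejected rather than coerced.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep=None, engine="python", header=None,
                            comment="#", skip_blank_lines=True)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: cannot parse delimited text: {exc}") from exc
    values = frame.to_numpy()
    if values.dtype == object or not np.issubdtype(values.dtype, np.number):
        for (row, col), cell in np.ndenumerate(values):
            try:
                float(cell)
            except (TypeError, ValueError):
                raise ParseError(
                    f"{path}: non-numeric cell {cell!r} at row {row}, column {col}"
                ) from None
        values = values.astype(float)
    if values.shape[1] != config.n_roi:
        raise DimensionError(
            f"{path}: expected {config.n_roi} ROI columns, found {values.shape[1]}"
        )
    sid = subject_id if subject_id is not None else path.stem
    return RoiTimeSeries(subject_id=sid, data=values, sampling_interval=config.tr)


def read_phenotypes(path: str | Path) -> list[Phenotype]:
    """Read the phenotype CSV (subject_id, label, five SRS subscales, optional metadata)."""
    path = Path(path)
    frame = pd.read_csv(path)
    required = ["subject_id", "label", *SRS_SUBSCALES]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    if frame["subject_id"].duplicated().any():
        dupes = frame.loc[frame["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValidationError(f"{path}: duplicate subject_id(s) {dupes}")
    out: list[Phenotype] = []
    for _, row in frame.iterrows():
        label_raw = row["label"]
        if label_raw not in (0, 1):
            raise ValidationError(
                f"{path}: subject {row['subject_id']}: label {label_raw!r} not in {{0, 1}}"
            )
        out.append(
            Phenotype(
                subject_id=str(row["subject_id"]),
                label=int(label_raw),
                srs=np.array([row[c] for c in SRS_SUBSCALES], dtype=float),
                sex=str(row["sex"]) if "sex" in frame.columns and pd.notna(row.get("sex")) else None,
                age=float(row["age"]) if "age" in frame.columns and pd.notna(row.get("age")) else None,
                site=str(row["site"]) if "site" in frame.columns and pd.notna(row.get("site")) else None,
            )
        )
    return out


def read_manifest(path: str | Path) -> dict[str, Path]:
    """Read a manifest CSV mapping subject_id -> time-series file path.

    Relative paths are resolved against the manifest's own directory.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    if not {"subject_id", "path"} <= set(frame.columns):
        raise SchemaError(f"{path}: manifest needs columns subject_id, path")
    base = path.parent
    out: dict[str, Path] = {}
    for _, row in frame.iterrows():
        p = Path(row["path"])
        out[str(row["subject_id"])] = p if p.is_absolute() else base / p
    return out


def write_tensor_store(records: Sequence[SubjectRecord], path: str | Path) -> None:
    """Write subject records to an HDF5 store, one group per subject.

    Each group holds datasets ``static_fc`` (R x R), ``dynamic_fc`` (R x R x Q),
    ``srs`` (5,) and ``label`` (scalar).  The round trip through
    :func:`read_tensor_store` is lossless to full floating precision.
    """
    records = list(records)
    if not records:
        raise ValidationError("cannot write an empty tensor store")
    shapes = {(r.static_fc.shape, r.dynamic_fc.shape) for r in records}
    if len(shapes) > 1:
        raise ValidationError(f"inconsistent FC shapes across subjects: {sorted(shapes)}")
    ids = [r.subject_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate subject_id among records")
    with h5py.File(path, "w") as f:
        f.attrs["n_subjects"] = len(records)
        f.attrs["subject_order"] = [r.subject_id for r in records]
        for rec in records:
            g = f.create_group(rec.subject_id)
            g.create_dataset("static_fc", data=rec.static_fc)
            g.create_dataset("dynamic_fc", data=rec.dynamic_fc)
            g.create_dataset("srs", data=rec.phenotype.srs)
            g.create_dataset("label", data=rec.phenotype.label)
            for key in ("sex", "age", "site"):
                val = getattr(rec.phenotype, key)
                if val is not None:
                    g.attrs[key] = val


def read_tensor_store(path: str | Path) -> list[SubjectRecord]:
    """Read back a tensor store written by :func:`write_tensor_store`."""
    out: list[SubjectRecord] = []
    with h5py.File(path, "r") as f:
        order = [s if isinstance(s, str) else s.decode() for s in f.attrs["subject_order"]]
        for sid in order:
            g = f[sid]
            pheno = Phenotype(
                subject_id=sid,
                label=int(g["label"][()]),
                srs=np.asarray(g["srs"]),
                sex=g.attrs.get("sex"),
                age=g.attrs.get("age"),
                site=g.attrs.get("site"),
            )
            out.append(
                SubjectRecord(
                    phenotype=pheno,
                    static_fc=np.asarray(g["static_fc"]),
                    dynamic_fc=np.asarray(g["dynamic_fc"]),
                )
            )
    return out


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from an optional YAML file plus overrides."""
    params: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValidationError(f"{path}: config file must hold a mapping")
        params.update(loaded)
    params.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(params) - known
    if unknown:
        raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
    config = PipelineConfig(**params)
    logger.info("resolved config: %s", dataclasses.asdict(config))
    return config


def atlas_labels(n_roi: int) -> list[str]:
    """Atlas region names for reporting.

    Returns the AAL-116 names when ``n_roi == 116``; otherwise generic
    ``ROI_<i>`` placeholders.  Computation never depends on these labels.
    """
    if n_roi == 116:
        text = (importlib.resources.files("fchybrid") / "data" / "aal116.txt").read_text()
        labels = [line.strip() for line in text.splitlines() if line.strip()]
        if len(labels) != 116:  # pragma: no cover - packaging error guard
            raise RuntimeError("bundled AAL label table is corrupt")
        return labels
    return [f"ROI_{i}" for i in range(n_roi)]
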