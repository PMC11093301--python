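"""Synthetic two-group cohorts with planted, recoverable connectivity effects.

The generator emulates the inputs the pipeline expects from a real
resting-state study: per-subject ROI time series that are band-limited to the
analysis band (BOLD signals band-pass filtered to 0.01-0.08 Hz), and SRS
subscale scores.  Ground truth is planted and fully documented:

* every ROI signal is Gaussian noise brick-wall filtered to the analysis band;
* each planted ROI pair additionally shares a common narrowband latent signal
  confined to ``planted_band``, mixed in with a weight chosen so the expected
  coherence inside that band matches the group's coupling target — for a
  flat-spectrum construction the weight obeys β² = c/(1-c) · W_sub/W_full,
  where c is the target coherence and W_* are bandwidths;
* SRS subscales are drawn from group-specific normals (TC mean 50, SD 10, a
  T-score-like convention) separated by a configurable standardized effect.

Everything is reproducible from a single master seed via spawned
``numpy.random.SeedSequence`` streams, one per subject.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io_core import Phenotype, RoiTimeSeries, SRS_SUBSCALES, ValidationError

__all__ = ["CohortTruth", "generate_subject", "simulate_cohort", "generate_cohort"]

_SRS_BASE_MEAN = 50.0
_SRS_SD = 10.0


@dataclass(frozen=True)
class CohortTruth:
    """Planted ground truth for a synthetic cohort.

    Defaults describe the desk-scale study the test suite exercises: 20 ROIs,
    150 time points at TR = 2 s, 100 subjects per group, one strongly coupled
    ROI pair in a narrow sub-band, and a one-SD SRS group difference.
    """

    n_roi: int = 20
    T: int = 150
    tr: float = 2.0
    n_asd: int = 100
    n_tc: int = 100
    freq_lo: float = 0.01
    freq_hi: float = 0.08
    planted_pairs: tuple[tuple[int, int], ...] = ((2, 7),)
    planted_band: tuple[float, float] = (0.04, 0.05)
    coupling_asd: float = 0.9
    coupling_tc: float = 0.1
    srs_effect: float = 1.0

    def __post_init__(self) -> None:
        for i, j in self.planted_pairs:
            if i == j:
                raise ValidationError(f"planted pair ({i}, {j}) must be off-diagonal")
            if not (0 <= i < self.n_roi and 0 <= j < self.n_roi):
                raise ValidationError(f"planted pair ({i}, {j}) outside 0..{self.n_roi - 1}")
        lo, hi = self.planted_band
        if not (self.freq_lo <= lo < hi <= self.freq_hi):
            raise ValidationError(
                f"planted band {self.planted_band} must lie inside "
                f"[{self.freq_lo}, {self.freq_hi}]"
            )
        for name in ("coupling_asd", "coupling_tc"):
            c = getattr(self, name)
            if not (0.0 <= c <= 0.999):
                raise ValidationError(f"{name} must be in [0, 0.999], got {c}")
        if self.n_asd < 1 or self.n_tc < 1:
            raise ValidationError("need at least one subject per group")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortTruth":
        with open(path) as fh:
            raw = json.load(fh)
        raw["planted_pairs"] = tuple(tuple(p) for p in raw["planted_pairs"])
        raw["planted_band"] = tuple(raw["planted_band"])
        return cls(**raw)


def _bandlimited_noise(rng: np.random.Generator, t: int, tr: float,
                       f_lo: float, f_hi: float) -> np.ndarray:
    """Unit-variance Gaussian noise brick-wall filtered to [f_lo, f_hi]."""
    white = rng.standard_normal(t)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(t, d=tr)
    mask = (freqs >= f_lo) & (freqs <= f_hi)
    if not mask.any():
        raise ValidationError(
            f"band [{f_lo}, {f_hi}] Hz contains no FFT bin for T={t}, TR={tr}"
        )
    spectrum[~mask] = 0.0
    signal = np.fft.irfft(spectrum, n=t)
    sd = signal.std()
    if sd == 0:  # pragma: no cover - brick-wall of nonzero noise
        raise RuntimeError("degenerate band-limited signal")
    return signal / sd


def _mixing_weight(coherence: float, band_width: float, full_width: float) -> float:
    """β so a shared unit-variance narrowband latent yields the target in-band coherence."""
    if coherence <= 0.0:
        return 0.0
    return float(np.sqrt(coherence / (1.0 - coherence) * band_width / full_width))


def generate_subject(
    truth: CohortTruth,
    group: str,
    rng: np.random.Generator | int,
    subject_id: str = "synthetic",
) -> tuple[RoiTimeSeries, Phenotype]:
    """Draw one subject (time series + phenotype) for ``group`` in {"ASD", "TC"}."""
    if group not in ("ASD", "TC"):
        raise ValidationError(f"group must be 'ASD' or 'TC', got {group!r}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    coupling = truth.coupling_asd if group == "ASD" else truth.coupling_tc
    data = np.column_stack(
        [
            _bandlimited_noise(rng, truth.T, truth.tr, truth.freq_lo, truth.freq_hi)
            for _ in range(truth.n_roi)
        ]
    )
    band_lo, band_hi = truth.planted_band
    beta = _mixing_weight(coupling, band_hi - band_lo, truth.freq_hi - truth.freq_lo)
    for i, j in truth.planted_pairs:
        latent = _bandlimited_noise(rng, truth.T, truth.tr, band_lo, band_hi)
        data[:, i] += beta * latent
        data[:, j] += beta * latent
    data /= data.std(axis=0, keepdims=True)

    shift = (truth.srs_effect * _SRS_SD) if group == "ASD" else 0.0
    srs = rng.normal(_SRS_BASE_MEAN + shift, _SRS_SD, size=5)
    pheno = Phenotype(
        subject_id=subject_id,
        label=1 if group == "ASD" else 0,
        srs=srs,
        sex=str(rng.choice(["M", "F"])),
        age=float(rng.uniform(8, 30)),
        site="SYN",
    )
    ts = RoiTimeSeries(subject_id=subject_id, data=data, sampling_interval=truth.tr)
    return ts, pheno


def simulate_cohort(
    truth: CohortTruth, seed: int
) -> tuple[list[RoiTimeSeries], list[Phenotype]]:
    """Generate the full cohort in memory, one spawned RNG stream per subject."""
    streams = np.random.SeedSequence(seed).spawn(truth.n_asd + truth.n_tc)
    series: list[RoiTimeSeries] = []
    phenos: list[Phenotype] = []
    for idx, stream in enumerate(streams):
        group = "ASD" if idx < truth.n_asd else "TC"
        sid = f"{'asd' if group == 'ASD' else 'tc'}{idx:04d}"
        ts, pheno = generate_subject(
            truth, group, np.random.default_rng(stream), subject_id=sid
        )
        series.append(ts)
        phenos.append(pheno)
    return series, phenos


def generate_cohort(truth: CohortTruth, seed: int, out_dir: str | Path) -> dict[str, Path]:
    """Write the cohort to disk: per-subject TSVs, manifest.csv, phenotypes.csv, truth.json.

    Returns the paths of the three index files.
    """
    out_dir = Path(out_dir)
    ts_dir = out_dir / "timeseries"
    try:
        ts_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create cohort directory {ts_dir}: {exc}") from exc
    series, phenos = simulate_cohort(truth, seed)
    manifest_rows = []
    pheno_rows = []
    for ts, pheno in zip(series, phenos):
        path = ts_dir / f"{ts.subject_id}.tsv"
        np.savetxt(path, ts.data, delimiter="\t", fmt="%.10g")
        manifest_rows.append({"subject_id": ts.subject_id,
                              "path": str(path.relative_to(out_dir))})
        pheno_rows.append(
            {
                "subject_id": pheno.subject_id,
                "label": pheno.label,
                **dict(zip(SRS_SUBSCALES, pheno.srs)),
                "sex": pheno.sex,
                "age": pheno.age,
                "site": pheno.site,
            }
        )
    manifest_path = out_dir / "manifest.csv"
    pheno_path = out_dir / "phenotypes.csv"
    truth_path = out_dir / "truth.json"
    pd.DataFrame(manifest_rows).to_csv(manifest_path, index=False)
    pd.DataFrame(pheno_rows).to_csv(pheno_path, index=False)
    truth.to_json(truth_path)
    return {"manifest": manifest_path, "phenotypes": pheno_path, "truth": truth_path}
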