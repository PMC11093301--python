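"""Static and dynamic (wavelet-coherence) functional connectivity.

Static FC is the Pearson correlation between two ROI time series:

    r(x, y) = sum_t (x_t - x̄)(y_t - ȳ) / sqrt(sum_t (x_t - x̄)² · sum_t (y_t - ȳ)²)

Dynamic FC localizes co-oscillation in time-frequency space.  For each ROI
pair the squared wavelet coherence

    R_xy(s, τ) = |S(W_x W_y*)|² / ( S(|W_x|²) · S(|W_y|²) )

is computed on a grid of Q Morlet scales spanning the analysis band, where
S(·) is a separable moving-average smoother over time and scale (without
smoothing the ratio is identically 1 for any pair).  Each Q x T coherence map
is then reduced along time by principal component analysis; the leading
component (a Q-vector per pair) populates the R x R x Q dynamic-FC tensor, so
the tensor shape is independent of scan length T.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .io_core import (
    DimensionError,
    PipelineConfig,
    RoiTimeSeries,
    ValidationError,
)

logger = logging.getLogger("fchybrid")

__all__ = [
    "StaticFC",
    "FrequencyGrid",
    "DynamicFC",
    "static_fc",
    "build_frequency_grid",
    "cwt",
    "cross_wavelet",
    "smooth",
    "wavelet_coherence",
    "pca_reduce_time",
    "dynamic_fc",
]


@dataclass(frozen=True)
class StaticFC:
    """R x R symmetric Pearson matrix with unit diagonal."""

    subject_id: str
    matrix: np.ndarray


@dataclass(frozen=True)
class FrequencyGrid:
    """Q contiguous frequency segments over the analysis band.

    ``edges`` (Q+1, Hz) delimit the segments, ``centers`` (Q, Hz) are segment
    midpoints, and ``scales`` (Q, samples) are the Morlet scales realizing each
    center frequency via f = ω0 / (2π s TR).  Scales decrease as frequency
    increases.
    """

    centers: np.ndarray
    edges: np.ndarray
    scales: np.ndarray
    omega0: float
    tr: float

    @property
    def n_bands(self) -> int:
        return self.centers.size

    def band_edges(self, q: int) -> tuple[float, float]:
        return float(self.edges[q]), float(self.edges[q + 1])


@dataclass(frozen=True)
class DynamicFC:
    """R x R x Q tensor of leading PCA components of pairwise wavelet coherence.

    ``k_used[i, j]`` is the minimal number of components needed to retain the
    configured variance fraction for that pair; only the first component is
    stored.  ``variance_retained[i, j]`` is the cumulative eigenvalue fraction
    at ``k_used``.
    """

    subject_id: str
    tensor: np.ndarray
    k_used: np.ndarray
    variance_retained: np.ndarray


def static_fc(ts: RoiTimeSeries) -> StaticFC:
    """Pearson-correlation static FC; symmetric, unit diagonal, entries in [-1, 1]."""
    dead = np.flatnonzero(ts.data.max(axis=0) == ts.data.min(axis=0))
    if dead.size:
        raise ValidationError(
            f"{ts.subject_id}: zero-variance ROI column(s) {dead.tolist()}; "
            "Pearson correlation undefined"
        )
    mat = np.corrcoef(ts.data, rowvar=False)
    mat = np.clip((mat + mat.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(mat, 1.0)
    return StaticFC(subject_id=ts.subject_id, matrix=mat)


def build_frequency_grid(config: PipelineConfig) -> FrequencyGrid:
    """Partition [freq_lo, freq_hi] into Q segments and derive Morlet scales.

    Spacing is linear by default; ``config.band_spacing = "log"`` selects
    geometric spacing.  Centers are segment midpoints.
    """
    q = config.n_bands
    if q < 2:
        raise ValidationError("n_bands must be >= 2")
    if config.band_spacing == "linear":
        edges = np.linspace(config.freq_lo, config.freq_hi, q + 1)
        centers = (edges[:-1] + edges[1:]) / 2.0
    else:
        edges = np.geomspace(config.freq_lo, config.freq_hi, q + 1)
        centers = np.sqrt(edges[:-1] * edges[1:])
    nyquist = 0.5 / config.tr
    if config.freq_hi > nyquist:
        warnings.warn(
            f"freq_hi={config.freq_hi} Hz exceeds the Nyquist frequency "
            f"{nyquist} Hz for TR={config.tr} s",
            stacklevel=2,
        )
    scales = config.morlet_omega0 / (2.0 * np.pi * centers * config.tr)
    return FrequencyGrid(centers=centers, edges=edges, scales=scales,
                         omega0=config.morlet_omega0, tr=config.tr)


def cwt(signal: np.ndarray, grid: FrequencyGrid, config: PipelineConfig) -> np.ndarray:
    """Continuous wavelet transform with the analytic Morlet mother wavelet.

    Returns the Q x T complex coefficient matrix W(s, τ) evaluated at the grid
    scales and every sample translation.  Implemented in the frequency domain:
    the signal's FFT is multiplied, scale by scale, by the conjugate Fourier
    transform of the scaled Morlet (only positive frequencies — the analytic
    wavelet), after zero-padding to the next power of two to curb wraparound.
    """
    x = np.asarray(signal, dtype=float).reshape(-1)
    if not np.isfinite(x).all():
        raise ValidationError("CWT input contains non-finite values")
    t = x.size
    max_support = 2.0 * float(grid.scales.max())
    if t < max_support:
        warnings.warn(
            f"series length {t} is below twice the largest wavelet scale "
            f"({grid.scales.max():.1f} samples); edge effects will be large",
            stacklevel=2,
        )
    n_fft = int(2 ** np.ceil(np.log2(max(t, 2)) + 1))
    xf = np.fft.fft(x, n_fft)
    omega = 2.0 * np.pi * np.fft.fftfreq(n_fft)  # rad/sample
    positive = omega > 0
    w0 = grid.omega0
    coeffs = np.empty((grid.n_bands, t), dtype=complex)
    norm_const = np.pi ** -0.25
    for qi, s in enumerate(grid.scales):
        daughter = np.zeros(n_fft)
        daughter[positive] = (
            np.sqrt(2.0 * np.pi * s) * norm_const
            * np.exp(-0.5 * (s * omega[positive] - w0) ** 2)
        )
        coeffs[qi] = np.fft.ifft(xf * daughter)[:t]
    return coeffs


def cross_wavelet(wx: np.ndarray, wy: np.ndarray) -> np.ndarray:
    """Cross-wavelet spectrum CW_xy = W_x · conj(W_y), elementwise."""
    wx = np.asarray(wx)
    wy = np.asarray(wy)
    if wx.shape != wy.shape:
        raise DimensionError(f"shape mismatch {wx.shape} vs {wy.shape}")
    return wx * np.conj(wy)


def _time_window(scale: float, factor: float) -> int:
    width = max(3, int(round(factor * scale)))
    return width if width % 2 == 1 else width + 1  # odd => symmetric boxcar


def smooth(map_qt: np.ndarray, grid: FrequencyGrid, config: PipelineConfig) -> np.ndarray:
    """Separable moving-average smoother over time then scale.

    Each scale row is filtered with a boxcar whose length grows with the
    wavelet scale (``max(3, round(smooth_time_factor · s))`` samples, forced
    odd, reflective edges), then a short boxcar (``smooth_scale_bins`` bins)
    runs across scales.  The operator is linear and maps constants to
    themselves.
    """
    arr = np.asarray(map_qt)
    if arr.shape[0] != grid.n_bands:
        raise DimensionError(
            f"map has {arr.shape[0]} scale rows, grid has {grid.n_bands}"
        )

    def _real_smooth(a: np.ndarray) -> np.ndarray:
        out = np.empty_like(a)
        for qi, s in enumerate(grid.scales):
            size = _time_window(float(s), config.smooth_time_factor)
            uniform_filter1d(a[qi], size=size, mode="reflect", output=out[qi])
        bins = max(1, int(config.smooth_scale_bins))
        if bins % 2 == 0:
            bins += 1
        if bins > 1:
            out = uniform_filter1d(out, size=bins, axis=0, mode="reflect")
        return out

    if np.iscomplexobj(arr):
        return _real_smooth(arr.real) + 1j * _real_smooth(arr.imag)
    return _real_smooth(arr.astype(float))


def wavelet_coherence(
    x_ts: np.ndarray,
    y_ts: np.ndarray,
    grid: FrequencyGrid,
    config: PipelineConfig,
    *,
    smoothing: bool = True,
) -> np.ndarray:
    """Squared wavelet coherence map (Q x T, values in [0, 1]) for one ROI pair.

    With ``smoothing=False`` the identity smoother is used, in which case the
    map is identically 1 for any pair — the degeneracy that makes the smoother
    essential.
    """
    wx = cwt(x_ts, grid, config)
    wy = cwt(y_ts, grid, config)
    if smoothing:
        sx = smooth(np.abs(wx) ** 2, grid, config)
        sy = smooth(np.abs(wy) ** 2, grid, config)
    else:
        sx = np.abs(wx) ** 2
        sy = np.abs(wy) ** 2
    return _coherence_from_parts(wx, wy, sx, sy, grid, config, smoothing)


def _coherence_from_parts(
    wx: np.ndarray,
    wy: np.ndarray,
    sx: np.ndarray,
    sy: np.ndarray,
    grid: FrequencyGrid,
    config: PipelineConfig,
    smoothing: bool = True,
) -> np.ndarray:
    """Coherence given CWTs and (already smoothed) per-signal power maps."""
    cw = cross_wavelet(wx, wy)
    num = np.abs(smooth(cw, grid, config) if smoothing else cw) ** 2
    denom = sx * sy
    bad = denom <= 0.0
    if bad.any():
        q, t = np.argwhere(bad)[0]
        raise ValidationError(
            f"zero smoothed wavelet power at scale row {q}, time {t}; "
            "coherence undefined"
        )
    wc = num / denom
    if wc.max() > 1.0 + 1e-9:
        raise ValidationError(
            f"coherence exceeded 1 by {wc.max() - 1.0:.3e}; smoothing misconfigured"
        )
    return np.clip(wc, 0.0, 1.0)


def pca_reduce_time(
    wc: np.ndarray, config: PipelineConfig
) -> tuple[np.ndarray, int, float]:
    """Reduce a Q x T coherence map along time by PCA.

    Procedure: subtract the time-mean of every scale row; eigendecompose
    (1/T)·ŴC·ŴCᵀ; find the minimal k whose cumulative eigenvalue fraction
    reaches ``config.pca_variance_threshold``; return the k leading component
    scores (columns u_i·σ_i of the demeaned map's SVD, a Q x k matrix), with
    each eigenvector's sign fixed so its entry sum is nonnegative (ties: first
    nonzero entry positive).

    Returns ``(scores, k, variance_retained)`` where ``variance_retained`` is
    the cumulative fraction at k.  A constant map demeans to zero and yields a
    zero score vector with k = 1.
    """
    arr = np.asarray(wc, dtype=float)
    if arr.ndim != 2:
        raise DimensionError("coherence map must be 2-D (scales x time)")
    if not np.isfinite(arr).all():
        raise ValidationError("coherence map contains non-finite values")
    q, n = arr.shape
    demeaned = arr - arr.mean(axis=1, keepdims=True)
    cov = (demeaned @ demeaned.T) / n
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    total = eigvals.sum()
    if total <= q * n * np.finfo(float).eps ** 2:
        return np.zeros((q, 1)), 1, 1.0
    frac = np.cumsum(eigvals) / total
    k = int(np.searchsorted(frac, config.pca_variance_threshold - 1e-12) + 1)
    k = min(k, q)
    vecs = eigvecs[:, :k].copy()
    for i in range(k):
        col_sum = vecs[:, i].sum()
        if col_sum < 0:
            vecs[:, i] = -vecs[:, i]
        elif col_sum == 0:
            nz = np.flatnonzero(vecs[:, i])
            if nz.size and vecs[nz[0], i] < 0:
                vecs[:, i] = -vecs[:, i]
    sigma = np.sqrt(n * eigvals[:k])
    scores = vecs * sigma
    return scores, k, float(frac[k - 1])


def dynamic_fc(
    ts: RoiTimeSeries, grid: FrequencyGrid, config: PipelineConfig
) -> DynamicFC:
    """Wavelet-coherence dynamic FC tensor (R x R x Q) for one subject.

    For every unordered ROI pair the coherence map is computed and reduced
    along time; the leading component (scaled by its singular value) fills
    ``tensor[i, j, :]`` and ``tensor[j, i, :]``.  The diagonal is zero: the
    self-coherence map is constant 1, which demeans to nothing.  Pairs whose
    minimal k exceeded 1 are collected into a single warning.
    """
    r = ts.n_roi
    q = grid.n_bands
    tensor = np.zeros((r, r, q))
    k_used = np.ones((r, r), dtype=int)
    variance_retained = np.ones((r, r))
    cwts = [cwt(ts.data[:, i], grid, config) for i in range(r)]
    powers = [smooth(np.abs(w) ** 2, grid, config) for w in cwts]
    multi_k: list[tuple[int, int, int]] = []
    for i in range(r):
        for j in range(i + 1, r):
            try:
                wc = _coherence_from_parts(
                    cwts[i], cwts[j], powers[i], powers[j], grid, config
                )
                scores, k, retained = pca_reduce_time(wc, config)
            except ValidationError as exc:
                raise ValidationError(
                    f"{ts.subject_id}: pair ({i}, {j}): {exc}"
                ) from exc
            tensor[i, j, :] = tensor[j, i, :] = scores[:, 0]
            k_used[i, j] = k_used[j, i] = k
            variance_retained[i, j] = variance_retained[j, i] = retained
            if k > 1:
                multi_k.append((i, j, k))
    if multi_k:
        preview = ", ".join(f"({i},{j}): k={k}" for i, j, k in multi_k[:10])
        more = "" if len(multi_k) <= 10 else f" (+{len(multi_k) - 10} more)"
        warnings.warn(
            f"{ts.subject_id}: {len(multi_k)} pair(s) needed more than one "
            f"component to retain {config.pca_variance_threshold:.0%} variance; "
            f"only the first is stored: {preview}{more}",
            stacklevel=2,
        )
    return DynamicFC(
        subject_id=ts.subject_id,
        tensor=tensor,
        k_used=k_used,
        variance_retained=variance_retained,
    )
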