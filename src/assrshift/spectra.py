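"""Multitaper spectral estimation of spontaneous (non-phase-locked) activity.

Induced power is the trial-averaged PSD of each task epoch *after*
subtracting the trial-averaged evoked response — what remains is activity
that is not phase-locked to the stimulus.  Resting power is the same
estimator on resting epochs.  Both are reported as the natural log of
V^2/Hz on the integer 4-100 Hz grid (matching the time-frequency grid used
for clustering), which puts typical scalp EEG in the -20..-27 range.
"""

from __future__ import annotations

import numpy as np
import scipy.fft as fft
from scipy.signal.windows import dpss

from .containers import EpochSet, EvokedResponse, SpectraMaps

DEFAULT_HALF_BANDWIDTH = 4.0  # Hz
GRID_FREQS = np.arange(4.0, 101.0)
LOG_GUARD = 1e-30  # V^2/Hz floor before taking the log


def n_tapers(half_bandwidth: float, duration: float) -> int:
    """Slepian taper count: floor(2 * half_bandwidth * duration) - 1."""
    k = int(np.floor(2 * half_bandwidth * duration)) - 1
    if k < 1:
        raise ValueError(
            f"half_bandwidth {half_bandwidth} Hz x duration {duration} s leaves no usable taper"
        )
    return k


def multitaper_psd(
    data: np.ndarray,
    fs: float,
    half_bandwidth: float = DEFAULT_HALF_BANDWIDTH,
    grid: np.ndarray | None = GRID_FREQS,
) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalue-weighted multitaper PSD along the last axis, in V^2/Hz.

    Returns ``(freqs, psd)``.  With ``grid`` given, the native FFT spectrum
    (resolution fs/n) is linearly interpolated onto that grid; with
    ``grid=None`` the full one-sided FFT grid is returned (useful for
    Parseval checks).  One-sided normalization: integrating over 0..Nyquist
    recovers the signal variance for zero-mean input.
    """
    x = np.asarray(data, dtype=float)
    n = x.shape[-1]
    duration = n / fs
    if half_bandwidth * duration <= 1:
        raise ValueError("half_bandwidth x duration must exceed 1")
    k = n_tapers(half_bandwidth, duration)
    tapers, eigvals = dpss(n, half_bandwidth * duration, Kmax=k, return_ratios=True)
    tapers = tapers / np.sqrt((tapers**2).sum(axis=1, keepdims=True))  # unit energy

    freqs = np.fft.rfftfreq(n, 1 / fs)
    # shape: lead... x tapers x freqs
    spec = fft.rfft(x[..., None, :] * tapers, axis=-1)
    pk = (np.abs(spec) ** 2) / fs
    # one-sided: double everything except DC (and Nyquist if n even)
    pk[..., 1:] *= 2.0
    if n % 2 == 0:
        pk[..., -1] /= 2.0
    weights = eigvals / eigvals.sum()
    psd = np.tensordot(pk, weights, axes=([-2], [0]))
    if grid is None:
        return freqs, psd
    grid = np.asarray(grid, dtype=float)
    if grid.max() > freqs.max():
        raise ValueError("grid extends beyond Nyquist")
    out = np.apply_along_axis(lambda p: np.interp(grid, freqs, p), -1, psd)
    return grid, out


def _log_psd(psd: np.ndarray) -> tuple[np.ndarray, bool]:
    floored = bool((psd < LOG_GUARD).any())
    return np.log(np.maximum(psd, LOG_GUARD)), floored


def mean_epoch_psd(
    epochs_data: np.ndarray,
    fs: float,
    half_bandwidth: float = DEFAULT_HALF_BANDWIDTH,
    grid: np.ndarray = GRID_FREQS,
) -> np.ndarray:
    """Arithmetic mean across epochs of per-epoch multitaper PSDs (linear)."""
    _, psd = multitaper_psd(epochs_data, fs, half_bandwidth, grid)
    return psd.mean(axis=0)


def induced_power(
    task_epochs: EpochSet,
    evoked: EvokedResponse,
    half_bandwidth: float = DEFAULT_HALF_BANDWIDTH,
    grid: np.ndarray = GRID_FREQS,
    post_stimulus_only: bool = False,
) -> tuple[np.ndarray, bool]:
    """Log-PSD of the non-phase-locked task activity.

    Per epoch the evoked response is subtracted, a multitaper PSD is taken
    of the residual, PSDs are averaged across epochs, and the natural log is
    applied (guarded at 1e-30 V^2/Hz; a ``floored`` flag reports degenerate
    inputs).  The full 1100 ms epoch enters by default;
    ``post_stimulus_only`` restricts to samples at t >= 0.
    """
    if task_epochs.data.shape[1:] != evoked.data.shape:
        raise ValueError("task epochs and evoked response have mismatched shapes")
    residual = task_epochs.data - evoked.data[None]
    if post_stimulus_only:
        sel = task_epochs.times >= 0.0
        residual = residual[..., sel]
    mean_psd = mean_epoch_psd(residual, task_epochs.fs, half_bandwidth, grid)
    return _log_psd(mean_psd)


def resting_power(
    rest_epochs: EpochSet,
    half_bandwidth: float = DEFAULT_HALF_BANDWIDTH,
    grid: np.ndarray = GRID_FREQS,
) -> tuple[np.ndarray, bool]:
    """Log-PSD of resting epochs: per-epoch multitaper PSD, epoch-averaged, logged."""
    mean_psd = mean_epoch_psd(rest_epochs.data, rest_epochs.fs, half_bandwidth, grid)
    return _log_psd(mean_psd)


def subject_spectra(
    rest_epochs: EpochSet,
    task_epochs: EpochSet,
    evoked: EvokedResponse,
    half_bandwidth: float = DEFAULT_HALF_BANDWIDTH,
    grid: np.ndarray = GRID_FREQS,
) -> SpectraMaps:
    ind, f1 = induced_power(task_epochs, evoked, half_bandwidth, grid)
    res, f2 = resting_power(rest_epochs, half_bandwidth, grid)
    return SpectraMaps(
        freqs=np.asarray(grid, float),
        channel_names=task_epochs.channel_names,
        induced=ind,
        resting=res,
        floored=f1 or f2,
    )
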