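"""Morlet time-frequency decomposition and the stimulus-evoked measures.

The task-state measures all derive from complex Morlet coefficients on a
4-100 Hz / 1 Hz grid over the -400..700 ms epoch:

* evoked power  - power of the trial-averaged response, baseline-corrected
  by subtracting the mean prestimulus (-100..0 ms) power per frequency;
* PLF (phase-locking factor) - norm of the trial-averaged unit-normalized
  coefficients, 0 = random phase across trials, 1 = perfect locking;
* PLA (phase-locking angle) - the argument of that trial-averaged vector,
  expressed relative to the control-group circular mean, so it measures a
  subject's phase lead (+) or lag (-).

The wavelet is the analytic complex Morlet w(t) = g(t) exp(2*pi*i*f*t) with
Gaussian envelope SD sigma_t = n_cycles / (2*pi*f), truncated at +-3
sigma_t, and scaled so that a unit-amplitude sinusoid at the centre
frequency yields |coefficient| = 1 (i.e. coefficients estimate amplitude).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft as fft

from .containers import EpochSet, EvokedResponse, TFRMaps, check_same_grid

DEFAULT_FREQS = np.arange(4.0, 101.0)  # 4-100 Hz, 1 Hz bins
GAUSS_SD_CUT = 3.0
ANALYSIS_TWINDOW = (0.100, 0.500)
ANALYSIS_FBAND = (38.0, 42.0)
BASELINE = (-0.100, 0.0)


def default_n_cycles(freqs: np.ndarray) -> np.ndarray:
    """Per-frequency cycle counts: max(2, f/4) — ~250 ms windows above 8 Hz."""
    f = np.asarray(freqs, dtype=float)
    return np.maximum(2.0, f / 4.0)


def morlet_kernel(freq: float, n_cycles: float, fs: float) -> np.ndarray:
    """Truncated analytic Morlet kernel, amplitude-calibrated (see module doc)."""
    sigma_t = n_cycles / (2 * np.pi * freq)
    half = int(np.ceil(GAUSS_SD_CUT * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    g = np.exp(-(t**2) / (2 * sigma_t**2))
    kernel = g * np.exp(2j * np.pi * freq * t)
    return kernel * (2.0 / g.sum())


def morlet_tfr(
    data: np.ndarray,
    fs: float,
    freqs: np.ndarray = DEFAULT_FREQS,
    n_cycles: np.ndarray | float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Complex Morlet coefficients of ``data`` along its last (time) axis.

    Returns ``(coefs, edge_mask)`` where ``coefs`` has shape
    ``data.shape[:-1] + (n_freqs, n_times)`` and ``edge_mask[f, t]`` is True
    wherever the wavelet support at frequency ``f`` extends beyond the epoch
    (including whole rows whose wavelet is longer than the epoch).
    ``abs(coefs)**2`` is power; ``angle(coefs)`` is instantaneous phase.
    """
    x = np.asarray(data, dtype=float)
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    if np.any(freqs >= fs / 2):
        raise ValueError("requested frequency at or above Nyquist")
    if n_cycles is None:
        n_cycles = default_n_cycles(freqs)
    n_cycles = np.broadcast_to(np.asarray(n_cycles, dtype=float), freqs.shape)

    n_times = x.shape[-1]
    lead = x.shape[:-1]
    flat = x.reshape(-1, n_times)

    kernels = [morlet_kernel(f, c, fs) for f, c in zip(freqs, n_cycles)]
    max_len = max(k.size for k in kernels)
    nfft = fft.next_fast_len(n_times + max_len - 1)
    xf = fft.fft(flat, nfft, axis=-1)

    coefs = np.empty((flat.shape[0], freqs.size, n_times), dtype=complex)
    edge = np.zeros((freqs.size, n_times), dtype=bool)
    for i, k in enumerate(kernels):
        kf = fft.fft(k, nfft)
        full = fft.ifft(xf * kf[None, :], axis=-1)
        half = (k.size - 1) // 2  # 'same' alignment (kernels are odd-length)
        coefs[:, i, :] = full[:, half: half + n_times]
        if k.size > n_times:
            edge[i, :] = True
        else:
            edge[i, :half] = True
            if half:
                edge[i, -half:] = True
    return coefs.reshape(*lead, freqs.size, n_times), edge


def plf_map(per_epoch_tfr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """PLF and the trial-averaged unit-vector mean from per-epoch coefficients.

    Each epoch's coefficient is normalized to unit magnitude; zero-magnitude
    coefficients are treated as missing at that bin (excluded, denominator
    adjusted) so the result stays within [0, 1].  Returns ``(plf,
    mean_vector)`` with the epoch axis (axis 0) reduced away; the PLA at a
    bin is ``angle(mean_vector)``.
    """
    c = np.asarray(per_epoch_tfr)
    if c.shape[0] < 2:
        raise ValueError("PLF needs at least two epochs")
    mag = np.abs(c)
    valid = mag > 0
    units = np.where(valid, c / np.where(valid, mag, 1.0), 0.0)
    count = valid.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean_vec = units.sum(axis=0) / count
    mean_vec = np.where(count > 0, mean_vec, 0.0)
    plf = np.abs(mean_vec)
    return np.clip(plf, 0.0, 1.0), mean_vec


def evoked_power_map(
    evoked: EvokedResponse,
    freqs: np.ndarray = DEFAULT_FREQS,
    n_cycles: np.ndarray | float | None = None,
    baseline: tuple[float, float] = BASELINE,
) -> tuple[np.ndarray, np.ndarray]:
    """Baseline-corrected evoked power (linear scale) of the trial average.

    Per channel and frequency, the time-averaged power over the prestimulus
    ``baseline`` window is subtracted at every time point, so the corrected
    map averages to exactly zero over the baseline.  Log-scaling, where
    needed, happens at the statistics stage.
    """
    times = evoked.times
    lo, hi = baseline
    sel = (times >= lo) & (times <= hi)
    if not sel.any():
        raise ValueError("baseline window lies outside the epoch")
    coefs, edge = morlet_tfr(evoked.data, evoked.fs, freqs, n_cycles)
    power = np.abs(coefs) ** 2
    corrected = power - power[..., sel].mean(axis=-1, keepdims=True)
    return corrected, edge


@dataclass
class _PLFAccumulator:
    """Streaming accumulation of unit vectors so per-epoch maps need not be held."""

    vec_sum: np.ndarray | None = None
    count: np.ndarray | None = None

    def add(self, coefs: np.ndarray) -> None:
        mag = np.abs(coefs)
        valid = mag > 0
        units = np.where(valid, coefs / np.where(valid, mag, 1.0), 0.0)
        if self.vec_sum is None:
            self.vec_sum = units.astype(complex)
            self.count = valid.astype(np.int64)
        else:
            self.vec_sum += units
            self.count += valid

    def finalize(self) -> tuple[np.ndarray, np.ndarray]:
        with np.errstate(invalid="ignore"):
            mean_vec = self.vec_sum / self.count
        mean_vec = np.where(self.count > 0, mean_vec, 0.0)
        return np.clip(np.abs(mean_vec), 0.0, 1.0), mean_vec


def subject_tfr_maps(
    task_epochs: EpochSet,
    evoked: EvokedResponse,
    freqs: np.ndarray = DEFAULT_FREQS,
    n_cycles: np.ndarray | float | None = None,
    keep_per_epoch: bool = False,
) -> TFRMaps:
    """All task-state time-frequency maps for one subject.

    Epochs are streamed through the wavelet transform one at a time; set
    ``keep_per_epoch`` to retain the full epochs x channels x freqs x times
    complex array (memory-heavy at the full grid).
    """
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    acc = _PLFAccumulator()
    kept = [] if keep_per_epoch else None
    edge = None
    for ep in task_epochs.data:
        coefs, edge = morlet_tfr(ep, task_epochs.fs, freqs, n_cycles)
        acc.add(coefs)
        if kept is not None:
            kept.append(coefs)
    plf, mean_vec = acc.finalize()
    epow, _ = evoked_power_map(evoked, freqs, n_cycles)
    return TFRMaps(
        freqs=freqs,
        times=task_epochs.times,
        channel_names=task_epochs.channel_names,
        plf=plf,
        mean_angle=np.angle(mean_vec),
        evoked_power=epow,
        edge_mask=edge,
        n_epochs=task_epochs.n_epochs,
        complex_tfr_per_epoch=np.stack(kept) if kept else None,
    )


# ---------------------------------------------------------------------------
# circular helpers and window reductions
# ---------------------------------------------------------------------------

def wrap_angle(theta: np.ndarray) -> np.ndarray:
    """Wrap to (-pi, pi]."""
    return -((-np.asarray(theta) + np.pi) % (2 * np.pi) - np.pi)


def circular_mean(theta: np.ndarray, axis=None) -> np.ndarray:
    """Angle of the summed unit vectors."""
    t = np.asarray(theta, dtype=float)
    return np.angle(np.exp(1j * t).sum(axis=axis))


def pla_relative(subject_angles: np.ndarray, nc_reference: np.ndarray) -> np.ndarray:
    """Wrapped circular difference subject - reference, in (-pi, pi].

    The reference is the circular mean over control-group subjects computed
    on the same grid; positive values mean the subject's phase leads it.
    """
    a = np.asarray(subject_angles, dtype=float)
    r = np.asarray(nc_reference, dtype=float)
    if a.shape != r.shape:
        raise ValueError(f"grid mismatch: subject {a.shape} vs reference {r.shape}")
    return wrap_angle(a - r)


def nc_reference_angles(nc_subject_angles: np.ndarray) -> np.ndarray:
    """Circular mean over the subject axis (axis 0) of control-group angles."""
    return circular_mean(nc_subject_angles, axis=0)


def reduce_window(
    values: np.ndarray,
    times: np.ndarray,
    freqs: np.ndarray,
    t_window: tuple[float, float] = ANALYSIS_TWINDOW,
    f_window: tuple[float, float] = ANALYSIS_FBAND,
    circular: bool = False,
    edge_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Mean of a channels x freqs x times map over a time x frequency window.

    Arithmetic mean for power/PLF maps; circular mean (summed unit vectors)
    for angle maps.  If an ``edge_mask`` is given, any flagged bin inside the
    window raises — the analysis window must be free of wavelet edge effects.
    """
    times = np.asarray(times, float)
    freqs = np.asarray(freqs, float)
    tsel = (times >= t_window[0]) & (times <= t_window[1])
    fsel = (freqs >= f_window[0]) & (freqs <= f_window[1])
    if not tsel.any() or not fsel.any():
        raise ValueError("empty reduction window")
    if edge_mask is not None and edge_mask[np.ix_(fsel, tsel)].any():
        raise ValueError("analysis window contains wavelet edge bins")
    block = np.asarray(values)[..., fsel, :][..., tsel]
    if circular:
        return circular_mean(block.reshape(*block.shape[:-2], -1), axis=-1)
    return block.reshape(*block.shape[:-2], -1).mean(axis=-1)
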