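"""Filtering, referencing, artifact rejection and epoch subsampling.

Order of operations mirrors standard clinical-EEG practice: 1-100 Hz
band-pass plus 60 Hz notch on the (continuous or epoched) signal, common
average reference, peak-to-peak artifact rejection at 200 uV, then random
subsampling without replacement to a fixed 120 epochs per state so that
epoch counts cannot bias the downstream estimators.

Independent-component artifact removal is deliberately not re-implemented:
it is upstream cleaning of real recordings.  ``ica_passthrough_hook`` lets a
caller slot in externally cleaned data at the same point in the chain.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
import scipy.signal as sig

from .containers import EpochSet, EvokedResponse

DEFAULT_BAND = (1.0, 100.0)
DEFAULT_NOTCH = 60.0
DEFAULT_THRESHOLD = 200e-6
DEFAULT_N_KEEP = 120
FILTER_ORDER = 4  # Butterworth order per band edge; applied forward-backward
NOTCH_Q = 30.0


def _design_filters(fs: float, band=DEFAULT_BAND, notch=DEFAULT_NOTCH):
    low, high = band
    if fs <= 2 * high:
        raise ValueError(f"fs={fs} Hz too low for a {high} Hz upper band edge")
    sos_bp = sig.butter(FILTER_ORDER, [low, high], btype="bandpass", fs=fs, output="sos")
    b_notch, a_notch = sig.iirnotch(notch, NOTCH_Q, fs=fs)
    return sos_bp, (b_notch, a_notch)


def bandpass_notch(
    continuous: np.ndarray,
    fs: float,
    band: tuple[float, float] = DEFAULT_BAND,
    notch: float = DEFAULT_NOTCH,
) -> np.ndarray:
    """Zero-phase 1-100 Hz band-pass + 60 Hz notch along the last axis.

    Forward-backward (filtfilt) application squares the magnitude response,
    so the effective attenuation is twice the single-pass design and the
    passband stays ripple-free in phase.
    """
    x = np.asarray(continuous, dtype=float)
    if fs <= 200:
        raise ValueError("fs must exceed 200 Hz")
    sos_bp, (b_n, a_n) = _design_filters(fs, band, notch)
    y = sig.sosfiltfilt(sos_bp, x, axis=-1)
    y = sig.filtfilt(b_n, a_n, y, axis=-1)
    return y


def filter_response(
    fs: float,
    freqs: np.ndarray,
    band: tuple[float, float] = DEFAULT_BAND,
    notch: float = DEFAULT_NOTCH,
) -> np.ndarray:
    """Theoretical effective (two-pass) magnitude response on a frequency grid."""
    sos_bp, (b_n, a_n) = _design_filters(fs, band, notch)
    w = 2 * np.pi * np.asarray(freqs, float) / fs
    _, h_bp = sig.sosfreqz(sos_bp, worN=w)
    _, h_n = sig.freqz(b_n, a_n, worN=w)
    return (np.abs(h_bp) * np.abs(h_n)) ** 2  # filtfilt applies |H|^2


def filter_epochs(epochs: EpochSet, **kwargs) -> EpochSet:
    return epochs.with_data(bandpass_notch(epochs.data, epochs.fs, **kwargs))


def average_reference(epochs: EpochSet) -> EpochSet:
    """Subtract the instantaneous mean across channels (common average)."""
    if epochs.n_channels < 2:
        raise ValueError("average reference needs at least two channels")
    data = epochs.data - epochs.data.mean(axis=1, keepdims=True)
    return epochs.with_data(data)


def peak_to_peak(epochs: EpochSet) -> np.ndarray:
    """Per-epoch, per-channel max - min amplitude (volts)."""
    return epochs.data.max(axis=2) - epochs.data.min(axis=2)


def reject_and_subsample(
    epochs: EpochSet,
    threshold: float = DEFAULT_THRESHOLD,
    n_keep: int = DEFAULT_N_KEEP,
    seed: int | np.random.Generator = 0,
) -> EpochSet:
    """Drop epochs whose peak-to-peak exceeds ``threshold`` (strictly >200 uV
    at default) on any channel, then select ``n_keep`` of the survivors at
    random without replacement, preserving recording order.
    """
    ptp = peak_to_peak(epochs)
    clean = np.flatnonzero((ptp <= threshold).all(axis=1))
    if clean.size < n_keep:
        raise ValueError(
            f"subject {epochs.subject_id!r} state {epochs.state!r}: only "
            f"{clean.size} epochs survive the {threshold * 1e6:.0f} uV rule, "
            f"need {n_keep}"
        )
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(clean, size=n_keep, replace=False))
    return epochs.with_data(epochs.data[chosen], finalized=True)


def compute_evoked(task_epochs: EpochSet) -> EvokedResponse:
    """Arithmetic mean across the finalized task epochs."""
    if not task_epochs.finalized:
        raise ValueError("compute_evoked expects a finalized (rejected+subsampled) EpochSet")
    return EvokedResponse(
        data=task_epochs.data.mean(axis=0),
        fs=task_epochs.fs,
        t0=task_epochs.t0,
        channel_names=task_epochs.channel_names,
        subject_id=task_epochs.subject_id,
        group=task_epochs.group,
    )


def segment_rest(
    continuous: np.ndarray,
    fs: float,
    epoch_len: float = 1.1,
    *,
    channel_names,
    subject_id: str = "",
    group: str = "NC",
) -> EpochSet:
    """Cut a continuous resting recording into contiguous non-overlapping
    epochs of ``epoch_len`` seconds; the trailing partial segment is dropped.
    """
    x = np.asarray(continuous, dtype=float)
    n_samp = int(round(epoch_len * fs))
    if abs(epoch_len * fs - n_samp) > 1e-9:
        raise ValueError(f"epoch_len x fs = {epoch_len * fs} is not an integer sample count")
    n_epochs = x.shape[1] // n_samp
    if n_epochs == 0:
        raise ValueError("recording shorter than one epoch")
    data = x[:, : n_epochs * n_samp].reshape(x.shape[0], n_epochs, n_samp).transpose(1, 0, 2)
    return EpochSet(
        data=data, fs=fs, t0=0.0, channel_names=tuple(channel_names),
        state="rest", subject_id=subject_id, group=group,
    )


def ica_passthrough_hook(
    epochs: EpochSet, clean: Callable[[EpochSet], EpochSet] | None = None
) -> EpochSet:
    """Optional hook for externally supplied artifact cleaning (e.g. ICA)."""
    return epochs if clean is None else clean(epochs)


def preprocess_subject(
    rest: EpochSet,
    task: EpochSet,
    *,
    threshold: float = DEFAULT_THRESHOLD,
    n_keep: int = DEFAULT_N_KEEP,
    seed: int = 0,
    apply_filter: bool = True,
) -> tuple[EpochSet, EpochSet, EvokedResponse]:
    """Full per-subject chain: filter -> average reference -> reject ->
    subsample to ``n_keep`` -> trial-average the task epochs.
    Separate deterministic substreams drive the rest/task subsampling.
    """
    out = []
    for k, eset in enumerate((rest, task)):
        if apply_filter:
            eset = filter_epochs(eset)
        eset = average_reference(eset)
        eset = reject_and_subsample(
            eset, threshold=threshold, n_keep=n_keep,
            seed=np.random.default_rng([int(seed), k]),
        )
        out.append(eset)
    rest_f, task_f = out
    return rest_f, task_f, compute_evoked(task_f)
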