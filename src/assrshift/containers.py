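"""In-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

REST = "rest"
TASK = "task"
NC = "NC"
SZ = "SZ"

GROUPS = (NC, SZ)
STATES = (REST, TASK)


@dataclass
class EpochSet:
    """Epoched EEG for one subject in one state.

    data is epochs x channels x samples in volts; ``t0`` is the epoch start
    time relative to stimulus onset (-0.4 s for the task state; arbitrary for
    rest).  ``finalized`` marks a set that has been through artifact rejection
    and fixed-size subsampling.
    """

    data: np.ndarray
    fs: float
    t0: float
    channel_names: tuple[str, ...]
    state: str
    subject_id: str
    group: str
    finalized: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channel_names = tuple(self.channel_names)
        if self.data.ndim != 3:
            raise ValueError("EpochSet.data must be epochs x channels x samples")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError(
                f"channel axis ({self.data.shape[1]}) does not match channel_names "
                f"({len(self.channel_names)})"
            )
        if self.state not in STATES:
            raise ValueError(f"state must be one of {STATES}, got {self.state!r}")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def with_data(self, data: np.ndarray, **changes) -> "EpochSet":
        return replace(self, data=data, **changes)


@dataclass
class EvokedResponse:
    """Trial-averaged (stimulus phase-locked) response: channels x samples, volts."""

    data: np.ndarray
    fs: float
    t0: float
    channel_names: tuple[str, ...]
    subject_id: str
    group: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channel_names = tuple(self.channel_names)
        if self.data.ndim != 2:
            raise ValueError("EvokedResponse.data must be channels x samples")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.data.shape[1]) / self.fs


@dataclass
class TFRMaps:
    """Per-subject Morlet time-frequency maps on the analysis grid.

    plf is the norm of the trial-averaged unit-normalized coefficients in
    [0, 1]; mean_angle the argument of that average in (-pi, pi]; evoked_power
    the baseline-corrected power of the trial-averaged response.  edge_mask
    flags (freq, time) bins whose wavelet support runs off the epoch.
    """

    freqs: np.ndarray
    times: np.ndarray
    channel_names: tuple[str, ...]
    plf: np.ndarray | None = None
    mean_angle: np.ndarray | None = None
    evoked_power: np.ndarray | None = None
    edge_mask: np.ndarray | None = None
    n_epochs: int | None = None
    complex_tfr_per_epoch: np.ndarray | None = None


@dataclass
class SpectraMaps:
    """Per-subject log-PSD (natural log of V^2/Hz) on the 4-100 Hz grid."""

    freqs: np.ndarray
    channel_names: tuple[str, ...]
    induced: np.ndarray | None = None
    resting: np.ndarray | None = None
    log_base: str = "e"
    floored: bool = False


@dataclass
class WindowedMeasures:
    """Per-subject per-channel scalars reduced over the analysis window."""

    channel_names: tuple[str, ...]
    evoked40: np.ndarray | None = None
    plf40: np.ndarray | None = None
    angle40: np.ndarray | None = None  # absolute circular-mean angle; PLA needs the NC reference
    subject_id: str = ""
    group: str = ""


def check_same_grid(a: Sequence[float], b: Sequence[float], what: str) -> None:
    if not np.allclose(np.asarray(a, float), np.asarray(b, float)):
        raise ValueError(f"grid mismatch: {what}")
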