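"""Reading and writing recordings.

Two on-disk forms are supported:

* the *array container*: a ``.npz`` holding the epoch array plus a JSON
  sidecar (same stem, ``.json``) with sampling metadata — the package's
  native format;
* EDF (European Data Format), the clinical-EEG interchange format.  Reading
  goes through MNE's built-in EDF reader.  Writing uses the small EDF+
  writer below (16-bit EDF is a simple, fully documented byte layout; no
  installed library exposes an EDF writer).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .containers import EpochSet, EvokedResponse

_UV = 1e-6


# ---------------------------------------------------------------------------
# array container
# ---------------------------------------------------------------------------

def save_epochset(epochs: EpochSet, path: str | Path) -> Path:
    """Write an EpochSet as ``<path>.npz`` + ``<path>.json`` sidecar."""
    path = Path(path)
    stem = path.with_suffix("") if path.suffix == ".npz" else path
    np.savez_compressed(stem.with_suffix(".npz"), data=epochs.data)
    meta = {
        "kind": "EpochSet",
        "fs": epochs.fs,
        "t0": epochs.t0,
        "channel_names": list(epochs.channel_names),
        "state": epochs.state,
        "subject_id": epochs.subject_id,
        "group": epochs.group,
        "finalized": epochs.finalized,
        "units": "V",
    }
    stem.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return stem.with_suffix(".npz")


def load_epochset(path: str | Path) -> EpochSet:
    path = Path(path)
    stem = path.with_suffix("") if path.suffix in {".npz", ".json"} else path
    meta = json.loads(stem.with_suffix(".json").read_text())
    if meta.get("kind") != "EpochSet":
        raise ValueError(f"{stem}: sidecar does not describe an EpochSet")
    data = np.load(stem.with_suffix(".npz"))["data"]
    return EpochSet(
        data=data,
        fs=meta["fs"],
        t0=meta["t0"],
        channel_names=tuple(meta["channel_names"]),
        state=meta["state"],
        subject_id=meta["subject_id"],
        group=meta["group"],
        finalized=meta.get("finalized", False),
    )


def save_evoked(evoked: EvokedResponse, path: str | Path) -> Path:
    path = Path(path)
    stem = path.with_suffix("") if path.suffix == ".npz" else path
    np.savez_compressed(stem.with_suffix(".npz"), data=evoked.data)
    meta = {
        "kind": "EvokedResponse",
        "fs": evoked.fs,
        "t0": evoked.t0,
        "channel_names": list(evoked.channel_names),
        "subject_id": evoked.subject_id,
        "group": evoked.group,
        "units": "V",
    }
    stem.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return stem.with_suffix(".npz")


def load_evoked(path: str | Path) -> EvokedResponse:
    path = Path(path)
    stem = path.with_suffix("") if path.suffix in {".npz", ".json"} else path
    meta = json.loads(stem.with_suffix(".json").read_text())
    if meta.get("kind") != "EvokedResponse":
        raise ValueError(f"{stem}: sidecar does not describe an EvokedResponse")
    data = np.load(stem.with_suffix(".npz"))["data"]
    return EvokedResponse(
        data=data, fs=meta["fs"], t0=meta["t0"],
        channel_names=tuple(meta["channel_names"]),
        subject_id=meta["subject_id"], group=meta["group"],
    )


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _edf_field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(epochs: EpochSet, path: str | Path) -> Path:
    """Write epochs as an EDF file, one data record per epoch.

    Signals are stored as 16-bit integers with per-channel physical scaling
    chosen from the data range; record duration equals the epoch length.
    """
    path = Path(path)
    data = epochs.data  # epochs x channels x samples, volts
    n_rec, n_ch, n_samp = data.shape
    duration = n_samp / epochs.fs

    uv = data / _UV
    phys_max = np.maximum(np.abs(uv).max(axis=(0, 2)), 1.0) * 1.0001
    phys_min = -phys_max
    dig_min, dig_max = -32768, 32767

    header = b"".join([
        _edf_field("0", 8),
        _edf_field(f"X X X {epochs.subject_id or 'X'}", 80),
        _edf_field(f"Startdate X X X X state={epochs.state} group={epochs.group}", 80),
        _edf_field("01.01.00", 8),
        _edf_field("00.00.00", 8),
        _edf_field(str(256 * (1 + n_ch)), 8),
        _edf_field("EDF+C", 44),
        _edf_field(str(n_rec), 8),
        _edf_field(f"{duration:g}", 8),
        _edf_field(str(n_ch), 4),
    ])
    per_signal = b"".join([
        b"".join(_edf_field(f"EEG {ch}", 16) for ch in epochs.channel_names),
        b"".join(_edf_field("AgAgCl electrode", 80) for _ in range(n_ch)),
        b"".join(_edf_field("uV", 8) for _ in range(n_ch)),
        b"".join(_edf_field(f"{phys_min[i]:.6g}"[:8], 8) for i in range(n_ch)),
        b"".join(_edf_field(f"{phys_max[i]:.6g}"[:8], 8) for i in range(n_ch)),
        b"".join(_edf_field(str(dig_min), 8) for _ in range(n_ch)),
        b"".join(_edf_field(str(dig_max), 8) for _ in range(n_ch)),
        b"".join(_edf_field("", 80) for _ in range(n_ch)),
        b"".join(_edf_field(str(n_samp), 8) for _ in range(n_ch)),
        b"".join(_edf_field("", 32) for _ in range(n_ch)),
    ])

    # physical -> digital, per EDF linear mapping
    pmin_r = np.array([float(f"{phys_min[i]:.6g}"[:8]) for i in range(n_ch)])
    pmax_r = np.array([float(f"{phys_max[i]:.6g}"[:8]) for i in range(n_ch)])
    gain = (dig_max - dig_min) / (pmax_r - pmin_r)
    dig = (uv - pmin_r[None, :, None]) * gain[None, :, None] + dig_min
    dig = np.clip(np.round(dig), dig_min, dig_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per_signal)
        for rec in range(n_rec):
            fh.write(dig[rec].tobytes())  # channel-major within record
    return path


def read_edf(
    path: str | Path,
    epoch_len: float | None = None,
    *,
    t0: float = 0.0,
    state: str = "rest",
    subject_id: str = "",
    group: str = "NC",
) -> EpochSet:
    """Read an EDF file into an EpochSet via MNE.

    The continuous signal is cut into consecutive non-overlapping epochs of
    ``epoch_len`` seconds (default: the EDF record duration), dropping any
    trailing partial segment.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    # the EDF record-duration field is ASCII decimal; undo its float round-off
    fs = float(np.round(raw.info["sfreq"], 6))
    sig = raw.get_data()  # channels x samples, volts
    names = tuple(n.removeprefix("EEG ").strip() for n in raw.ch_names)
    if epoch_len is None:
        epoch_len = raw.n_times / fs
    n_samp = int(round(epoch_len * fs))
    n_rec = sig.shape[1] // n_samp
    data = sig[:, : n_rec * n_samp].reshape(sig.shape[0], n_rec, n_samp).transpose(1, 0, 2)
    return EpochSet(
        data=data, fs=fs, t0=t0, channel_names=names,
        state=state, subject_id=subject_id, group=group,
    )
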