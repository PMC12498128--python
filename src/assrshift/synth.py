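"""Synthetic two-state EEG cohorts with known ground truth.

Each subject's signal is a sum of

* a 1/f^slope Gaussian background (spectral factorization of white noise,
  band-limited to the 1-100 Hz acquisition band),
* narrowband oscillators — one sinusoid per band at the band's centre
  frequency (theta 6, alpha 10, beta 20, gamma 60 Hz) with a fresh uniform
  phase every epoch and a fixed scalp profile per band,
* in the task state only, a 40 Hz steady-state component over 0-500 ms
  post-onset whose per-epoch phase is von Mises distributed with a
  group-dependent concentration kappa (the ground-truth phase locking), and
* optional rectangular 250 uV artifact excursions that exercise the
  peak-to-peak rejection rule.

Group effects are controlled by the config: patients get elevated theta
power (both states), reduced phase concentration kappa, near-absent alpha
task suppression and a task-only gamma boost — the qualitative pattern the
analysis pipeline is meant to recover.  A per-subject lognormal amplitude
factor and kappa jitter create between-subject dispersion; an optional
latent factor couples that dispersion to the synthetic symptom scores for
exercising the PLSC stage.

All randomness flows from ``numpy.random.default_rng`` seeded by
``(config.seed, subject index)``: the same config reproduces bit-identical
cohorts, and subjects can be regenerated lazily one at a time (a full
cohort of raw epochs would not fit comfortably in memory).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterator

import numpy as np
import pandas as pd

from .containers import NC, SZ, EpochSet
from .montage import CHANNELS

BAND_FREQS = {"theta": 6.0, "alpha": 10.0, "beta": 20.0, "gamma": 60.0}

# scalp profiles (gain per channel) for the 19-channel montage
_PROFILES = {
    "assr": {  # right-lateralized fronto-central
        "Fz": 1.0, "Cz": 1.0, "F4": 0.9, "C4": 0.9, "F3": 0.75, "C3": 0.75,
        "Fp1": 0.55, "Fp2": 0.6, "F7": 0.5, "F8": 0.6, "T7": 0.35, "T8": 0.45,
        "P3": 0.35, "P4": 0.4, "Pz": 0.5, "P7": 0.25, "P8": 0.3, "O1": 0.2, "O2": 0.25,
    },
    "theta": {  # fronto-midline dominant, widespread
        "Fz": 1.0, "Cz": 0.9, "F3": 0.9, "F4": 0.9, "Fp1": 0.8, "Fp2": 0.8,
        "F7": 0.7, "F8": 0.7, "C3": 0.7, "C4": 0.7, "T7": 0.6, "T8": 0.6,
        "P3": 0.6, "P4": 0.6, "Pz": 0.65, "P7": 0.5, "P8": 0.5, "O1": 0.45, "O2": 0.45,
    },
    "alpha": {  # parieto-occipital dominant
        "O1": 1.0, "O2": 1.0, "P7": 0.9, "P8": 0.9, "P3": 0.85, "P4": 0.85,
        "Pz": 0.85, "T7": 0.5, "T8": 0.5, "C3": 0.45, "C4": 0.45, "Cz": 0.45,
        "F3": 0.3, "F4": 0.3, "Fz": 0.3, "F7": 0.25, "F8": 0.25, "Fp1": 0.2, "Fp2": 0.2,
    },
    "beta": {  # central
        "C3": 1.0, "C4": 1.0, "Cz": 0.9, "F3": 0.6, "F4": 0.6, "Fz": 0.6,
        "P3": 0.6, "P4": 0.6, "Pz": 0.6, "T7": 0.5, "T8": 0.5, "F7": 0.4, "F8": 0.4,
        "P7": 0.4, "P8": 0.4, "Fp1": 0.3, "Fp2": 0.3, "O1": 0.35, "O2": 0.35,
    },
    "gamma": {  # right temporo-parietal emphasis
        "T8": 1.0, "P8": 0.9, "C4": 0.85, "F8": 0.8, "P4": 0.8, "F4": 0.7,
        "Cz": 0.6, "Pz": 0.6, "T7": 0.55, "C3": 0.5, "P7": 0.5, "F3": 0.45,
        "F7": 0.45, "P3": 0.5, "Fz": 0.5, "O1": 0.4, "O2": 0.45, "Fp1": 0.35, "Fp2": 0.35,
    },
}

DEFAULT_BAND_POWERS = {
    NC: {"theta": 3.0, "alpha": 4.0, "beta": 1.2, "gamma": 0.9},
    SZ: {"theta": 4.2, "alpha": 4.0, "beta": 1.5, "gamma": 0.9},
}
DEFAULT_TASK_BAND_SCALE = {NC: {}, SZ: {"gamma": 1.35}}

PANSS_FACTORS = ("positive", "negative", "disorganized", "excited", "depression")
_PANSS_PARAMS = {  # mean, sd, low, high — plausible against published summaries
    "positive": (12.22, 5.71, 4.0, 35.0),
    "negative": (21.07, 8.86, 6.0, 42.0),
    "disorganized": (14.46, 7.22, 5.0, 40.0),
    "excited": (10.01, 5.23, 4.0, 28.0),
    "depression": (14.26, 6.53, 4.0, 35.0),
}


@dataclass
class GeneratorConfig:
    """Study-condition knobs of the synthetic cohort (amplitudes in uV)."""

    n_controls: int = 66
    n_patients: int = 68
    n_channels: int = 19
    fs: float = 500.0
    epoch_len: float = 1.1
    n_task_epochs: int = 150
    n_rest_epochs: int = 150
    background_slope: float = 1.0
    background_amp: float = 5.0  # uV RMS over the 1-100 Hz band
    band_powers: dict = field(default_factory=lambda: {g: dict(v) for g, v in DEFAULT_BAND_POWERS.items()})
    task_band_scale: dict = field(default_factory=lambda: {g: dict(v) for g, v in DEFAULT_TASK_BAND_SCALE.items()})
    assr_amp: float = 3.0
    assr_phase_mu: dict = field(default_factory=lambda: {NC: 0.0, SZ: 0.0})
    assr_phase_kappa: dict = field(default_factory=lambda: {NC: 0.8, SZ: 0.55})
    alpha_task_suppression: dict = field(default_factory=lambda: {NC: 0.7, SZ: 0.95})
    artifact_rate: float = 0.08
    artifact_amp: float = 250.0  # uV
    subject_amp_jitter: float = 0.12  # lognormal sigma on the global amplitude
    subject_kappa_jitter: float = 0.15  # lognormal sigma on kappa
    state_amp_jitter: float = 0.10  # lognormal sigma on band amplitude per state (arousal drift)
    panss_eeg_corr: float = 0.0  # latent coupling of symptom scores to EEG deviations
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_controls", "n_patients", "n_channels", "n_task_epochs", "n_rest_epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        n_samp = self.fs * self.epoch_len
        if abs(n_samp - round(n_samp)) > 1e-9:
            raise ValueError(
                f"fs x epoch_len = {n_samp} is not an integer sample count"
            )
        for g, kappa in self.assr_phase_kappa.items():
            if kappa < 0:
                raise ValueError(f"kappa for {g} must be >= 0")
        for g, s in self.alpha_task_suppression.items():
            if not (0 < s <= 1):
                raise ValueError(f"alpha_task_suppression for {g} must be in (0, 1]")
        if not (0 <= self.artifact_rate < 1):
            raise ValueError("artifact_rate must be in [0, 1)")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.epoch_len))

    @property
    def channel_names(self) -> tuple[str, ...]:
        if self.n_channels == len(CHANNELS):
            return CHANNELS
        return tuple(f"CH{i + 1}" for i in range(self.n_channels))

    def to_dict(self) -> dict:
        return asdict(self)


def _profile(name: str, channel_names: tuple[str, ...]) -> np.ndarray:
    """Scalp gain profile, centered to zero mean and scaled to max |gain| = 1.

    Centering makes each source dipolar (a polarity reversal somewhere on the
    scalp), which is both physically realistic and exactly invariant under
    the common-average reference applied in preprocessing.
    """
    table = _PROFILES[name]
    p = np.array([table.get(ch, 1.0) for ch in channel_names])
    p = p - p.mean()
    m = np.abs(p).max()
    return p / m if m > 0 else p


def _background(rng: np.random.Generator, n_epochs: int, n_ch: int, n_samp: int,
                fs: float, slope: float, amp_uv: float) -> np.ndarray:
    """Band-limited (1-100 Hz) 1/f^slope Gaussian noise, epochs x ch x samples, uV."""
    freqs = np.fft.rfftfreq(n_samp, 1 / fs)
    shape = np.zeros_like(freqs)
    band = (freqs >= 1.0) & (freqs <= 100.0)
    shape[band] = freqs[band] ** (-slope / 2)
    w = rng.standard_normal((n_epochs, n_ch, n_samp))
    x = np.fft.irfft(np.fft.rfft(w, axis=-1) * shape, n_samp, axis=-1)
    # E var(x) = sum over the full (two-sided) spectrum of shape^2 / n
    full = shape[0] ** 2 + 2 * (shape[1:-1] ** 2).sum() + (
        shape[-1] ** 2 if n_samp % 2 == 0 else 2 * shape[-1] ** 2
    )
    expected_rms = np.sqrt(full / n_samp)
    return x * (amp_uv / expected_rms)


@dataclass
class SubjectTruth:
    """Ground-truth per-subject parameters the generator drew."""

    amp_factor: float
    kappa: float
    latent_z: float


def _draw_truth(config: GeneratorConfig, group: str, rng: np.random.Generator) -> SubjectTruth:
    """Subject-level latent variables; must stay the generator's first draws
    so the cohort table and the signal synthesis agree."""
    latent_z = rng.standard_normal()
    rho = config.panss_eeg_corr
    amp_eps = rho * latent_z + np.sqrt(max(0.0, 1 - rho**2)) * rng.standard_normal()
    kap_eps = -rho * latent_z + np.sqrt(max(0.0, 1 - rho**2)) * rng.standard_normal()
    return SubjectTruth(
        amp_factor=float(np.exp(config.subject_amp_jitter * amp_eps)),
        kappa=float(config.assr_phase_kappa[group] * np.exp(config.subject_kappa_jitter * kap_eps)),
        latent_z=float(latent_z),
    )


def generate_subject(
    config: GeneratorConfig, group: str, subject_seed: int
) -> tuple[EpochSet, EpochSet, SubjectTruth]:
    """One subject's (rest, task) raw EpochSets plus the drawn ground truth."""
    if group not in (NC, SZ):
        raise ValueError(f"group must be {NC!r} or {SZ!r}, got {group!r}")
    rng = np.random.default_rng([int(config.seed), int(subject_seed)])
    names = config.channel_names
    n_ch, n_samp, fs = config.n_channels, config.n_samples, config.fs
    t = np.arange(n_samp) / fs

    truth = _draw_truth(config, group, rng)
    amp_factor, kappa = truth.amp_factor, truth.kappa

    profiles = {b: _profile(b, names) for b in BAND_FREQS}
    assr_profile = _profile("assr", names)

    def build_state(state: str, n_epochs: int, t0: float) -> EpochSet:
        x = _background(rng, n_epochs, n_ch, n_samp, fs,
                        config.background_slope, config.background_amp)
        for band, f0 in BAND_FREQS.items():
            amp = config.band_powers[group].get(band, 0.0)
            if state == "task":
                amp *= config.task_band_scale.get(group, {}).get(band, 1.0)
                if band == "alpha":
                    amp *= config.alpha_task_suppression[group]
            if amp == 0.0:
                continue
            # the two recordings are minutes apart: band amplitude drifts
            # between states (arousal), making within-subject contrasts noisy
            amp *= np.exp(config.state_amp_jitter * rng.standard_normal())
            phase = rng.uniform(0, 2 * np.pi, size=n_epochs)
            x += (amp * profiles[band])[None, :, None] * np.sin(
                2 * np.pi * f0 * t[None, None, :] + phase[:, None, None]
            )
        if state == "task" and config.assr_amp > 0:
            stim_t = t + t0  # time relative to stimulus onset
            gate = (stim_t >= 0.0) & (stim_t <= 0.5)
            phases = rng.vonmises(config.assr_phase_mu[group], kappa, size=n_epochs) \
                if kappa > 0 else rng.uniform(-np.pi, np.pi, size=n_epochs)
            x += (config.assr_amp * assr_profile)[None, :, None] * gate[None, None, :] * np.sin(
                2 * np.pi * 40.0 * stim_t[None, None, :] + phases[:, None, None]
            )
        x *= amp_factor
        if config.artifact_rate > 0:
            hit = rng.random(n_epochs) < config.artifact_rate
            width = int(round(0.1 * fs))
            for e in np.flatnonzero(hit):
                ch = rng.integers(n_ch)
                start = rng.integers(0, n_samp - width)
                x[e, ch, start: start + width] += config.artifact_amp
        return EpochSet(
            data=x * 1e-6, fs=fs, t0=t0, channel_names=names, state=state,
            subject_id=f"{group}{subject_seed:03d}", group=group,
        )

    rest = build_state("rest", config.n_rest_epochs, 0.0)
    task = build_state("task", config.n_task_epochs, -0.4)
    return rest, task, truth


@dataclass
class Cohort:
    """Cohort table plus deterministic lazy access to per-subject epochs."""

    config: GeneratorConfig
    table: pd.DataFrame

    def subject_epochs(self, subject_id: str) -> tuple[EpochSet, EpochSet]:
        row = self.table.loc[self.table.subject_id == subject_id]
        if row.empty:
            raise KeyError(subject_id)
        rest, task, _ = generate_subject(
            self.config, row.group.iloc[0], int(row.subject_seed.iloc[0])
        )
        return rest, task

    def iter_subjects(self) -> Iterator[tuple[str, EpochSet, EpochSet]]:
        for _, row in self.table.iterrows():
            rest, task, _ = generate_subject(self.config, row.group, int(row.subject_seed))
            yield row.subject_id, rest, task


def _trunc_normal(rng, mean, sd, low, high, size=None, shift=0.0):
    x = mean + shift + sd * rng.standard_normal(size)
    return np.clip(x, low, high)


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Cohort table: group labels, demographics, symptom scores and the
    per-subject ground truth.  Epoch data are generated lazily via
    ``Cohort.subject_epochs`` (deterministic under the config seed).
    """
    rows = []
    groups = [NC] * config.n_controls + [SZ] * config.n_patients
    for i, group in enumerate(groups):
        rng = np.random.default_rng([int(config.seed), i])
        # same subject-level draws generate_subject will make
        truth = _draw_truth(config, group, rng)
        latent_z = truth.latent_z
        rho = config.panss_eeg_corr
        rng_demo = np.random.default_rng([int(config.seed), i, 999])
        row = {
            "subject_id": f"{group}{i:03d}",
            "subject_seed": i,
            "group": group,
            "age": float(_trunc_normal(rng_demo, 36.95 if group == NC else 34.94,
                                       10.26 if group == NC else 12.26, 18, 60)),
            "sex": "M" if rng_demo.random() < (30 / 66 if group == NC else 35 / 68) else "F",
            "education": float(_trunc_normal(rng_demo, 15.40 if group == NC else 13.54,
                                             2.78 if group == NC else 2.61, 6, 24)),
        }
        if group == SZ:
            for factor in PANSS_FACTORS:
                mean, sd, low, high = _PANSS_PARAMS[factor]
                noise = np.sqrt(max(0.0, 1 - rho**2)) * rng_demo.standard_normal()
                row[f"panss_{factor}"] = float(
                    np.clip(mean + sd * (rho * latent_z + noise), low, high)
                )
            row["cpz_dose"] = float(_trunc_normal(rng_demo, 514.57, 460.69, 0, 2400))
        else:
            for factor in PANSS_FACTORS:
                row[f"panss_{factor}"] = np.nan
            row["cpz_dose"] = np.nan
        row["latent_z"] = float(latent_z)
        row["true_amp_factor"] = truth.amp_factor
        row["true_kappa"] = truth.kappa
        rows.append(row)
    return Cohort(config=config, table=pd.DataFrame(rows))
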