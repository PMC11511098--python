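"""Seeded two-group synthetic multichannel surface-EMG cohorts.

The generator emulates the structure of a functional hand-assessment study:
two groups of participants (healthy women and women with hand osteoarthritis),
seven forearm sensors sampled at 1000 Hz, and three task families per
participant — 20 Sollerman hand-function-test (SHFT) daily-living tasks,
7 maximal-voluntary-contraction (MVC) movements and 6 maximal-effort grasps.

Each recording is amplitude-modulated band-limited Gaussian noise — the
standard surrogate for an sEMG interference signal — plus a small baseline
noise floor.  The modulation envelope is a sum of smooth activation bursts
for functional tasks and a trapezoidal ramp-hold-ramp profile for maximal
efforts.  Three group effects can be injected, each aimed at one family of
downstream features:

* ``mvc_amplitude_scale`` (< 1) scales patients' maximal-effort amplitude,
  modelling pain-limited effort; it moves MVC/GRASP normalization values and
  hence MVC/GRASP-normalized amplitude features.
* ``envelope_complexity_shift`` adds activation bursts to patients' functional
  tasks, raising the enhanced wavelength (EWL) of the raw signal.
* ``spectral_shift_hz`` moves patients' interference-noise band upward,
  raising the zero-crossing rate (NZC).

Every (participant, family, task, sensor) triple draws from an independent
random substream keyed on the cohort seed, so paired comparisons between
configurations that share a seed are variance-reduced, and a fixed seed gives
a bit-identical cohort regardless of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import ConfigurationError

__all__ = [
    "GroupEffect",
    "CohortConfig",
    "RawRecording",
    "ParticipantProfile",
    "TaskSpec",
    "generate_cohort",
    "generate_recording",
    "recordings_to_frame",
    "frame_to_recordings",
]

_FAMILIES = ("shft", "mvc", "grasp")
_FAMILY_CODE = {"shft": 0, "mvc": 1, "grasp": 2}

#: Default interference-noise band (Hz); sits inside the 25-500 Hz analysis band.
DEFAULT_NOISE_BAND = (60.0, 350.0)


@dataclass(frozen=True)
class GroupEffect:
    """Injected group differences (applied to patients only).

    ``affected_sensors=None`` means every sensor is affected.
    """

    mvc_amplitude_scale: float = 1.0
    envelope_complexity_shift: float = 0.0
    spectral_shift_hz: float = 0.0
    affected_sensors: frozenset[int] | None = None

    @staticmethod
    def null() -> "GroupEffect":
        """A neutral effect: groups are statistically exchangeable."""
        return GroupEffect(1.0, 0.0, 0.0, None)

    def is_null(self) -> bool:
        return (
            self.mvc_amplitude_scale == 1.0
            and self.envelope_complexity_shift == 0.0
            and self.spectral_shift_hz == 0.0
        )

    def affects(self, sensor: int) -> bool:
        return self.affected_sensors is None or sensor in self.affected_sensors


#: Study-condition default: pain-limited maximal effort, busier activation
#: envelopes and a mild upward spectral shift, on all sensors.
DEFAULT_EFFECT = GroupEffect(
    mvc_amplitude_scale=0.75,
    envelope_complexity_shift=1.0,
    spectral_shift_hz=10.0,
    affected_sensors=None,
)


@dataclass(frozen=True)
class CohortConfig:
    """Cohort layout mirroring the study design (21 healthy vs 20 patients,
    7 sensors at 1000 Hz; 20 SHFT + 7 MVC + 6 GRASP tasks)."""

    n_healthy: int = 21
    n_patients: int = 20
    n_sensors: int = 7
    n_shft_tasks: int = 20
    n_mvc_tasks: int = 7
    n_grasp_tasks: int = 6
    fs: float = 1000.0
    task_duration_s: float = 4.0
    duration_jitter: float = 0.25
    noise_band: tuple[float, float] = DEFAULT_NOISE_BAND
    baseline_noise_mV: float = 0.005
    seed: int = 0
    effect: GroupEffect = field(default_factory=lambda: DEFAULT_EFFECT)
    simulate_age: bool = False

    def validate(self) -> None:
        for name in (
            "n_healthy",
            "n_patients",
            "n_sensors",
            "n_shft_tasks",
            "n_mvc_tasks",
            "n_grasp_tasks",
        ):
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or value < 1:
                raise ConfigurationError(f"{name} must be an integer >= 1, got {value!r}")
        if self.task_duration_s <= 0:
            raise ConfigurationError(
                f"task_duration_s must be > 0, got {self.task_duration_s!r}"
            )
        if not 0 <= self.duration_jitter < 1:
            raise ConfigurationError(
                f"duration_jitter must be in [0, 1), got {self.duration_jitter!r}"
            )
        lo, hi = self.noise_band
        if not 0 < lo < hi:
            raise ConfigurationError(f"noise_band must satisfy 0 < low < high, got {self.noise_band!r}")
        if self.fs <= 2 * hi:
            raise ConfigurationError(
                f"fs must exceed twice the noise_band upper edge ({hi} Hz), got fs={self.fs!r}"
            )
        if self.baseline_noise_mV < 0:
            raise ConfigurationError(
                f"baseline_noise_mV must be >= 0, got {self.baseline_noise_mV!r}"
            )
        eff = self.effect
        if eff.mvc_amplitude_scale <= 0:
            raise ConfigurationError(
                f"effect.mvc_amplitude_scale must be > 0, got {eff.mvc_amplitude_scale!r}"
            )
        if eff.envelope_complexity_shift < 0:
            raise ConfigurationError(
                "effect.envelope_complexity_shift must be >= 0, got "
                f"{eff.envelope_complexity_shift!r}"
            )
        if eff.affected_sensors is not None:
            bad = [s for s in eff.affected_sensors if not 1 <= s <= self.n_sensors]
            if bad:
                raise ConfigurationError(
                    f"effect.affected_sensors contains out-of-range sensors {sorted(bad)}"
                )


@dataclass
class RawRecording:
    """One participant x task x sensor signal trace, amplitudes in mV."""

    participant_id: str
    group: str  # "healthy" | "patient"
    task_family: str  # "shft" | "mvc" | "grasp"
    task_id: int  # 1-based index within the family
    sensor: int  # 1-based
    fs: float
    samples: np.ndarray


@dataclass(frozen=True)
class ParticipantProfile:
    """Latent per-participant parameters (the generator's ground truth).

    ``base_amplitude_mV`` and the noise-band edges are per sensor; amplitudes
    are drawn independently per sensor so that sensor-level features are close
    to independent across sensors.
    """

    participant_id: str
    group: str
    index: int
    base_amplitude_mV: np.ndarray  # shape (n_sensors,)
    band_low_hz: np.ndarray
    band_high_hz: np.ndarray
    extra_bump_rate: float  # Poisson rate of extra envelope bursts (patient effect)
    mvc_scale: np.ndarray  # per-sensor maximal-effort scaling
    age_years: float


@dataclass(frozen=True)
class TaskSpec:
    family: str
    task_id: int
    sensor: int
    duration_s: float
    fs: float


def _substream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=tuple(key)))


def _draw_profile(config: CohortConfig, index: int, group: str) -> ParticipantProfile:
    rng = _substream(config.seed, 0, index)
    n = config.n_sensors
    # lognormal around ~0.3 mV: a typical forearm sEMG envelope peak
    base_amp = np.exp(rng.normal(np.log(0.3), 0.35, size=n))
    lo, hi = config.noise_band
    band_lo = np.full(n, lo)
    band_hi = np.full(n, hi)
    mvc_scale = np.ones(n)
    extra_rate = 0.0
    eff = config.effect
    if group == "patient":
        affected = np.array([eff.affects(s) for s in range(1, n + 1)])
        shift = eff.spectral_shift_hz
        band_lo = np.where(affected, np.clip(lo + shift, 26.0, config.fs / 2 - 40.0), band_lo)
        band_hi = np.where(affected, np.clip(hi + shift, band_lo + 20.0, config.fs / 2 - 10.0), band_hi)
        mvc_scale = np.where(affected, eff.mvc_amplitude_scale, 1.0)
        extra_rate = eff.envelope_complexity_shift
    if config.simulate_age:
        age = rng.normal(71.0, 9.0) if group == "patient" else rng.normal(47.0, 11.0)
    else:
        age = float("nan")
    prefix = "H" if group == "healthy" else "P"
    local = index if group == "healthy" else index - config.n_healthy
    return ParticipantProfile(
        participant_id=f"{prefix}{local + 1:02d}",
        group=group,
        index=index,
        base_amplitude_mV=base_amp,
        band_low_hz=band_lo,
        band_high_hz=band_hi,
        extra_bump_rate=extra_rate,
        mvc_scale=mvc_scale,
        age_years=age,
    )


def _burst_envelope(
    t: np.ndarray, rng: np.random.Generator, extra_rate: float
) -> np.ndarray:
    """Sum of 1-4 Gaussian activation bursts (plus Poisson extras), peak 1."""
    duration = t[-1] - t[0] if len(t) > 1 else 1.0
    n_bumps = int(rng.integers(1, 5))
    if extra_rate > 0:
        n_bumps += int(rng.poisson(extra_rate))
    centers = rng.uniform(0.1, 0.9, size=n_bumps) * duration
    widths = rng.uniform(0.05, 0.15, size=n_bumps) * duration
    heights = rng.uniform(0.4, 1.0, size=n_bumps)
    env = np.zeros_like(t)
    for c, w, h in zip(centers, widths, heights):
        env += h * np.exp(-0.5 * ((t - c) / w) ** 2)
    peak = env.max()
    if peak > 0:
        env /= peak
    return env


def _effort_envelope(t: np.ndarray) -> np.ndarray:
    """Trapezoidal ramp-hold-ramp profile for a maximal effort, peak 1."""
    if len(t) < 2:
        return np.ones_like(t)
    duration = t[-1] - t[0]
    ramp = 0.15 * duration
    up = np.clip(t / ramp, 0.0, 1.0)
    down = np.clip((duration - t) / ramp, 0.0, 1.0)
    return np.minimum(up, down)


@lru_cache(maxsize=256)
def _noise_sos(fs: float, low: float, high: float) -> np.ndarray:
    return sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")


def _band_noise(
    n: int, fs: float, low: float, high: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-RMS zero-mean Gaussian noise band-passed to [low, high] Hz."""
    white = rng.standard_normal(n)
    sos = _noise_sos(float(fs), float(low), float(high))
    x = sps.sosfiltfilt(sos, white)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def generate_recording(
    profile: ParticipantProfile,
    task: TaskSpec,
    rng: np.random.Generator,
    baseline_noise_mV: float = 0.005,
    amplitude_scale: float = 1.0,
) -> RawRecording:
    """Simulate one recording: envelope x band-limited noise + baseline noise.

    ``amplitude_scale`` multiplies the envelope after all random draws, so two
    calls with identical ``rng`` states and different scales yield exactly
    proportional activation components (used for paired oracles).
    """
    n = int(round(task.fs * task.duration_s))
    t = np.arange(n) / task.fs
    k = task.sensor - 1
    if task.family == "shft":
        env = _burst_envelope(t, rng, profile.extra_bump_rate)
        effort = rng.uniform(0.6, 1.0)
        peak = profile.base_amplitude_mV[k] * effort
    else:  # maximal efforts: mvc / grasp
        env = _effort_envelope(t)
        effort = rng.uniform(0.9, 1.1)
        peak = profile.base_amplitude_mV[k] * effort * profile.mvc_scale[k]
    carrier = _band_noise(n, task.fs, profile.band_low_hz[k], profile.band_high_hz[k], rng)
    baseline = baseline_noise_mV * rng.standard_normal(n)
    samples = amplitude_scale * peak * env * carrier + baseline
    return RawRecording(
        participant_id=profile.participant_id,
        group=profile.group,
        task_family=task.family,
        task_id=task.task_id,
        sensor=task.sensor,
        fs=task.fs,
        samples=samples,
    )


def _family_tasks(config: CohortConfig, family: str) -> int:
    return {
        "shft": config.n_shft_tasks,
        "mvc": config.n_mvc_tasks,
        "grasp": config.n_grasp_tasks,
    }[family]


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[RawRecording], pd.DataFrame]:
    """Generate all recordings of a cohort plus the latent ground truth.

    Returns ``(recordings, ground_truth)`` where ``ground_truth`` has one row
    per participant x sensor with the sampled latent parameters.
    """
    config.validate()
    profiles = [
        _draw_profile(config, i, "healthy" if i < config.n_healthy else "patient")
        for i in range(config.n_healthy + config.n_patients)
    ]
    recordings: list[RawRecording] = []
    for prof in profiles:
        for family in _FAMILIES:
            fam_code = _FAMILY_CODE[family]
            for task_id in range(1, _family_tasks(config, family) + 1):
                # one duration per task, shared across sensors
                if family == "shft" and config.duration_jitter > 0:
                    trng = _substream(config.seed, 1, prof.index, fam_code, task_id)
                    jitter = trng.uniform(-config.duration_jitter, config.duration_jitter)
                    duration = config.task_duration_s * (1.0 + jitter)
                else:
                    duration = config.task_duration_s
                for sensor in range(1, config.n_sensors + 1):
                    rng = _substream(config.seed, 2, prof.index, fam_code, task_id, sensor)
                    recordings.append(
                        generate_recording(
                            prof,
                            TaskSpec(family, task_id, sensor, duration, config.fs),
                            rng,
                            baseline_noise_mV=config.baseline_noise_mV,
                        )
                    )
    truth = pd.DataFrame(
        [
            {
                "participant_id": p.participant_id,
                "group": p.group,
                "sensor": s + 1,
                "base_amplitude_mV": p.base_amplitude_mV[s],
                "band_low_hz": p.band_low_hz[s],
                "band_high_hz": p.band_high_hz[s],
                "mvc_scale": p.mvc_scale[s],
                "extra_bump_rate": p.extra_bump_rate,
                "age_years": p.age_years,
            }
            for p in profiles
            for s in range(config.n_sensors)
        ]
    )
    return recordings, truth


def recordings_to_frame(recordings: Iterable[RawRecording]) -> pd.DataFrame:
    """Long-format table: one row per sample."""
    parts = []
    for rec in recordings:
        n = len(rec.samples)
        parts.append(
            pd.DataFrame(
                {
                    "participant_id": np.repeat(rec.participant_id, n),
                    "group": np.repeat(rec.group, n),
                    "task_family": np.repeat(rec.task_family, n),
                    "task_id": np.repeat(rec.task_id, n),
                    "sensor": np.repeat(rec.sensor, n),
                    "t_ms": np.arange(n) * 1000.0 / rec.fs,
                    "amplitude_mV": rec.samples,
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def frame_to_recordings(frame: pd.DataFrame, fs: float | None = None) -> list[RawRecording]:
    """Inverse of :func:`recordings_to_frame` (samples assumed time-ordered)."""
    recs = []
    keys = ["participant_id", "group", "task_family", "task_id", "sensor"]
    for (pid, group, family, task_id, sensor), sub in frame.groupby(keys, sort=True):
        sub = sub.sort_values("t_ms")
        if fs is None:
            dt = np.diff(sub["t_ms"].to_numpy()[:2])
            rate = 1000.0 / dt[0] if len(dt) and dt[0] > 0 else 1000.0
        else:
            rate = fs
        recs.append(
            RawRecording(
                participant_id=str(pid),
                group=str(group),
                task_family=str(family),
                task_id=int(task_id),
                sensor=int(sensor),
                fs=float(rate),
                samples=sub["amplitude_mV"].to_numpy(float),
            )
        )
    return recs


def scaled_config(config: CohortConfig, **overrides) -> CohortConfig:
    """Convenience for building reduced copies of a cohort configuration."""
    return replace(config, **overrides)
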