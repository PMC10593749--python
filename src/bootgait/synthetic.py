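"""Synthetic immobilizing-boot gait cohorts with known ground truth.

Generates walking trials that carry the statistical structure the monitoring
models assume: stride-periodic insole force and IMU waveforms whose amplitude
and timing features hold a linear-plus-subject-offset relationship to walking
speed and peak Achilles tendon load; heavier loading as the heel wedge is
removed (0 deg > 5 deg > 30 deg); speeds ordered pathological < slow <
medium < fast; within-subject noise on the load target.  Every stride is
paired with its ground-truth targets and boundary samples, so segmentation,
target construction and model evaluation can all be validated end to end.

The waveforms are stylized, not physiological: insole stance force is a
smooth double bump; the boot accelerometer carries a heel-strike transient
whose plateau amplitude is linear in walking speed (the plateau makes its
sampled maximum identical at 100/50/25 Hz, so decimation degrades sampling
density, not the speed encoding); the boot gyroscope ML channel oscillates
with extrema scaling with cadence; remaining channels are low-amplitude
correlated noise.  Subject-specific load offsets are deliberately *invisible*
to the IMU features — that is the mechanism by which generalized models
degrade on new subjects while personalized models do not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .recordings import ImuChannelSet, TrialRecording

GRAVITY = 9.80665


class ConfigurationError(ValueError):
    """A simulation-config field is invalid; the message names the field."""


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level simulation parameters (defaults are the study conditions).

    Ten subjects walk at four self-selected speeds under three heel-wedge
    conditions; 7 trials per cell with 7 strides each gives 5880 strides, a
    desk-scale echo of a full collection.  ``subject_sd_load_bw`` /
    ``subject_sd_speed`` set the spread of subject-specific target offsets;
    ``noise_sd_load_bw`` is the within-stride load noise and
    ``noise_sd_speed_mps`` the trial-to-trial speed jitter.  Kinematic jitters
    perturb the waveform features without touching the targets.
    """

    n_subjects: int = 10
    conditions: tuple[int, ...] = (30, 5, 0)
    speed_labels: tuple[str, ...] = ("pathological", "slow", "medium", "fast")
    trials_per_cell: int = 7
    strides_per_trial: int = 7
    fs: float = 100.0
    body_weight_mean_N: float = 700.0
    body_weight_sd_N: float = 90.0
    subject_sd_load_bw: float = 0.35
    subject_sd_speed: float = 0.04
    noise_sd_load_bw: float = 0.08
    noise_sd_speed_mps: float = 0.03
    duration_jitter_sd: float = 0.02
    stance_jitter_sd: float = 0.01
    amp_jitter_frac: float = 0.03
    imu_noise_sd: float = 0.3
    locations: tuple[str, ...] = ("boot", "contra_foot")
    lever_ratio: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ConfigurationError("n_subjects must be >= 2")
        if len(self.conditions) == 0:
            raise ConfigurationError("conditions must be non-empty")
        if self.fs <= 0:
            raise ConfigurationError("fs must be > 0")
        if self.trials_per_cell < 1 or self.strides_per_trial < 1:
            raise ConfigurationError("trials_per_cell and strides_per_trial must be >= 1")
        for name in (
            "subject_sd_load_bw",
            "subject_sd_speed",
            "noise_sd_load_bw",
            "noise_sd_speed_mps",
            "duration_jitter_sd",
            "stance_jitter_sd",
            "amp_jitter_frac",
            "imu_noise_sd",
            "body_weight_sd_N",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.body_weight_mean_N <= 0:
            raise ConfigurationError("body_weight_mean_N must be > 0")
        if self.lever_ratio <= 0:
            raise ConfigurationError("lever_ratio must be > 0")


@dataclass(frozen=True)
class StrideParams:
    """Resolved parameters of one simulated stride."""

    duration_s: float
    stance_fraction: float
    peak_force_N: float
    speed_mps: float
    at_load_bw: float

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        if not (0 < self.stance_fraction < 1):
            raise ValueError("stance_fraction must lie in (0, 1)")
        if self.peak_force_N <= 50.0:
            raise ValueError("peak_force_N must exceed the 50 N detection threshold")


@dataclass
class SyntheticCohort:
    """Generated trials plus the stride-level ground-truth table."""

    trials: list[TrialRecording]
    ground_truth: pd.DataFrame
    subjects: pd.DataFrame
    config: SimConfig


# -- target link ------------------------------------------------------------

#: base walking speed per self-selected label, m/s (evenly spaced)
def base_speed(label_index: int) -> float:
    return 0.60 + 0.30 * label_index


#: condition base load in BW: removing wedge material loads the tendon more
def base_load(condition_deg: float) -> float:
    return 2.0 - condition_deg / 30.0


#: marginal load per walking speed, BW per m/s
LOAD_SPEED_SLOPE = 0.6

#: minimum simulated stride load; keeps every stance detectable (> 50 N)
MIN_SIM_LOAD_BW = 0.15


def _stride_duration(speed: float) -> float:
    """Cadence rises with speed: nominal stride time in seconds."""
    return float(np.clip(1.45 - 0.45 * speed, 0.75, 1.80))


# -- waveform primitives ----------------------------------------------------


def _stance_force_shape(n: int) -> np.ndarray:
    """Smooth double-bump stance profile (weight acceptance + push-off).

    Tapered to zero at both edges and normalized to a sampled maximum of 1,
    so scaling by the peak force reproduces the peak exactly at the sensor's
    sample grid.
    """
    p = np.arange(n) / max(n - 1, 1)
    bump = np.exp(-0.5 * ((p - 0.30) / 0.14) ** 2) + 0.95 * np.exp(
        -0.5 * ((p - 0.72) / 0.14) ** 2
    )
    taper = np.clip(np.minimum(p / 0.04, (1.0 - p) / 0.04), 0.0, 1.0)
    shape = bump * taper
    return shape / shape.max()


def _flat_top_pulse(t: np.ndarray, onset_s: float = 0.04, flat_s: float = 0.06) -> np.ndarray:
    """Heel-strike transient: Gaussian rise, 60 ms plateau, Gaussian decay.

    The plateau spans more than one sample interval even at 25 Hz, so the
    sampled maximum equals the plateau amplitude at every supported rate.
    """
    rise = np.exp(-0.5 * ((t - onset_s) / 0.025) ** 2)
    fall = np.exp(-0.5 * ((t - onset_s - flat_s) / 0.040) ** 2)
    out = np.where(t < onset_s, rise, np.where(t <= onset_s + flat_s, 1.0, fall))
    return np.where(t < 0, 0.0, out)


def _ar1_noise(rng: np.random.Generator, n: int, sd: float, rho: float = 0.95) -> np.ndarray:
    if sd == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    x = lfilter([1.0], [1.0, -rho], white)
    innovation_sd = math.sqrt(1.0 - rho**2)
    return sd * innovation_sd * x


# -- trial synthesis --------------------------------------------------------

_LEAD_S = 0.6
_TAIL_S = 0.6


def _synth_trial(
    rng: np.random.Generator,
    cfg: SimConfig,
    subject_id: str,
    condition: int,
    label_index: int,
    trial_id: int,
    body_weight_N: float,
    load_offset: float,
    speed_offset: float,
) -> tuple[TrialRecording, list[dict]]:
    fs = cfg.fs
    label = cfg.speed_labels[label_index]
    v = base_speed(label_index) + speed_offset + rng.normal(0.0, cfg.noise_sd_speed_mps)
    v = float(np.clip(v, 0.3, 2.5))

    n_contacts = cfg.strides_per_trial + 1
    durations = np.clip(
        _stride_duration(v) + rng.normal(0.0, cfg.duration_jitter_sd, n_contacts),
        0.6,
        2.2,
    )
    stance_fracs = np.clip(
        0.62 + rng.normal(0.0, cfg.stance_jitter_sd, n_contacts), 0.50, 0.72
    )
    loads = (
        base_load(condition)
        + LOAD_SPEED_SLOPE * (v - 1.0)
        + load_offset
        + rng.normal(0.0, cfg.noise_sd_load_bw, n_contacts)
    )
    loads = np.maximum(loads, MIN_SIM_LOAD_BW)

    starts_s = _LEAD_S + np.concatenate(([0.0], np.cumsum(durations[:-1])))
    total_s = starts_s[-1] + durations[-1] * stance_fracs[-1] + _TAIL_S
    n = int(round(total_s * fs))
    t = np.arange(n) / fs

    force = np.zeros(n)
    acc_amp = np.zeros(n_contacts)
    contact_windows = []
    for k in range(n_contacts):
        params = StrideParams(
            duration_s=float(durations[k]),
            stance_fraction=float(stance_fracs[k]),
            peak_force_N=float(loads[k] * body_weight_N / cfg.lever_ratio),
            speed_mps=v,
            at_load_bw=float(loads[k]),
        )
        a = int(round(starts_s[k] * fs))
        b = a + max(int(round(params.duration_s * params.stance_fraction * fs)), 8)
        force[a:b] = params.peak_force_N * _stance_force_shape(b - a)
        contact_windows.append((a, b))
        acc_amp[k] = (2.0 + 6.0 * v) * (1.0 + rng.normal(0.0, cfg.amp_jitter_frac))

    # ground-truth boundaries: contact onset/offset at the 50 N detection line
    hs_idx, to_idx = [], []
    for a, b in contact_windows:
        above = np.flatnonzero(force[a:b] >= 50.0)
        hs_idx.append(a + int(above[0]))
        to_idx.append(a + int(above[-1]) + 1)

    gyro_amp = (40.0 + 120.0 * v) * (1.0 + rng.normal(0.0, cfg.amp_jitter_frac, n_contacts))

    def _imu_for(location: str) -> ImuChannelSet:
        phase_shift = 0.0 if location == "boot" else 0.5
        amp_scale = 1.0 if location == "boot" else 0.85
        acc_si = np.full(n, GRAVITY)
        gyr_ml = np.zeros(n)
        for k in range(n_contacts):
            t0 = starts_s[k] + phase_shift * durations[k]
            rel = t - t0
            mask = (rel >= 0) & (rel < 0.35)
            acc_si[mask] += amp_scale * acc_amp[k] * _flat_top_pulse(rel[mask])
            # stance/swing oscillation over the stride window
            a = int(round(t0 * fs))
            b_st = a + int(round(durations[k] * stance_fracs[k] * fs))
            b_sw = a + int(round(durations[k] * fs))
            b_st, b_sw = min(b_st, n), min(b_sw, n)
            if b_st > a:
                p = np.arange(b_st - a) / max(b_st - a, 1)
                gyr_ml[a:b_st] += -0.35 * gyro_amp[k] * np.sin(np.pi * p)
            if b_sw > b_st:
                p = np.arange(b_sw - b_st) / max(b_sw - b_st, 1)
                gyr_ml[b_st:b_sw] += gyro_amp[k] * np.sin(np.pi * p)
        return ImuChannelSet(
            location=location,
            acc_si=acc_si,
            acc_ap=_ar1_noise(rng, n, cfg.imu_noise_sd),
            acc_ml=_ar1_noise(rng, n, cfg.imu_noise_sd),
            gyr_si=_ar1_noise(rng, n, 8.0 * cfg.imu_noise_sd),
            gyr_ap=_ar1_noise(rng, n, 8.0 * cfg.imu_noise_sd),
            gyr_ml=gyr_ml,
            fs=fs,
        )

    imus = {loc: _imu_for(loc) for loc in cfg.locations}
    com_x = v * t + 0.004 * np.sin(2.0 * np.pi * t / 1.1)

    trial = TrialRecording(
        subject_id=subject_id,
        condition_deg=condition,
        speed_label=label,
        imus=imus,
        insole_force=force,
        fs_insole=fs,
        com_x=com_x,
        fs_com=fs,
        body_weight_N=body_weight_N,
        trial_id=trial_id,
    )
    truth_rows = [
        {
            "subject_id": subject_id,
            "condition_deg": condition,
            "speed_label": label,
            "trial": trial_id,
            "stride": k,
            "at_load_bw": float(loads[k]),
            "speed_mps": v,
            "hs_idx": hs_idx[k],
            "to_idx": to_idx[k],
            "next_hs_idx": hs_idx[k + 1],
            "body_weight_n": body_weight_N,
        }
        for k in range(cfg.strides_per_trial)
    ]
    return trial, truth_rows


def generate_cohort(config: SimConfig = SimConfig()) -> SyntheticCohort:
    """Generate a full subject x condition x speed cohort with ground truth.

    Deterministic given ``config.seed``; each subject draws from its own
    substream (seed, subject index), so subsetting subjects reproduces their
    trials exactly.
    """
    trials: list[TrialRecording] = []
    truth_rows: list[dict] = []
    subject_rows: list[dict] = []
    for s in range(config.n_subjects):
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, s)))
        subject_id = f"S{s + 1:02d}"
        bw = float(np.clip(rng.normal(config.body_weight_mean_N, config.body_weight_sd_N), 400.0, 1200.0))
        load_offset = float(rng.normal(0.0, config.subject_sd_load_bw))
        speed_offset = float(rng.normal(0.0, config.subject_sd_speed))
        subject_rows.append(
            {
                "subject_id": subject_id,
                "body_weight_n": bw,
                "load_offset_bw": load_offset,
                "speed_offset_mps": speed_offset,
            }
        )
        for condition in config.conditions:
            for label_index in range(len(config.speed_labels)):
                for j in range(config.trials_per_cell):
                    trial, rows = _synth_trial(
                        rng,
                        config,
                        subject_id,
                        condition,
                        label_index,
                        trial_id=j,
                        body_weight_N=bw,
                        load_offset=load_offset,
                        speed_offset=speed_offset,
                    )
                    trials.append(trial)
                    truth_rows.extend(rows)
    return SyntheticCohort(
        trials=trials,
        ground_truth=pd.DataFrame(truth_rows),
        subjects=pd.DataFrame(subject_rows),
        config=config,
    )


def perturb_recording_length(trial: TrialRecording, delta_s: float) -> TrialRecording:
    """Truncate the insole trace by ``delta_s`` seconds (integrity-check fixture).

    Returns a copy; the IMU streams keep their full length, so the perturbed
    trial fails the recording-length screen whenever ``delta_s`` exceeds the
    tolerance.
    """
    if delta_s < 0:
        raise ValueError("delta_s must be >= 0")
    n_cut = int(round(delta_s * trial.fs_insole))
    if n_cut >= len(trial.insole_force):
        raise ValueError(
            f"cannot truncate {delta_s} s from a "
            f"{len(trial.insole_force) / trial.fs_insole:.2f} s insole trace"
        )
    n_keep = len(trial.insole_force) - n_cut
    return replace(trial, insole_force=trial.insole_force[:n_keep].copy())


def write_cohort(cohort: SyntheticCohort, path) -> None:
    """Write one directory per trial plus a cohort-level ground_truth.csv."""
    from pathlib import Path

    from .recordings import write_trial

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for trial in cohort.trials:
        name = f"{trial.subject_id}_c{trial.condition_deg:02d}_{trial.speed_label}_t{trial.trial_id:02d}"
        write_trial(trial, path / name)
    cohort.ground_truth.to_csv(path / "ground_truth.csv", index=False)
    cohort.subjects.to_csv(path / "subjects.csv", index=False)
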