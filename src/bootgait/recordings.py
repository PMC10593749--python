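"""Trial-recording data model, file IO, integrity screening and decimation.

A *trial* is one walking pass in the immobilizing boot: six-axis IMU signals
from one or more body locations, the total plantar force from an instrumented
insole, and the forward center-of-mass (COM) position trace, plus subject
metadata.  All series are uniformly sampled; after parsing, time is carried as
(sample index, sampling rate) only.

Units: accelerometer m/s^2, gyroscope deg/s, insole force N, COM position m.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: conversion used when sensor ranges are quoted in g
GRAVITY_MS2 = 9.80665

#: IMU body locations the pipeline understands
IMU_LOCATIONS = ("boot", "contra_wrist", "contra_shank", "contra_foot")

#: sampling rates the hardware (or its simulated decimation) can produce
ALLOWED_IMU_FS = (100.0, 50.0, 25.0)

#: axis channels, superior-inferior / anterior-posterior / medial-lateral
IMU_CHANNELS = ("acc_si", "acc_ap", "acc_ml", "gyr_si", "gyr_ap", "gyr_ml")
ACC_CHANNELS = IMU_CHANNELS[:3]


class SchemaError(ValueError):
    """A required column/key is missing or a value violates the schema."""


class SignalParseError(ValueError):
    """A signal file is malformed (bad CSV/JSON, non-uniform time base...)."""


@dataclass
class ImuChannelSet:
    """Six synchronized IMU channels from one body location."""

    location: str
    acc_si: np.ndarray
    acc_ap: np.ndarray
    acc_ml: np.ndarray
    gyr_si: np.ndarray
    gyr_ap: np.ndarray
    gyr_ml: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        if self.location not in IMU_LOCATIONS:
            raise SchemaError(
                f"unknown IMU location {self.location!r}; expected one of {IMU_LOCATIONS}"
            )
        if not any(math.isclose(self.fs, f) for f in ALLOWED_IMU_FS):
            raise SchemaError(f"IMU sampling rate {self.fs} Hz not in {ALLOWED_IMU_FS}")
        lengths = {len(self.channel(name)) for name in IMU_CHANNELS}
        if len(lengths) != 1:
            raise SchemaError(f"IMU channels at {self.location!r} have unequal lengths {lengths}")
        if lengths == {0}:
            raise SchemaError(f"IMU channels at {self.location!r} are empty")

    def channel(self, name: str) -> np.ndarray:
        if name not in IMU_CHANNELS:
            raise KeyError(name)
        return getattr(self, name)

    @property
    def n_samples(self) -> int:
        return len(self.acc_si)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class TrialRecording:
    """One walking pass: IMUs, insole force, COM trace and metadata."""

    subject_id: str
    condition_deg: int
    speed_label: str
    imus: dict[str, ImuChannelSet]
    insole_force: np.ndarray
    fs_insole: float
    com_x: np.ndarray
    fs_com: float
    body_weight_N: float
    trial_id: int = 0

    def __post_init__(self) -> None:
        if self.condition_deg not in (30, 5, 0):
            raise SchemaError(f"condition_deg {self.condition_deg} not in (30, 5, 0)")
        if self.body_weight_N <= 0:
            raise SchemaError(f"body_weight_N must be > 0, got {self.body_weight_N}")
        if len(self.insole_force) == 0:
            raise SchemaError("insole force trace is empty")
        if len(self.com_x) < 2:
            raise SchemaError("COM trace needs at least 2 samples")
        if not self.imus:
            raise SchemaError("trial carries no IMU data")

    @property
    def duration_insole_s(self) -> float:
        return len(self.insole_force) / self.fs_insole

    def imu(self, location: str) -> ImuChannelSet:
        try:
            return self.imus[location]
        except KeyError:
            raise KeyError(
                f"trial has no IMU at {location!r}; available: {sorted(self.imus)}"
            ) from None


@dataclass
class IntegrityReport:
    """Outcome of the recording-length consistency screen."""

    accepted: bool
    duration_imu_s: float
    duration_insole_s: float
    reason: str = ""


def check_integrity(trial: TrialRecording, tolerance_s: float = 0.1) -> IntegrityReport:
    """Screen a trial for a recording-length discrepancy between streams.

    Trials whose insole and IMU recordings differ in duration by more than
    ``tolerance_s`` indicate a synchronization/logging fault and are rejected
    from downstream analysis.  The check is symmetric in which stream is
    longer; it always returns a report, never raises.
    """
    if tolerance_s < 0:
        raise ValueError("tolerance_s must be >= 0")
    dur_imu = next(iter(trial.imus.values())).duration_s
    dur_ins = trial.duration_insole_s
    gap = abs(dur_imu - dur_ins)
    if gap <= tolerance_s:
        return IntegrityReport(True, dur_imu, dur_ins)
    return IntegrityReport(
        False,
        dur_imu,
        dur_ins,
        reason=f"recording-length mismatch of {gap:.3f} s exceeds tolerance {tolerance_s:.3f} s",
    )


def decimate_trial(trial: TrialRecording, target_fs: float) -> TrialRecording:
    """Simulate an IMU natively sampling at ``target_fs`` by subsampling.

    Keeps every k-th sample (k = fs/target_fs) starting at index 0, with no
    anti-alias filter: a sensor configured to a lower rate applies none.  The
    insole and COM streams are lab-grade equipment and are left untouched.
    """
    out_imus = {}
    for loc, imu in trial.imus.items():
        if math.isclose(imu.fs, target_fs):
            out_imus[loc] = imu
            continue
        factor = imu.fs / target_fs
        if abs(factor - round(factor)) > 1e-9 or factor < 1:
            raise ValueError(
                f"target_fs {target_fs} Hz must divide the IMU rate {imu.fs} Hz evenly"
            )
        k = int(round(factor))
        out_imus[loc] = ImuChannelSet(
            location=loc,
            **{ch: imu.channel(ch)[::k].copy() for ch in IMU_CHANNELS},
            fs=target_fs,
        )
    return replace(trial, imus=out_imus)


# ---------------------------------------------------------------------------
# file IO — one directory per trial: signals.csv + meta.json

_META_REQUIRED = ("subject", "condition_deg", "speed_label", "fs_hz", "body_weight_n")


def _signal_columns(locations: tuple[str, ...]) -> list[str]:
    cols = ["time_s"]
    for loc in locations:
        cols += [f"{loc}_{ch}" for ch in IMU_CHANNELS]
    cols += ["insole_force_n", "com_x_m"]
    return cols


def write_trial(trial: TrialRecording, path: str | Path) -> Path:
    """Write a trial directory (``signals.csv`` + ``meta.json``).

    The CSV dialect requires all streams at a common rate; it is the on-disk
    exchange format for freshly collected (or simulated) 100 Hz trials.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    locations = tuple(sorted(trial.imus))
    n = len(trial.insole_force)
    for loc in locations:
        imu = trial.imus[loc]
        if imu.n_samples != n or not math.isclose(imu.fs, trial.fs_insole):
            raise ValueError("write_trial requires all streams at a common length and rate")
    if len(trial.com_x) != n:
        raise ValueError("write_trial requires all streams at a common length and rate")
    data = {"time_s": np.arange(n) / trial.fs_insole}
    for loc in locations:
        for ch in IMU_CHANNELS:
            data[f"{loc}_{ch}"] = trial.imus[loc].channel(ch)
    data["insole_force_n"] = trial.insole_force
    data["com_x_m"] = trial.com_x
    pd.DataFrame(data, columns=_signal_columns(locations)).to_csv(
        path / "signals.csv", index=False, float_format="%.6f"
    )
    meta = {
        "subject": trial.subject_id,
        "condition_deg": trial.condition_deg,
        "speed_label": trial.speed_label,
        "fs_hz": trial.fs_insole,
        "body_weight_n": trial.body_weight_N,
        "trial_id": trial.trial_id,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2))
    return path


def load_trial(path: str | Path) -> TrialRecording:
    """Load a trial directory written in the ``signals.csv``/``meta.json`` dialect."""
    path = Path(path)
    meta_path = path / "meta.json"
    csv_path = path / "signals.csv"
    try:
        meta = json.loads(meta_path.read_text())
    except FileNotFoundError:
        raise SignalParseError(f"{meta_path}: missing meta.json") from None
    except json.JSONDecodeError as exc:
        raise SignalParseError(f"{meta_path}: invalid JSON ({exc})") from None
    missing = [k for k in _META_REQUIRED if k not in meta]
    if missing:
        raise SchemaError(f"{meta_path}: missing required keys {missing}")
    try:
        df = pd.read_csv(csv_path)
    except FileNotFoundError:
        raise SignalParseError(f"{csv_path}: missing signals.csv") from None
    except (pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise SignalParseError(f"{csv_path}: {exc}") from None

    for col in ("time_s", "insole_force_n", "com_x_m"):
        if col not in df.columns:
            raise SchemaError(f"{csv_path}: missing required column {col!r}")
    t = df["time_s"].to_numpy(float)
    if len(t) < 2 or np.any(np.diff(t) <= 0):
        raise SignalParseError(f"{csv_path}: time_s must be strictly increasing")
    fs = float(meta["fs_hz"])
    if not np.allclose(np.diff(t), 1.0 / fs, atol=1e-4):
        raise SignalParseError(f"{csv_path}: time_s is not uniform at the declared {fs} Hz")

    imus = {}
    for loc in IMU_LOCATIONS:
        cols = [f"{loc}_{ch}" for ch in IMU_CHANNELS]
        present = [c for c in cols if c in df.columns]
        if not present:
            continue  # optional location absent entirely
        if len(present) != len(cols):
            raise SchemaError(f"{csv_path}: location {loc!r} has partial channels {present}")
        imus[loc] = ImuChannelSet(
            location=loc,
            **{ch: df[f"{loc}_{ch}"].to_numpy(float) for ch in IMU_CHANNELS},
            fs=fs,
        )
    if not imus:
        raise SchemaError(f"{csv_path}: no IMU channel columns found")
    return TrialRecording(
        subject_id=str(meta["subject"]),
        condition_deg=int(meta["condition_deg"]),
        speed_label=str(meta["speed_label"]),
        imus=imus,
        insole_force=df["insole_force_n"].to_numpy(float),
        fs_insole=fs,
        com_x=df["com_x_m"].to_numpy(float),
        fs_com=fs,
        body_weight_N=float(meta["body_weight_n"]),
        trial_id=int(meta.get("trial_id", 0)),
    )
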