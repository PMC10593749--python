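"""Stride-level feature extraction from IMU channels and stride timing.

For every gait cycle and every IMU channel, five statistics are computed over
the stride window: the maximum, the minimum, the absolute impulse (time
integral of |x| over the whole stride), and the signed impulses of the stance
and swing phases.  Stance and swing time, measured by the insole, join the
table once per stride.  With one IMU location and both data streams this
gives 6 channels x 5 stats + 2 times = 32 feature columns; accelerometer-only
gives 17; each additional location adds 30.

Integration convention: phase impulses are trapezoidal integrals over the
closed sample windows [hs..to] and [to..next_hs], so stance + swing tiles the
stride integral exactly and a constant signal c over a T-second stride has
absolute impulse c*T.  Maximum/minimum are taken over [hs, next_hs).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .recordings import ACC_CHANNELS, IMU_CHANNELS, TrialRecording
from .segmentation import Stride

STAT_NAMES = ("max", "min", "abs_impulse", "swing_impulse", "stance_impulse")

#: columns identifying a stride row (not model features)
KEY_COLUMNS = ("subject_id", "condition_deg", "speed_label", "trial", "stride_index")

#: target/bookkeeping columns joined later (not model features)
TARGET_COLUMNS = ("at_peak_bw", "speed_mps", "kept", "com_r_squared")


def stride_channel_stats(
    signal: np.ndarray, fs: float, hs: int, to: int, next_hs: int
) -> dict[str, float]:
    """Five stride statistics of one channel; see module docstring for windows."""
    signal = np.asarray(signal, dtype=float)
    n = len(signal)
    if not (0 <= hs < to < next_hs <= n):
        raise IndexError(
            f"stride window ({hs}, {to}, {next_hs}) out of range for series of length {n}"
        )
    dt = 1.0 / fs
    window = signal[hs:next_hs]
    # closed windows for integration; clamp when next_hs is the series end
    end = min(next_hs, n - 1)
    stance = signal[hs : to + 1]
    swing = signal[to : end + 1]
    full = signal[hs : end + 1]
    return {
        "max": float(window.max()),
        "min": float(window.min()),
        "abs_impulse": float(np.trapezoid(np.abs(full), dx=dt)),
        "swing_impulse": float(np.trapezoid(swing, dx=dt)),
        "stance_impulse": float(np.trapezoid(stance, dx=dt)),
    }


def feature_column_names(
    locations: tuple[str, ...] = ("boot",), use_gyro: bool = True
) -> list[str]:
    """Deterministic feature-column order: location_channel_stat, then times."""
    channels = IMU_CHANNELS if use_gyro else ACC_CHANNELS
    cols = [
        f"{loc}_{ch}_{stat}" for loc in locations for ch in channels for stat in STAT_NAMES
    ]
    return cols + ["stance_time_s", "swing_time_s"]


def _map_index(ins_idx: int, fs_from: float, fs_to: float) -> int:
    """Insole-clock index -> IMU-clock index (round half up); streams share t=0."""
    return int(np.floor(ins_idx * fs_to / fs_from + 0.5))


def extract_features(
    trial: TrialRecording,
    strides: list[Stride],
    locations: tuple[str, ...] = ("boot",),
    use_gyro: bool = True,
) -> pd.DataFrame:
    """One feature row per stride for the requested sensor configuration.

    Stride boundaries live on the insole clock; when an IMU was decimated to a
    lower rate its sample windows are obtained by time-proportional index
    mapping (streams are synchronized at t = 0 by collection design).
    """
    for loc in locations:
        if loc not in trial.imus:
            raise KeyError(
                f"trial has no IMU at location {loc!r}; available: {sorted(trial.imus)}"
            )
    channels = IMU_CHANNELS if use_gyro else ACC_CHANNELS
    rows = []
    for i, stride in enumerate(strides):
        row: dict[str, float] = {
            "subject_id": trial.subject_id,
            "condition_deg": trial.condition_deg,
            "speed_label": trial.speed_label,
            "trial": trial.trial_id,
            "stride_index": i,
        }
        for loc in locations:
            imu = trial.imus[loc]
            if np.isclose(imu.fs, trial.fs_insole):
                hs, to, nhs = stride.hs_idx, stride.to_idx, stride.next_hs_idx
            else:
                hs = _map_index(stride.hs_idx, trial.fs_insole, imu.fs)
                to = _map_index(stride.to_idx, trial.fs_insole, imu.fs)
                nhs = _map_index(stride.next_hs_idx, trial.fs_insole, imu.fs)
                nhs = min(nhs, imu.n_samples)
            for ch in channels:
                stats = stride_channel_stats(imu.channel(ch), imu.fs, hs, to, nhs)
                for stat, value in stats.items():
                    row[f"{loc}_{ch}_{stat}"] = value
        row["stance_time_s"] = stride.stance_time_s
        row["swing_time_s"] = stride.swing_time_s
        rows.append(row)
    columns = list(KEY_COLUMNS) + feature_column_names(locations, use_gyro)
    return pd.DataFrame(rows, columns=columns)


def feature_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Drop key/target columns, leaving only model features."""
    drop = [c for c in table.columns if c in KEY_COLUMNS or c in TARGET_COLUMNS]
    return table.drop(columns=drop)
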