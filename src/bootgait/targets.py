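"""Prediction targets: peak Achilles tendon load per stride and trial walking speed.

Tendon load is estimated from the total insole force through a configurable
moment-balance lever ratio and normalized to body weight (BW).  The published
regional physics model this package's users may hold is deliberately not
reproduced here: the estimator is a documented, replaceable stand-in that is
monotone in plantar force; simulated cohorts carry generator ground truth for
validation.  Strides whose peak load falls under 0.5 BW are excluded from
modeling — surgical repair strength exceeds that level, so such strides are
not clinically informative loading events.

Walking speed is the net forward progression of the center of mass divided by
elapsed time, computed per trial; the linearity of COM displacement vs time
(R^2) is reported as a constant-speed quality check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats

from .segmentation import Stride

#: strides peaking under this load are excluded from the models
MIN_LOAD_BW = 0.5

#: trials whose COM displacement-vs-time R^2 falls under this are flagged
COM_R2_QC = 0.98


@dataclass(frozen=True)
class LoadModelParams:
    """Stand-in insole-to-Achilles mapping: tendon force = lever_ratio x plantar force."""

    lever_ratio: float = 1.0
    source: str = "stand_in"  # or "ground_truth" when taken from a simulator

    def __post_init__(self) -> None:
        if self.lever_ratio <= 0:
            raise ValueError("lever_ratio must be > 0")


def estimate_achilles_load(
    insole_force: np.ndarray, body_weight_N: float, params: LoadModelParams = LoadModelParams()
) -> np.ndarray:
    """Per-sample Achilles load in BW from total plantar force."""
    if body_weight_N <= 0:
        raise ValueError(f"body_weight_N must be > 0, got {body_weight_N}")
    force = np.asarray(insole_force, dtype=float)
    return params.lever_ratio * force / body_weight_N


def peak_load_per_stride(
    load_bw: np.ndarray, strides: list[Stride], min_bw: float = MIN_LOAD_BW
) -> list[tuple[float, bool]]:
    """Peak load over each stride window and its inclusion flag.

    The boundary is inclusive: a stride peaking at exactly ``min_bw`` is kept
    (only values *under* the threshold are excluded).
    """
    load_bw = np.asarray(load_bw, dtype=float)
    out = []
    for s in strides:
        if s.next_hs_idx > len(load_bw):
            raise IndexError("stride window exceeds load series length")
        peak = float(load_bw[s.hs_idx : s.next_hs_idx].max())
        out.append((peak, peak >= min_bw))
    return out


def trial_walking_speed(com_x: np.ndarray, fs_com: float) -> tuple[float, float]:
    """Trial walking speed (m/s) and the COM-vs-time R^2 quality score.

    Speed is net displacement over elapsed time (endpoints); R^2 comes from
    the least-squares line of position on time.  A low R^2 signals
    non-constant speed but does not reject the trial.
    """
    x = np.asarray(com_x, dtype=float)
    if len(x) < 2:
        raise ValueError("COM trace needs at least 2 samples")
    t = np.arange(len(x)) / fs_com
    elapsed = t[-1] - t[0]
    if elapsed <= 0:
        raise ValueError("zero elapsed time in COM trace")
    speed = (x[-1] - x[0]) / elapsed
    lr = _stats.linregress(t, x)
    return float(speed), float(lr.rvalue**2)
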