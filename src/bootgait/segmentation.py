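"""Gait-event detection and stride segmentation from the insole force trace.

Foot-ground contact is detected by the total plantar force crossing a 50 N
threshold: with that floor, the force minima separating steps lie in the
sub-threshold (swing) region, so threshold crossings give reproducible
heel-strike and toe-off instants where raw local-minimum positions would be
noise-sensitive.  A stride (gait cycle) runs from one heel strike to the next.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: default contact threshold on total plantar force
FORCE_THRESHOLD_N = 50.0

#: minimum sub-threshold dwell for an on/off transition to count (debounce)
MIN_OFF_S = 0.05


@dataclass(frozen=True)
class Stride:
    """One gait cycle, heel strike to next heel strike, on the insole clock."""

    hs_idx: int
    to_idx: int
    next_hs_idx: int
    stance_time_s: float
    swing_time_s: float

    def __post_init__(self) -> None:
        if not (self.hs_idx < self.to_idx < self.next_hs_idx):
            raise ValueError(
                f"stride indices must satisfy hs < to < next_hs, got "
                f"({self.hs_idx}, {self.to_idx}, {self.next_hs_idx})"
            )


def detect_gait_events(
    force: np.ndarray,
    fs: float,
    threshold_N: float = FORCE_THRESHOLD_N,
    min_off_s: float = MIN_OFF_S,
) -> list[tuple[int, int]]:
    """Detect (heel-strike, toe-off) sample-index pairs from insole force.

    Heel strike is the first sample where force rises to >= ``threshold_N``
    after a sub-threshold interval of at least ``min_off_s``; toe-off is the
    first subsequent sample where force stays below threshold for at least
    ``min_off_s``.  Sub-threshold dips shorter than the debounce are treated
    as chatter and merged into the surrounding contact.  Leading and trailing
    partial contacts (trace starts on the ground, or ends before toe-off is
    confirmed) are discarded.  Returns an empty list when no complete contact
    exists.
    """
    force = np.asarray(force, dtype=float)
    if force.size == 0:
        raise ValueError("force trace is empty")
    if threshold_N <= 0:
        raise ValueError("threshold_N must be > 0")
    min_off = max(1, int(round(min_off_s * fs)))

    above = force >= threshold_N
    if not above.any():
        return []

    # run-length encode the on/off state
    change = np.flatnonzero(np.diff(above.astype(np.int8))) + 1
    bounds = np.concatenate(([0], change, [above.size]))
    runs = [
        (int(bounds[i]), int(bounds[i + 1]), bool(above[bounds[i]]))
        for i in range(len(bounds) - 1)
    ]

    # chatter suppression: interior off-runs shorter than the debounce are
    # dips inside a contact, not swing — flip them to on and coalesce
    flipped = [
        (start, stop, True)
        if (not on and 0 < i < len(runs) - 1 and (stop - start) < min_off)
        else (start, stop, on)
        for i, (start, stop, on) in enumerate(runs)
    ]
    coalesced: list[list] = []
    for start, stop, on in flipped:
        if coalesced and coalesced[-1][2] == on:
            coalesced[-1][1] = stop
        else:
            coalesced.append([start, stop, on])

    events: list[tuple[int, int]] = []
    for i, (start, stop, is_on) in enumerate(coalesced):
        if not is_on:
            continue
        if i == 0:
            continue  # trace starts mid-contact: leading partial, discard
        prev_start, prev_stop, _ = coalesced[i - 1]
        if (prev_stop - prev_start) < min_off:
            continue  # heel strike not preceded by a confirmed off interval
        if i + 1 >= len(coalesced):
            continue  # trace ends mid-contact: trailing partial, discard
        nxt_start, nxt_stop, _ = coalesced[i + 1]
        if (nxt_stop - nxt_start) < min_off:
            continue  # toe-off not confirmed by a full debounce interval
        events.append((start, stop))
    return events


def segment_strides(events: list[tuple[int, int]], fs: float) -> list[Stride]:
    """Cut consecutive heel strikes into strides with stance/swing times.

    Each stride is the half-open window ``[hs_idx, next_hs_idx)``; the last
    contact has no following heel strike and is dropped, so ``n`` complete
    contacts yield ``n - 1`` strides.
    """
    if len(events) < 2:
        return []
    strides = []
    for (hs, to), (next_hs, _) in zip(events[:-1], events[1:]):
        strides.append(
            Stride(
                hs_idx=hs,
                to_idx=to,
                next_hs_idx=next_hs,
                stance_time_s=(to - hs) / fs,
                swing_time_s=(next_hs - to) / fs,
            )
        )
    return strides


def events_to_frame(strides: list[Stride]):
    """Optional tabular export of stride boundaries (events.csv dialect)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "stride": i,
                "hs_idx": s.hs_idx,
                "to_idx": s.to_idx,
                "next_hs_idx": s.next_hs_idx,
                "stance_time_s": s.stance_time_s,
                "swing_time_s": s.swing_time_s,
            }
            for i, s in enumerate(strides)
        ]
    )
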