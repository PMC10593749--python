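"""Training-paradigm evaluation, sensor ablations, learning curves, agreement.

Three training paradigms are compared per heel-wedge condition and target:

* **generalized** — leave-one-subject-out: the test subject contributes no
  training data; each subject is held out once and the per-subject MAPEs are
  aggregated as mean +/- SD across subjects.
* **hybridized** — half of the test subject's strides join the other
  subjects' data for training; the remaining half is the test set.
* **personalized** — the model is trained solely on half of the test
  subject's strides and tested on the other half.

The hybridized and personalized paradigms share one 50/50 stride split per
subject (a :class:`SplitPlan`), so their test sets coincide and paradigm
comparisons are paired.  Sensor ablations re-run the whole pipeline —
decimate, segment, extract, evaluate — for each sensor configuration, since
decimation changes the extracted features.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import segmentation
from .features import extract_features
from .model import ModelConfig, StrideLassoModel, grade_mape, mape
from .recordings import TrialRecording, check_integrity, decimate_trial
from .targets import (
    MIN_LOAD_BW,
    LoadModelParams,
    estimate_achilles_load,
    peak_load_per_stride,
    trial_walking_speed,
)

logger = logging.getLogger("bootgait")

PARADIGMS = ("generalized", "hybridized", "personalized")
TARGETS = ("at_peak_bw", "speed_mps")


@dataclass(frozen=True)
class SensorConfig:
    """One sensor-configuration row: IMU locations, data streams, rate."""

    locations: tuple[str, ...] = ("boot",)
    use_gyro: bool = True
    fs: float = 100.0

    def label(self) -> str:
        streams = "acc+gyr" if self.use_gyro else "acc"
        return f"{'+'.join(self.locations)}/{streams}/{self.fs:g}Hz"


def default_ablation_grid() -> list[SensorConfig]:
    """The five benchmark sensor configurations (baseline first)."""
    return [
        SensorConfig(("boot",), True, 100.0),
        SensorConfig(("boot",), False, 100.0),
        SensorConfig(("boot",), True, 50.0),
        SensorConfig(("boot",), True, 25.0),
        SensorConfig(("boot", "contra_foot"), True, 100.0),
    ]


# ---------------------------------------------------------------------------
# dataset assembly: recordings -> stride feature/target table


def build_stride_dataset(
    trials: list[TrialRecording],
    sensor_config: SensorConfig = SensorConfig(),
    load_params: LoadModelParams = LoadModelParams(),
    min_bw: float = MIN_LOAD_BW,
    integrity_tolerance_s: float = 0.1,
    threshold_N: float = 50.0,
) -> tuple[pd.DataFrame, dict]:
    """Run the processing pipeline over a cohort of recordings.

    Returns the stride-level table (features + targets + ``kept`` flag) and an
    attrition audit: trials rejected by the integrity screen, strides
    segmented, strides dropped by the minimum-load rule.
    """
    frames = []
    audit = {
        "trials_total": len(trials),
        "trials_rejected": 0,
        "strides_segmented": 0,
        "strides_dropped_min_bw": 0,
        "strides_kept": 0,
    }
    for trial in trials:
        report = check_integrity(trial, integrity_tolerance_s)
        if not report.accepted:
            audit["trials_rejected"] += 1
            logger.warning(
                "rejecting trial %s/%sdeg/%s/%d: %s",
                trial.subject_id,
                trial.condition_deg,
                trial.speed_label,
                trial.trial_id,
                report.reason,
            )
            continue
        if not np.isclose(sensor_config.fs, next(iter(trial.imus.values())).fs):
            trial = decimate_trial(trial, sensor_config.fs)
        events = segmentation.detect_gait_events(
            trial.insole_force, trial.fs_insole, threshold_N
        )
        strides = segmentation.segment_strides(events, trial.fs_insole)
        if not strides:
            continue
        table = extract_features(
            trial, strides, locations=sensor_config.locations, use_gyro=sensor_config.use_gyro
        )
        load = estimate_achilles_load(trial.insole_force, trial.body_weight_N, load_params)
        peaks = peak_load_per_stride(load, strides, min_bw=min_bw)
        speed, r2 = trial_walking_speed(trial.com_x, trial.fs_com)
        table["at_peak_bw"] = [p for p, _ in peaks]
        table["kept"] = [k for _, k in peaks]
        table["speed_mps"] = speed
        table["com_r_squared"] = r2
        audit["strides_segmented"] += len(strides)
        audit["strides_dropped_min_bw"] += sum(1 for _, k in peaks if not k)
        frames.append(table)
    if not frames:
        raise ValueError("no usable strides in the provided trials")
    dataset = pd.concat(frames, ignore_index=True)
    audit["strides_kept"] = int(dataset["kept"].sum())
    logger.info(
        "dataset: %d trials (%d rejected), %d strides segmented, %d dropped under %.2f BW, %d kept",
        audit["trials_total"],
        audit["trials_rejected"],
        audit["strides_segmented"],
        audit["strides_dropped_min_bw"],
        min_bw,
        audit["strides_kept"],
    )
    return dataset, audit


# ---------------------------------------------------------------------------
# results containers


@dataclass
class EvalResult:
    """Per-subject MAPEs and their mean +/- SD for one evaluation cell."""

    paradigm: str
    condition_deg: int
    target: str
    sensor_config: SensorConfig
    subjects: list[str]
    per_subject_mape: list[float]
    mape_mean: float = field(init=False)
    mape_sd: float = field(init=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.per_subject_mape, dtype=float)
        self.mape_mean = float(arr.mean())
        self.mape_sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0

    @property
    def grade(self) -> str:
        return grade_mape(self.mape_mean)

    def to_row(self) -> dict:
        return {
            "paradigm": self.paradigm,
            "condition_deg": self.condition_deg,
            "target": self.target,
            "locations": "+".join(self.sensor_config.locations),
            "use_gyro": self.sensor_config.use_gyro,
            "fs_hz": self.sensor_config.fs,
            "n_subjects": len(self.subjects),
            "mape_mean": self.mape_mean,
            "mape_sd": self.mape_sd,
            "grade": self.grade,
        }


@dataclass(frozen=True)
class SplitPlan:
    """Seeded per-subject 50/50 stride partition (row labels of the dataset)."""

    assignments: dict
    seed: int

    def train_half(self, subject: str) -> np.ndarray:
        return self.assignments[subject][0]

    def test_half(self, subject: str) -> np.ndarray:
        return self.assignments[subject][1]


def make_split_plan(kept: pd.DataFrame, seed: int) -> SplitPlan:
    """Random stride-level halves per subject; sizes differ by at most one."""
    rng = np.random.default_rng(seed)
    assignments = {}
    for subject, group in kept.groupby("subject_id", sort=True):
        idx = group.index.to_numpy()
        perm = rng.permutation(idx)
        half = len(perm) // 2
        assignments[str(subject)] = (np.sort(perm[:half]), np.sort(perm[half:]))
    return SplitPlan(assignments=assignments, seed=seed)


# ---------------------------------------------------------------------------
# paradigms


def _kept_condition(dataset: pd.DataFrame, condition_deg: int) -> pd.DataFrame:
    sel = dataset[(dataset["condition_deg"] == condition_deg) & dataset["kept"]]
    if sel.empty:
        raise ValueError(f"no kept strides for condition {condition_deg} deg")
    return sel


def _subjects_with_strides(kept: pd.DataFrame) -> list[str]:
    counts = kept.groupby("subject_id").size()
    empty = [s for s in counts.index if counts[s] == 0]
    for s in empty:
        logger.warning("subject %s has zero kept strides; excluded from evaluation", s)
    return [str(s) for s in counts.index if counts[s] > 0]


def _fit_and_score(
    train: pd.DataFrame, test: pd.DataFrame, target: str, config: ModelConfig
) -> float:
    results = StrideLassoModel.from_dataframe(train, target).fit(config)
    return results.score_mape(test, test[target])


def _sensor_of(dataset: pd.DataFrame, sensor_config: SensorConfig | None) -> SensorConfig:
    return sensor_config if sensor_config is not None else SensorConfig()


def evaluate_generalized(
    dataset: pd.DataFrame,
    condition_deg: int,
    target: str,
    config: ModelConfig = ModelConfig(),
    sensor_config: SensorConfig | None = None,
) -> EvalResult:
    """Leave-one-subject-out evaluation: no test-subject data in training."""
    kept = _kept_condition(dataset, condition_deg)
    subjects = _subjects_with_strides(kept)
    if len(subjects) < 2:
        raise ValueError("generalized evaluation needs at least 2 subjects")
    mapes = []
    for subject in subjects:
        train = kept[kept["subject_id"] != subject]
        test = kept[kept["subject_id"] == subject]
        mapes.append(_fit_and_score(train, test, target, config))
    return EvalResult(
        "generalized", condition_deg, target, _sensor_of(dataset, sensor_config), subjects, mapes
    )


def evaluate_hybridized(
    dataset: pd.DataFrame,
    condition_deg: int,
    target: str,
    split: SplitPlan,
    config: ModelConfig = ModelConfig(),
    sensor_config: SensorConfig | None = None,
) -> EvalResult:
    """Other subjects' strides plus half the test subject's; tested on the rest."""
    kept = _kept_condition(dataset, condition_deg)
    subjects = _subjects_with_strides(kept)
    evaluated, mapes = [], []
    for subject in subjects:
        test = kept.loc[split.test_half(subject)]
        if test.empty:
            logger.warning("subject %s has an empty test half; excluded from hybridized", subject)
            continue
        others = kept[kept["subject_id"] != subject]
        train = pd.concat([others, kept.loc[split.train_half(subject)]])
        evaluated.append(subject)
        mapes.append(_fit_and_score(train, test, target, config))
    return EvalResult(
        "hybridized", condition_deg, target, _sensor_of(dataset, sensor_config), evaluated, mapes
    )


def evaluate_personalized(
    dataset: pd.DataFrame,
    condition_deg: int,
    target: str,
    split: SplitPlan,
    config: ModelConfig = ModelConfig(),
    sensor_config: SensorConfig | None = None,
) -> EvalResult:
    """Trained solely on half the subject's own strides; tested on the rest."""
    kept = _kept_condition(dataset, condition_deg)
    subjects = _subjects_with_strides(kept)
    evaluated, mapes = [], []
    for subject in subjects:
        train = kept.loc[split.train_half(subject)]
        test = kept.loc[split.test_half(subject)]
        if len(train) < config.inner_cv_folds or test.empty:
            logger.warning(
                "subject %s keeps too few strides (%d) for a personalized model; excluded",
                subject,
                len(train) + len(test),
            )
            continue
        evaluated.append(subject)
        mapes.append(_fit_and_score(train, test, target, config))
    if not evaluated:
        raise ValueError("no subject keeps enough strides for a personalized model")
    return EvalResult(
        "personalized", condition_deg, target, _sensor_of(dataset, sensor_config), evaluated, mapes
    )


def evaluate_paradigm(
    dataset: pd.DataFrame,
    paradigm: str,
    condition_deg: int,
    target: str,
    config: ModelConfig = ModelConfig(),
    split: SplitPlan | None = None,
    split_seed: int = 0,
    sensor_config: SensorConfig | None = None,
) -> EvalResult:
    """Dispatch on paradigm name, building a split plan when one is needed."""
    if paradigm == "generalized":
        return evaluate_generalized(dataset, condition_deg, target, config, sensor_config)
    if split is None:
        split = make_split_plan(_kept_condition(dataset, condition_deg), split_seed)
    if paradigm == "hybridized":
        return evaluate_hybridized(dataset, condition_deg, target, split, config, sensor_config)
    if paradigm == "personalized":
        return evaluate_personalized(dataset, condition_deg, target, split, config, sensor_config)
    raise ValueError(f"unknown paradigm {paradigm!r}; expected one of {PARADIGMS}")


def evaluate_baseline(
    dataset: pd.DataFrame,
    conditions: tuple[int, ...] = (30, 5, 0),
    targets: tuple[str, ...] = TARGETS,
    paradigms: tuple[str, ...] = PARADIGMS,
    config: ModelConfig = ModelConfig(),
    split_seed: int = 0,
    sensor_config: SensorConfig | None = None,
) -> list[EvalResult]:
    """The full baseline grid: conditions x paradigms x targets (18 cells)."""
    results = []
    for condition in conditions:
        split = make_split_plan(_kept_condition(dataset, condition), split_seed)
        for target in targets:
            for paradigm in paradigms:
                results.append(
                    evaluate_paradigm(
                        dataset,
                        paradigm,
                        condition,
                        target,
                        config,
                        split=split,
                        sensor_config=sensor_config,
                    )
                )
    return results


# ---------------------------------------------------------------------------
# ablations


def run_ablation_grid(
    trials: list[TrialRecording],
    grid: list[SensorConfig] | None = None,
    paradigms: tuple[str, ...] = ("generalized",),
    conditions: tuple[int, ...] = (30, 5, 0),
    targets: tuple[str, ...] = TARGETS,
    config: ModelConfig = ModelConfig(),
    split_seed: int = 0,
    load_params: LoadModelParams = LoadModelParams(),
) -> list[EvalResult]:
    """Re-run the whole pipeline per sensor configuration and evaluate.

    Features are re-extracted for every grid row because decimation changes
    them; segmentation and targets always come from the lab-grade insole and
    COM streams.
    """
    if grid is None:
        grid = default_ablation_grid()
    results = []
    for sensor_config in grid:
        dataset, _ = build_stride_dataset(trials, sensor_config, load_params=load_params)
        results.extend(
            evaluate_baseline(
                dataset,
                conditions=conditions,
                targets=targets,
                paradigms=paradigms,
                config=config,
                split_seed=split_seed,
                sensor_config=sensor_config,
            )
        )
    return results


# ---------------------------------------------------------------------------
# learning curve


def learning_curve(
    dataset: pd.DataFrame,
    condition_deg: int,
    target: str,
    fractions: tuple[float, ...] = (0.1, 0.2, 0.4, 0.6, 0.8, 0.9, 1.0),
    config: ModelConfig = ModelConfig(),
    n_repeats: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Validation MAPE vs training-set fraction under leave-one-subject-out.

    For each fraction, the pooled training rows of every LOSO fold are
    subsampled at that fraction (repeated ``n_repeats`` times with fresh
    seeds and averaged); fraction 1.0 reproduces the generalized evaluation
    exactly.  The returned table carries the pairwise deltas between
    consecutive fractions.
    """
    for f in fractions:
        if not (0 < f <= 1):
            raise ValueError(f"fractions must lie in (0, 1], got {f}")
    kept = _kept_condition(dataset, condition_deg)
    subjects = _subjects_with_strides(kept)
    rows = []
    for f in fractions:
        repeats = 1 if f == 1.0 else n_repeats
        repeat_mapes = []
        for r in range(repeats):
            rng = np.random.default_rng(np.random.SeedSequence((seed, r)))
            fold_mapes = []
            for subject in subjects:
                train = kept[kept["subject_id"] != subject]
                if f < 1.0:
                    n_take = max(int(round(f * len(train))), 1)
                    take = np.sort(rng.choice(len(train), size=n_take, replace=False))
                    train = train.iloc[take]
                if len(train) < config.inner_cv_folds:
                    raise ValueError(
                        f"fraction {f} leaves {len(train)} rows, fewer than "
                        f"inner_cv_folds={config.inner_cv_folds}"
                    )
                test = kept[kept["subject_id"] == subject]
                fold_mapes.append(_fit_and_score(train, test, target, config))
            repeat_mapes.append(float(np.mean(fold_mapes)))
        rows.append({"fraction": f, "mape_mean": float(np.mean(repeat_mapes))})
    curve = pd.DataFrame(rows)
    curve["delta_from_previous"] = curve["mape_mean"].diff()
    return curve


# ---------------------------------------------------------------------------
# two-sensor agreement


def sensor_agreement(
    sig_a: np.ndarray, sig_b: np.ndarray, fs: float = 100.0, max_lag_s: float = 1.0
) -> float:
    """Agreement between two sensors' recordings of the same motion, percent.

    The maximum over integer lags (|lag| <= ``max_lag_s``) of the normalized
    cross-correlation — the Pearson correlation of the overlapping segments —
    times 100.  The maximum is signed, so an anti-phase pair scores -100, not
    +100.  The lag range is bounded because residual synchronization error is
    small and an unbounded search invites spurious maxima.
    """
    a = np.asarray(sig_a, dtype=float)
    b = np.asarray(sig_b, dtype=float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("sensor_agreement requires non-constant series")
    max_lag = int(round(max_lag_s * fs))
    best = -np.inf
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            x, y = a[: len(a) - lag], b[lag:]
        else:
            x, y = a[-lag:], b[: len(b) + lag]
        m = min(len(x), len(y))
        if m < 8:
            continue
        x, y = x[:m], y[:m]
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            continue
        c = float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))
        best = max(best, c)
    if not np.isfinite(best):
        raise ValueError("no overlapping non-constant segment within the lag range")
    return 100.0 * best


# ---------------------------------------------------------------------------
# result export


def results_table(results: list[EvalResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in results])


def write_results(results: list[EvalResult], out_dir) -> tuple[Path, Path]:
    """Write results.csv (one row per cell) and results.json (per-subject vectors)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / "results.csv"
    results_table(results).to_csv(csv_path, index=False, float_format="%.6f")
    payload = [
        {**r.to_row(), "subjects": r.subjects, "per_subject_mape": r.per_subject_mape}
        for r in results
    ]
    json_path = out_dir / "results.json"
    json_path.write_text(json.dumps(payload, indent=2))
    return csv_path, json_path


def plot_paradigm_comparison(results: list[EvalResult], target: str, ax=None):
    """Grouped bar chart of mean MAPE by condition and paradigm for one target."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    table = results_table([r for r in results if r.target == target])
    conditions = sorted(table["condition_deg"].unique(), reverse=True)
    width = 0.8 / len(PARADIGMS)
    for i, paradigm in enumerate(PARADIGMS):
        sub = table[table["paradigm"] == paradigm].set_index("condition_deg")
        xs = np.arange(len(conditions)) + i * width
        heights = [sub.loc[c, "mape_mean"] if c in sub.index else np.nan for c in conditions]
        errs = [sub.loc[c, "mape_sd"] if c in sub.index else np.nan for c in conditions]
        ax.bar(xs, heights, width=width, yerr=errs, capsize=3, label=paradigm)
    ax.set_xticks(np.arange(len(conditions)) + 0.4 - width / 2)
    ax.set_xticklabels([f"{c} deg" for c in conditions])
    ax.set_ylabel("MAPE (%)")
    ax.set_title(target)
    ax.legend()
    return ax
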