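"""Paradigm mechanics, split plans, agreement score, learning curve."""

import numpy as np
import pandas as pd
import pytest

from bootgait import (
    ModelConfig,
    SimConfig,
    build_stride_dataset,
    evaluate_generalized,
    evaluate_hybridized,
    evaluate_personalized,
    generate_cohort,
    learning_curve,
    make_split_plan,
    sensor_agreement,
)
from bootgait.evaluation import (
    EvalResult,
    SensorConfig,
    _kept_condition,
    default_ablation_grid,
    evaluate_baseline,
    results_table,
)

FAST = ModelConfig(n_penalties=8, inner_cv_folds=3, seed=0)


def linear_frame(n_subjects=2, n_strides=30, subject_shift=0.0, noise=0.0, seed=0):
    """Minimal stride table whose target is linear in two features."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        f1 = rng.uniform(0, 1, n_strides)
        f2 = rng.uniform(0, 1, n_strides)
        y = 2.0 + 1.0 * f1 + 0.5 * f2 + s * subject_shift + noise * rng.standard_normal(n_strides)
        for i in range(n_strides):
            rows.append(
                {
                    "subject_id": f"S{s}",
                    "condition_deg": 0,
                    "speed_label": "medium",
                    "trial": 0,
                    "stride_index": i,
                    "f1": f1[i],
                    "f2": f2[i],
                    "at_peak_bw": y[i],
                    "speed_mps": 1.0,
                    "kept": True,
                    "com_r_squared": 1.0,
                }
            )
    return pd.DataFrame(rows)


class TestSplitPlan:
    def test_halves_disjoint_exhaustive_and_balanced(self, tiny_dataset):
        kept = _kept_condition(tiny_dataset, 0)
        plan = make_split_plan(kept, seed=1)
        for subject, group in kept.groupby("subject_id"):
            train, test = plan.train_half(subject), plan.test_half(subject)
            assert set(train).isdisjoint(test)
            assert set(train) | set(test) == set(group.index)
            assert abs(len(train) - len(test)) <= 1

    def test_seeded_reproducibility(self, tiny_dataset):
        kept = _kept_condition(tiny_dataset, 0)
        a = make_split_plan(kept, seed=9)
        b = make_split_plan(kept, seed=9)
        for s in a.assignments:
            np.testing.assert_array_equal(a.train_half(s), b.train_half(s))


class TestParadigms:
    def test_identical_subjects_zero_noise_give_zero_mape(self):
        frame = linear_frame(n_subjects=2, subject_shift=0.0, noise=0.0)
        res = evaluate_generalized(frame, 0, "at_peak_bw", FAST)
        assert res.mape_mean < 0.5
        assert res.mape_sd < 0.5

    def test_one_model_and_mape_per_subject(self):
        frame = linear_frame(n_subjects=4, noise=0.05)
        res = evaluate_generalized(frame, 0, "at_peak_bw", FAST)
        assert len(res.per_subject_mape) == 4
        assert res.subjects == ["S0", "S1", "S2", "S3"]

    def test_subject_offsets_penalize_generalized_not_personalized(self):
        frame = linear_frame(n_subjects=4, subject_shift=1.0, noise=0.01, seed=2)
        split = make_split_plan(_kept_condition(frame, 0), seed=0)
        gen = evaluate_generalized(frame, 0, "at_peak_bw", FAST)
        pers = evaluate_personalized(frame, 0, "at_peak_bw", split, FAST)
        assert gen.mape_mean > pers.mape_mean

    def test_hybridized_close_to_generalized_without_subject_effects(self):
        frame = linear_frame(n_subjects=4, subject_shift=0.0, noise=0.05, seed=3)
        split = make_split_plan(_kept_condition(frame, 0), seed=0)
        gen = evaluate_generalized(frame, 0, "at_peak_bw", FAST)
        hyb = evaluate_hybridized(frame, 0, "at_peak_bw", split, FAST)
        assert abs(gen.mape_mean - hyb.mape_mean) < 1.0

    def test_shared_split_gives_identical_test_sets(self, tiny_dataset):
        kept = _kept_condition(tiny_dataset, 0)
        split = make_split_plan(kept, seed=4)
        hyb = evaluate_hybridized(tiny_dataset, 0, "at_peak_bw", split, FAST)
        pers = evaluate_personalized(tiny_dataset, 0, "at_peak_bw", split, FAST)
        assert hyb.subjects == pers.subjects

    def test_personalized_independent_of_other_subjects(self):
        frame = linear_frame(n_subjects=3, subject_shift=0.5, noise=0.02, seed=4)
        split = make_split_plan(_kept_condition(frame, 0), seed=0)
        base = evaluate_personalized(frame, 0, "at_peak_bw", split, FAST)
        tampered = frame.copy()
        mask = tampered.subject_id != "S0"
        tampered.loc[mask, "at_peak_bw"] = tampered.loc[mask, "at_peak_bw"] * 3.0
        again = evaluate_personalized(tampered, 0, "at_peak_bw", split, FAST)
        assert again.per_subject_mape[0] == pytest.approx(base.per_subject_mape[0], abs=1e-9)

    def test_mean_recomputes_from_per_subject_values(self):
        res = EvalResult("generalized", 0, "at_peak_bw", SensorConfig(), ["a", "b"], [4.0, 8.0])
        assert res.mape_mean == pytest.approx(np.mean(res.per_subject_mape), abs=1e-12)
        assert res.grade in {"excellent", "acceptable", "unacceptable"}

    def test_fewer_than_two_subjects_rejected(self):
        frame = linear_frame(n_subjects=2).query("subject_id == 'S0'")
        with pytest.raises(ValueError):
            evaluate_generalized(frame, 0, "at_peak_bw", FAST)


class TestBaselineGrid:
    def test_full_grid_has_18_cells(self):
        cfg = SimConfig(
            n_subjects=2, trials_per_cell=1, strides_per_trial=6, seed=8, subject_sd_load_bw=0.1
        )
        cohort = generate_cohort(cfg)
        dataset, _ = build_stride_dataset(cohort.trials)
        results = evaluate_baseline(dataset, config=FAST)
        table = results_table(results)
        assert len(table) == 18
        assert set(table.paradigm) == {"generalized", "hybridized", "personalized"}
        assert set(table.condition_deg) == {30, 5, 0}
        assert set(table.target) == {"at_peak_bw", "speed_mps"}

    def test_default_ablation_grid_matches_benchmark_rows(self):
        grid = default_ablation_grid()
        labels = [(g.locations, g.use_gyro, g.fs) for g in grid]
        assert labels == [
            (("boot",), True, 100.0),
            (("boot",), False, 100.0),
            (("boot",), True, 50.0),
            (("boot",), True, 25.0),
            (("boot", "contra_foot"), True, 100.0),
        ]


class TestLearningCurve:
    def test_full_fraction_reproduces_generalized(self):
        frame = linear_frame(n_subjects=3, noise=0.05, seed=5)
        gen = evaluate_generalized(frame, 0, "at_peak_bw", FAST)
        curve = learning_curve(frame, 0, "at_peak_bw", fractions=(1.0,), config=FAST)
        assert curve.mape_mean.iloc[0] == pytest.approx(gen.mape_mean, abs=1e-12)

    def test_curve_length_and_delta_column(self):
        frame = linear_frame(n_subjects=3, n_strides=40, noise=0.05, seed=6)
        curve = learning_curve(
            frame, 0, "at_peak_bw", fractions=(0.4, 0.8, 1.0), config=FAST, n_repeats=2
        )
        assert len(curve) == 3
        assert np.isnan(curve.delta_from_previous.iloc[0])
        assert np.isfinite(curve.delta_from_previous.iloc[1:]).all()

    def test_invalid_fraction_rejected(self):
        frame = linear_frame(n_subjects=2)
        with pytest.raises(ValueError):
            learning_curve(frame, 0, "at_peak_bw", fractions=(0.0,), config=FAST)


class TestSensorAgreement:
    def test_self_agreement_is_100(self, rng):
        sig = rng.normal(size=400)
        assert sensor_agreement(sig, sig) == pytest.approx(100.0)

    def test_delayed_copy_still_100(self, rng):
        sig = rng.normal(size=400)
        delayed = np.roll(sig, 10)
        assert sensor_agreement(sig, delayed, fs=100.0, max_lag_s=0.5) == pytest.approx(
            100.0, abs=1e-9
        )

    def test_anti_phase_scores_poorly(self, rng):
        sig = rng.normal(size=400)
        # at lag 0 the signed correlation is exactly -100%
        assert sensor_agreement(sig, -sig, max_lag_s=0.0) == pytest.approx(-100.0)
        # the signed maximum over lags never rescues an inverted sensor
        assert sensor_agreement(sig, -sig) < 50.0

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            sensor_agreement(np.ones(100), np.arange(100.0))
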