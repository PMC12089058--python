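"""Macro metrics, frozen pipelines, online replay, LOO-CV structure."""

import numpy as np
import pytest

import fnirsbci as fb
from fnirsbci import evaluate, featurize, synth
from fnirsbci.synth import REST, TASK_A, TASK_B


def _brute_force_metrics(cm):
    """Independent loop-based macro metrics (the oracle for Eqs 1-3)."""
    k = cm.shape[0]
    precisions, recalls, f1s = [], [], []
    for i in range(k):
        tp = cm[i, i]
        fp = sum(cm[j, i] for j in range(k) if j != i)
        fn = sum(cm[i, j] for j in range(k) if j != i)
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f = 2 * p * r / (p + r) if p + r else 0.0
        precisions.append(p)
        recalls.append(r)
        f1s.append(f)
    return (
        sum(precisions) / k,
        sum(recalls) / k,
        sum(f1s) / k,
    )


class TestMetrics:
    def test_agrees_with_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            k = rng.integers(2, 5)
            cm = rng.integers(0, 40, size=(k, k))
            if cm.sum() == 0:
                continue
            rep = evaluate.metrics_from_confusion(cm)
            mp, mr, mf = _brute_force_metrics(cm)
            assert np.isclose(rep.macro_precision, mp)
            assert np.isclose(rep.macro_recall, mr)
            assert np.isclose(rep.macro_f1, mf)

    def test_perfect_diagonal_all_ones(self):
        rep = evaluate.metrics_from_confusion(np.diag([10, 20]))
        assert rep.macro_precision == rep.macro_recall == rep.macro_f1 == 1.0

    def test_zero_denominator_convention(self):
        # nothing predicted as class 1, nothing truly class 1 beyond FN
        rep = evaluate.metrics_from_confusion(np.array([[5, 0], [3, 0]]))
        assert rep.precision[1] == rep.recall[1] == rep.f1[1] == 0.0

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            evaluate.metrics_from_confusion(np.zeros((2, 2), int))

    def test_f1_harmonic_mean(self):
        assert evaluate.round_half_up(evaluate.f1_from_precision_recall(1.0, 0.929)) == 0.963
        assert evaluate.f1_from_precision_recall(0.0, 0.0) == 0.0

    def test_aggregate_mean_and_population_sd(self):
        mean, sd = evaluate.aggregate_participants([0.4, 0.4, 0.4])
        assert np.isclose(mean, 0.4) and sd < 1e-12
        with pytest.raises(ValueError):
            evaluate.aggregate_participants([])


class TestSourceSubset:
    def test_all_is_identity(self, session):
        sub = evaluate.source_subset(session, "ALL")
        assert sub.channel_names == session.channel_names
        assert np.array_equal(sub.data, session.data)

    def test_lateral_keeps_six_long_channels_plus_short(self, session):
        sub = evaluate.source_subset(session, "LATERAL")
        longs = [c for c in sub.channels if c.side == "LATERAL"]
        shorts = [c for c in sub.channels if c.side == "SHORT_LATERAL"]
        assert len(longs) == 6  # 3 positions x 2 chromophores
        assert len(shorts) == 2  # 1 short position x 2 chromophores
        assert len(sub.channels) == 8

    def test_subset_is_idempotent(self, session):
        once = evaluate.source_subset(session, "MEDIAL")
        twice = evaluate.source_subset(once, "MEDIAL")
        assert once.channel_names == twice.channel_names

    def test_unknown_subset_rejected(self, session):
        with pytest.raises(ValueError):
            evaluate.source_subset(session, "FRONTAL")


class TestTrainedPipeline:
    def test_training_f1_high_in_strong_regime(self, session, online_pipeline_cfg):
        train = synth.split_by_groups(session, (0, 1))
        pipe = evaluate.train_pipeline([train], online_pipeline_cfg)
        table = evaluate.pipeline_features(pipe, train)
        preds = evaluate.pipeline_predict(pipe, table)
        rep = evaluate.metrics_from_labels(table.y, preds)
        assert rep.macro_f1 >= 0.9

    def test_selector_keeps_ten_of_twentyfour(self, session, online_pipeline_cfg):
        train = synth.split_by_groups(session, (0, 1))
        pipe = evaluate.train_pipeline([train], online_pipeline_cfg)
        assert len(pipe.feature_names) == 24
        assert len(pipe.selector.selected) == 10

    def test_missing_class_rejected(self, session, online_pipeline_cfg):
        only_a = session.select_samples(session.labels == TASK_A)
        with pytest.raises(ValueError, match="both task classes"):
            evaluate.train_pipeline([only_a], online_pipeline_cfg)

    def test_serialised_pipeline_predicts_identically(self, tmp_path, session, online_pipeline_cfg):
        train = synth.split_by_groups(session, (0, 1))
        test = synth.split_by_groups(session, (2,))
        pipe = evaluate.train_pipeline([train], online_pipeline_cfg)
        path = tmp_path / "pipeline.joblib"
        pipe.save(path)
        reloaded = evaluate.TrainedPipeline.load(path)
        p1, _, _ = evaluate.online_replay(pipe, test)
        p2, _, _ = evaluate.online_replay(reloaded, test)
        assert np.array_equal(p1, p2)


class TestOnlineReplay:
    def test_prediction_count_per_block(self, session, online_pipeline_cfg):
        """floor(block samples / stride) predictions per task block."""
        train = synth.split_by_groups(session, (0, 1))
        test = synth.split_by_groups(session, (2,))
        pipe = evaluate.train_pipeline([train], online_pipeline_cfg)
        preds, labels, _ = evaluate.online_replay(pipe, test)
        block_len = int(np.floor(180.0 * 5.8))
        expected = 2 * (block_len // 100)  # one A and one B block in the test group
        assert len(preds) == len(labels) == expected

    def test_replay_deterministic(self, session, online_pipeline_cfg):
        train = synth.split_by_groups(session, (0, 1))
        test = synth.split_by_groups(session, (2,))
        pipe = evaluate.train_pipeline([train], online_pipeline_cfg)
        p1, _, r1 = evaluate.online_replay(pipe, test)
        p2, _, r2 = evaluate.online_replay(pipe, test)
        assert np.array_equal(p1, p2)
        assert r1.macro_f1 == r2.macro_f1

    def test_replay_on_training_data_near_perfect(self, session, online_pipeline_cfg):
        train = synth.split_by_groups(session, (0, 1))
        pipe = evaluate.train_pipeline([train], online_pipeline_cfg)
        _, _, rep = evaluate.online_replay(pipe, train)
        assert rep.macro_f1 >= 0.9


class TestLoocv:
    def test_each_participant_tested_exactly_once(self, cv_strong, cohort):
        cell = cv_strong.cell("RF", 100)
        tested = [f.test_participant for f in cell.folds]
        assert sorted(tested) == sorted(s.participant_id for s in cohort)

    def test_pooled_and_per_fold_aggregations_available(self, cv_strong):
        cell = cv_strong.cell("SVM_LINEAR", 100)
        pooled = cell.macro_f1(evaluate.POOLED)
        per_fold = cell.macro_f1(evaluate.PER_FOLD_MEAN)
        assert 0.0 <= pooled <= 1.0
        assert 0.0 <= per_fold <= 1.0

    def test_leakage_guard_raises_on_injected_test_rows(self):
        table = featurize.FeatureTable(
            X=np.zeros((4, 2)),
            y=np.array([TASK_A, TASK_B, TASK_A, TASK_B]),
            participants=np.array(["P0", "P0", "P1", "P1"]),
            groups=np.zeros(4, int),
            names=["f0", "f1"],
        )
        with pytest.raises(evaluate.LeakageError):
            evaluate.ensure_no_leakage(table, "P1")
        evaluate.ensure_no_leakage(table, "P7")  # absent participant passes

    def test_duplicate_participants_rejected(self, session):
        with pytest.raises(ValueError, match="unique"):
            fb.loocv([session, session, session])

    def test_too_few_participants_rejected(self, session):
        with pytest.raises(ValueError, match="3 participants"):
            fb.loocv([session])


class TestSweepSummary:
    def test_table2_style_row_mean(self):
        row = [0.590, 0.690, 0.650, 0.680, 0.680, 0.710]
        assert evaluate.window_row_mean(row) == 0.667

    def test_constant_row_mean_is_constant(self):
        assert evaluate.window_row_mean([0.6, 0.6, 0.6]) == 0.6

    def test_missing_cell_raises(self, cv_strong):
        with pytest.raises(KeyError):
            evaluate.summarize_window_sweep(cv_strong, families=("LDA",))
        with pytest.raises(KeyError):
            cv_strong.cell("RF", 300)

    def test_summary_contains_mean_column(self, cv_strong):
        df = evaluate.summarize_window_sweep(cv_strong)
        assert "Mean" in df.columns
        assert set(df.index) == {"RF", "SVM_LINEAR"}
        assert (df["Mean"] == df["100"]).all()  # single-window sweep
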