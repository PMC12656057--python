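"""Class weights, fold assignment, metrics and the training loop."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import f1_score, precision_score, recall_score

import ictalnet as ic
from ictalnet.errors import ConfigurationError, LeakageError
from ictalnet.model import ArchitectureSpec, Network
from ictalnet.training import (
    TrainConfig,
    assign_folds,
    class_weights,
    fit_network,
    metrics_report,
    summarize_folds,
    train,
)


class TestClassWeights:
    def test_balanced_data_gives_unit_weights(self):
        labels = np.repeat(np.arange(5), 100)
        np.testing.assert_allclose(class_weights(labels).weights, 1.0)

    def test_corpus_event_counts(self):
        counts = (43, 6924, 942, 247, 380)
        labels = np.repeat(np.arange(5), counts)
        w = class_weights(labels)
        assert w[0] == pytest.approx(39.70, abs=0.01)   # absence
        assert w[1] == pytest.approx(0.2466, abs=0.0005)  # focal non-specific

    def test_absent_class_rejected(self):
        with pytest.raises(ConfigurationError):
            class_weights(np.array([0, 0, 1, 1]))


class TestFoldAssignment:
    def _table(self, n_patients=20, seed=0, n_classes=5):
        rng = np.random.default_rng(seed)
        rows = []
        for p in range(n_patients):
            klass = ic.CLASS_LABELS[rng.integers(0, n_classes)]
            for _ in range(int(rng.integers(3, 15))):
                rows.append({"patient_id": f"P{p:02d}", "label": klass})
        return pd.DataFrame(rows)

    def test_patient_exclusivity(self):
        table = self._table()
        fa = assign_folds(table, k=5, seed=0)
        for p in table["patient_id"].unique():
            assert p in fa.mapping
        folds = [fa.patients_in(f) for f in range(5)]
        assert sum(len(f) for f in folds) == table["patient_id"].nunique()
        assert all(len(f) > 0 for f in folds)

    def test_balanced_totals_two_classes(self):
        """Equal-size patients spread so fold totals differ by at most one patient."""
        rows = []
        for p in range(10):
            for _ in range(8):
                rows.append({"patient_id": f"P{p}", "label": "ABSZ" if p % 2 else "FNSZ"})
        fa = assign_folds(pd.DataFrame(rows), k=5, seed=1)
        totals = np.zeros(5, dtype=int)
        for p, f in fa.mapping.items():
            totals[f] += 8
        assert totals.max() - totals.min() <= 8

    def test_rare_class_warning(self):
        rows = [{"patient_id": "P0", "label": "ABSZ"}]
        rows += [{"patient_id": f"P{i}", "label": "FNSZ"} for i in range(1, 8)]
        with pytest.warns(UserWarning, match="ABSZ"):
            assign_folds(pd.DataFrame(rows), k=5, seed=0)

    def test_k_exceeding_patients_rejected(self):
        with pytest.raises(ValueError):
            assign_folds(self._table(n_patients=3), k=5)

    def test_deterministic_for_seed(self):
        table = self._table(seed=3)
        a = assign_folds(table, k=4, seed=9).mapping
        b = assign_folds(table, k=4, seed=9).mapping
        assert a == b


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.repeat(np.arange(5), 4)
        rep = metrics_report(y, y)
        assert rep.accuracy == 100.0
        for stats in rep.per_class.values():
            assert stats["f1"] == pytest.approx(100.0)
        np.testing.assert_allclose(np.diag(rep.confusion_percent), 100.0)

    def test_degenerate_single_prediction(self):
        """truth (A,A,B,B), predicted all A."""
        with pytest.warns(UserWarning):
            rep = metrics_report([0, 0, 1, 1], [0, 0, 0, 0],
                                 class_names=["A", "B", "C", "D", "E"])
        a = rep.per_class["A"]
        assert a["sensitivity"] == 100.0
        assert a["specificity"] == 0.0
        assert a["precision"] == 50.0
        assert a["f1"] == pytest.approx(66.67, abs=0.01)
        assert rep.per_class["B"]["sensitivity"] == 0.0

    def test_matches_sklearn_on_random_labels(self):
        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 5, 300)
        y_pred = rng.integers(0, 5, 300)
        rep = metrics_report(y_true, y_pred)
        skl_prec = precision_score(y_true, y_pred, average=None, zero_division=0)
        skl_rec = recall_score(y_true, y_pred, average=None, zero_division=0)
        skl_f1 = f1_score(y_true, y_pred, average=None, zero_division=0)
        for i, name in enumerate(rep.classes):
            assert rep.per_class[name]["precision"] == pytest.approx(100 * skl_prec[i])
            assert rep.per_class[name]["sensitivity"] == pytest.approx(100 * skl_rec[i])
            assert rep.per_class[name]["f1"] == pytest.approx(100 * skl_f1[i])
        assert rep.macro["f1"] == pytest.approx(
            100 * f1_score(y_true, y_pred, average="macro", zero_division=0)
        )

    def test_confusion_rows_sum_to_100(self):
        rng = np.random.default_rng(1)
        rep = metrics_report(rng.integers(0, 5, 200), rng.integers(0, 5, 200))
        np.testing.assert_allclose(rep.confusion_percent.sum(axis=1), 100.0, atol=1e-6)

    def test_macro_f1_invariant_under_relabeling(self):
        rng = np.random.default_rng(2)
        y_true = rng.integers(0, 5, 400)
        y_pred = rng.integers(0, 5, 400)
        base = metrics_report(y_true, y_pred).macro["f1"]
        perm = np.array([3, 0, 4, 1, 2])
        permuted = metrics_report(perm[y_true], perm[y_pred]).macro["f1"]
        assert permuted == pytest.approx(base)


class TestSummaryStats:
    def _values(self, mean, sd, n=5):
        pattern = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        pattern = pattern / pattern.std(ddof=1)
        return mean + sd * pattern

    def test_published_macro_f1_interval(self):
        s = summarize_folds(self._values(99.59, 0.28))
        assert (round(s.ci_lower, 2), round(s.ci_upper, 2)) == (99.24, 99.94)

    def test_published_precision_interval(self):
        s = summarize_folds(self._values(99.33, 0.42))
        assert (round(s.ci_lower, 2), round(s.ci_upper, 2)) == (98.81, 99.85)

    def test_zero_sd_collapses_interval(self):
        s = summarize_folds([7.5] * 5)
        assert s.ci_lower == s.ci_upper == s.mean == 7.5

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            summarize_folds([1.0])

    @given(st.lists(st.floats(min_value=0, max_value=100), min_size=2, max_size=10))
    def test_interval_brackets_mean(self, vals):
        s = summarize_folds(vals)
        assert s.ci_lower <= s.mean <= s.ci_upper


class TestTrainingLoop:
    def _small_net(self, seed=0):
        spec = ArchitectureSpec(stage_widths=(8, 16, 24), kernel_sizes=(3, 3, 3),
                                head_width=16, dropout=0.0, n_classes=3)
        return Network(spec, seed=seed)

    def test_history_and_lr_schedule(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((48, 20, 14))
        y = rng.integers(0, 3, 48)
        cfg = TrainConfig(learning_rate=1e-3, lr_patience=1, lr_floor=3e-4,
                          max_epochs=12, early_stop_patience=12, seed=0)
        hist = fit_network(self._small_net(), X, y, cfg,
                           validation=(X[:16], y[:16]))
        assert set(hist) >= {"loss", "accuracy", "lr", "val_loss", "val_accuracy"}
        lrs = np.array(hist["lr"])
        assert lrs[0] == 1e-3
        assert np.all(np.diff(lrs) <= 0)  # never increases
        assert np.all(lrs >= 3e-4 - 1e-12)  # floor respected
        # any reduction is by the configured factor
        for a, b in zip(lrs[:-1], lrs[1:]):
            assert b == a or b == pytest.approx(max(a * 0.5, 3e-4))

    def test_hyperparameter_validation(self):
        with pytest.raises(ConfigurationError):
            TrainConfig(learning_rate=-1.0)
        with pytest.raises(ConfigurationError):
            TrainConfig(learning_rate=1e-7, lr_floor=1e-6)

    def test_leakage_guard(self, tiny_cohort):
        segs = []
        for rec in tiny_cohort.recordings[:4]:
            segs.extend(ic.segment_events(ic.preprocess(rec)))
        with pytest.raises(LeakageError):
            train(self._small_net(), segs, segs)

    def test_early_stopping_restores_best_weights(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((64, 20, 14)) + rng.integers(0, 3, 64)[:, None, None]
        y = ((X.mean(axis=(1, 2)) > 1.0)).astype(int)
        net = self._small_net(seed=1)
        cfg = TrainConfig(learning_rate=1e-3, max_epochs=10, early_stop_patience=2, seed=1)
        hist = fit_network(net, X, y, cfg, validation=(X, y))
        best = max(hist["val_accuracy"])
        logits = net.forward(X, training=False)
        final = float((logits.argmax(axis=1) == y).mean())
        assert final == pytest.approx(best, abs=1e-9)
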