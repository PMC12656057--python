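"""Class-weighted training, patient-level stratified cross-validation and metrics.

The validation strategy keeps every patient's segments inside a single
fold (no subject appears in both training and validation), while a
greedy assignment balances rare seizure types across folds: patients
are processed in ascending order of their rarest label's global segment
count and each goes to the fold currently poorest in that class.

Metrics are one-vs-rest per class — sensitivity TP/(TP+FN), specificity
TN/(TN+FP), precision TP/(TP+FP), F1 the harmonic mean — reported as
percentages with unweighted macro averages, plus a row-normalized
confusion matrix.  Cross-fold summaries carry a t-based 95% CI
(mean ± t_{0.975,n-1} · SD/√n; 2.776 for five folds).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .errors import ConfigurationError, LeakageError
from .features import FeatureExtractor, labels_of, patients_of
from .nn.losses import softmax, weighted_cross_entropy
from .nn.optim import Adam
from .recording import Segment
from .seizures import CLASS_LABELS, N_CLASSES, SeizureClass


@dataclass
class TrainConfig:
    """Optimizer and schedule hyperparameters.

    Defaults follow the published configuration: Adam (lr 1e-4,
    beta1 0.9, beta2 0.999), reduce-on-plateau (factor 0.5, patience 3,
    floor 1e-6) on validation loss, early stopping (patience 5, best
    weights restored) on validation accuracy, at most 15 epochs of
    batch-32 training.
    """

    learning_rate: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    lr_factor: float = 0.5
    lr_patience: int = 3
    lr_floor: float = 1e-6
    early_stop_patience: int = 5
    max_epochs: int = 15
    batch_size: int = 32
    seed: int = 0
    plateau_monitor: str = "val_loss"
    early_stop_monitor: str = "val_accuracy"

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.lr_factor, self.lr_floor,
               self.max_epochs, self.batch_size) <= 0:
            raise ConfigurationError("all hyperparameters must be positive")
        if self.lr_floor > self.learning_rate:
            raise ConfigurationError("lr floor must not exceed the initial rate")


@dataclass(frozen=True)
class ClassWeights:
    """Per-class loss weights w_c = N / (K * N_c)."""

    weights: np.ndarray

    def __getitem__(self, c) -> float:
        return float(self.weights[int(c)])


def class_weights(labels: np.ndarray, n_classes: int = N_CLASSES) -> ClassWeights:
    """Inverse-frequency class weights, w_c = N / (K * N_c).

    K is the number of classes in the task; a class with zero samples
    cannot be weighted and raises.
    """
    labels = np.asarray(labels, dtype=int)
    counts = np.bincount(labels, minlength=n_classes)
    if (counts == 0).any():
        missing = [CLASS_LABELS[i] if n_classes == N_CLASSES else str(i)
                   for i in np.flatnonzero(counts == 0)]
        raise ConfigurationError(f"cannot weight classes with zero samples: {missing}")
    n = labels.size
    return ClassWeights(n / (n_classes * counts.astype(float)))


# ----------------------------------------------------------------------
# fold assignment
# ----------------------------------------------------------------------

@dataclass
class FoldAssignment:
    """Patient -> fold index map for k folds."""

    mapping: dict[str, int]
    k: int

    def fold_of(self, patient: str) -> int:
        return self.mapping[patient]

    def patients_in(self, fold: int) -> list[str]:
        return [p for p, f in self.mapping.items() if f == fold]


def assign_folds(patient_label_table: pd.DataFrame, k: int = 5, seed: int = 0) -> FoldAssignment:
    """Greedy patient-exclusive stratified fold assignment.

    ``patient_label_table`` has one row per segment with columns
    ``patient_id`` and ``label``.  Patients are processed in ascending
    order of their rarest label's global segment count and assigned to
    the fold with the fewest segments of that class (ties: fewest total
    segments, then lowest fold index).  Warns when a class is
    contributed by fewer than k patients (it then cannot reach every fold).
    """
    tab = patient_label_table
    if not {"patient_id", "label"}.issubset(tab.columns):
        raise ValueError("table needs columns 'patient_id' and 'label'")
    labels = np.array([int(SeizureClass.from_label(l)) for l in tab["label"]])
    patients_col = tab["patient_id"].astype(str).to_numpy()
    unique_patients = list(dict.fromkeys(patients_col))
    if k < 1 or k > len(unique_patients):
        raise ValueError(f"k={k} exceeds the number of patients ({len(unique_patients)})")

    global_counts = np.bincount(labels, minlength=N_CLASSES).astype(float)
    global_counts[global_counts == 0] = np.inf  # absent classes never 'rarest'

    per_patient: dict[str, np.ndarray] = {}
    for p in unique_patients:
        per_patient[p] = np.bincount(labels[patients_col == p], minlength=N_CLASSES)

    for c in range(N_CLASSES):
        contributors = sum(1 for p in unique_patients if per_patient[p][c] > 0)
        if 0 < contributors < k:
            warnings.warn(
                f"class {CLASS_LABELS[c]} is contributed by only {contributors} "
                f"patient(s); it will be absent from some of the {k} folds",
                stacklevel=2,
            )

    rng = np.random.default_rng(seed)
    order = list(unique_patients)
    rng.shuffle(order)

    def rarest_class(p: str) -> int:
        present = np.flatnonzero(per_patient[p] > 0)
        return int(present[np.argmin(global_counts[present])])

    order.sort(key=lambda p: global_counts[rarest_class(p)])  # stable

    fold_class = np.zeros((k, N_CLASSES), dtype=int)
    fold_total = np.zeros(k, dtype=int)
    mapping: dict[str, int] = {}
    for p in order:
        rc = rarest_class(p)
        best = min(range(k), key=lambda f: (fold_class[f, rc], fold_total[f], f))
        mapping[p] = best
        fold_class[best] += per_patient[p]
        fold_total[best] += per_patient[p].sum()
    return FoldAssignment(mapping=mapping, k=k)


# ----------------------------------------------------------------------
# training loop
# ----------------------------------------------------------------------

def fit_network(network, X: np.ndarray, y: np.ndarray, config: TrainConfig,
                *, validation: "tuple[np.ndarray, np.ndarray] | None" = None,
                class_weight: "np.ndarray | None" = None) -> dict:
    """Mini-batch Adam training with plateau schedule and early stopping.

    Returns a history dict with per-epoch ``loss``, ``accuracy``,
    ``lr`` and, when validation data is given, ``val_loss`` and
    ``val_accuracy``.  The plateau schedule halves the learning rate
    (never below the floor) when validation loss stops improving; early
    stopping watches validation accuracy and restores the best weights.
    """
    rng = np.random.default_rng(config.seed)
    opt = Adam(network.trainable_layers(), lr=config.learning_rate,
               beta1=config.beta1, beta2=config.beta2)
    sample_w = None if class_weight is None else np.asarray(class_weight, dtype=float)

    history: dict[str, list] = {"loss": [], "accuracy": [], "lr": []}
    if validation is not None:
        history["val_loss"] = []
        history["val_accuracy"] = []

    best_acc, best_weights, es_wait = -np.inf, None, 0
    best_plateau, lr_wait = np.inf, 0
    n = len(X)
    for epoch in range(config.max_epochs):
        idx = rng.permutation(n)
        ep_loss, ep_correct = 0.0, 0
        for start in range(0, n, config.batch_size):
            b = idx[start : start + config.batch_size]
            logits = network.forward(X[b], training=True)
            w = sample_w[y[b]] if sample_w is not None else None
            loss, dlogits = weighted_cross_entropy(logits, y[b], w)
            network.backward(dlogits)
            opt.step()
            ep_loss += loss * len(b)
            ep_correct += int((logits.argmax(axis=1) == y[b]).sum())
        history["loss"].append(ep_loss / n)
        history["accuracy"].append(ep_correct / n)
        history["lr"].append(opt.lr)

        if validation is None:
            continue
        Xv, yv = validation
        logits_v = network.forward(Xv, training=False)
        val_loss, _ = weighted_cross_entropy(logits_v, yv)
        val_acc = float((logits_v.argmax(axis=1) == yv).mean())
        history["val_loss"].append(val_loss)
        history["val_accuracy"].append(val_acc)

        # early stopping on validation accuracy, best-weights restore
        if val_acc > best_acc + 1e-12:
            best_acc, best_weights, es_wait = val_acc, network.get_weights(), 0
        else:
            es_wait += 1
            if es_wait >= config.early_stop_patience:
                break
        # plateau schedule on validation loss
        monitored = val_loss if config.plateau_monitor == "val_loss" else -val_acc
        if monitored < best_plateau - 1e-12:
            best_plateau, lr_wait = monitored, 0
        else:
            lr_wait += 1
            if lr_wait >= config.lr_patience:
                opt.lr = max(opt.lr * config.lr_factor, config.lr_floor)
                lr_wait = 0

    if best_weights is not None:
        network.set_weights(best_weights)
    return history


def _check_patient_disjoint(train_segments, val_segments) -> None:
    overlap = set(s.patient_id for s in train_segments) & set(
        s.patient_id for s in val_segments
    )
    if overlap:
        raise LeakageError(f"patients present in both train and validation: {sorted(overlap)}")


def train(network, train_segments: list[Segment], val_segments: list[Segment],
          config: TrainConfig | None = None,
          class_weight: "np.ndarray | None" = None) -> dict:
    """Segment-level training entry point with a leakage guard.

    Extracts 280-feature vectors, asserts that no patient appears on
    both sides, applies inverse-frequency class weighting (unless given
    explicitly) and runs :func:`fit_network`.
    """
    config = config or TrainConfig()
    _check_patient_disjoint(train_segments, val_segments)
    fx = FeatureExtractor()
    X, y = fx.transform(train_segments), labels_of(train_segments)
    Xv, yv = fx.transform(val_segments), labels_of(val_segments)
    if class_weight is None:
        counts = np.bincount(y, minlength=N_CLASSES).astype(float)
        counts[counts == 0] = np.inf  # absent classes get weight 0 (never sampled)
        class_weight = y.size / (N_CLASSES * counts)
    return fit_network(network, X, y, config, validation=(Xv, yv),
                       class_weight=class_weight)


# ----------------------------------------------------------------------
# metrics
# ----------------------------------------------------------------------

@dataclass
class MetricsReport:
    """One-vs-rest per-class metrics (percent), macro aggregates and
    a row-normalized confusion matrix."""

    classes: list[str]
    per_class: dict[str, dict[str, float]]
    accuracy: float
    macro: dict[str, float]
    confusion_percent: np.ndarray  # rows: truth (percent, rows sum to 100)
    confusion_counts: np.ndarray
    support: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_class).T


def metrics_report(y_true: np.ndarray, y_pred: np.ndarray,
                   class_names: "list[str] | None" = None) -> MetricsReport:
    """Compute the full metric battery from labels.

    Classes absent from the truth get NaN per-class metrics and are
    excluded from the macro averages (with a warning).
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    names = class_names or list(CLASS_LABELS)
    k = len(names)
    cm = np.zeros((k, k), dtype=int)
    np.add.at(cm, (y_true, y_pred), 1)
    total = cm.sum()

    per_class: dict[str, dict[str, float]] = {}
    support: dict[str, int] = {}
    for i, name in enumerate(names):
        tp = cm[i, i]
        fn = cm[i].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = total - tp - fn - fp
        support[name] = int(cm[i].sum())
        if support[name] == 0:
            per_class[name] = {m: float("nan") for m in
                               ("sensitivity", "specificity", "precision", "f1")}
            continue
        sens = tp / (tp + fn)
        spec = tn / (tn + fp) if (tn + fp) else 0.0
        prec = tp / (tp + fp) if (tp + fp) else 0.0
        f1 = 2 * prec * sens / (prec + sens) if (prec + sens) else 0.0
        per_class[name] = {
            "sensitivity": 100 * sens,
            "specificity": 100 * spec,
            "precision": 100 * prec,
            "f1": 100 * f1,
        }

    absent = [n for n in names if support[n] == 0]
    if absent:
        warnings.warn(
            f"classes absent from the truth excluded from macro averages: {absent}",
            stacklevel=2,
        )
    present = [n for n in names if support[n] > 0]
    macro = {
        m: float(np.mean([per_class[n][m] for n in present]))
        for m in ("sensitivity", "specificity", "precision", "f1")
    }

    conf_pct = np.full((k, k), np.nan)
    row_sums = cm.sum(axis=1)
    nz = row_sums > 0
    conf_pct[nz] = 100.0 * cm[nz] / row_sums[nz, None]

    return MetricsReport(
        classes=names,
        per_class=per_class,
        accuracy=float(100.0 * np.trace(cm) / total) if total else float("nan"),
        macro=macro,
        confusion_percent=conf_pct,
        confusion_counts=cm,
        support=support,
    )


def evaluate(network, segments: list[Segment]) -> MetricsReport:
    """Predict on segments and compute the metric battery."""
    fx = FeatureExtractor()
    X = fx.transform(segments)
    y_true = labels_of(segments)
    if hasattr(network, "predict_proba"):
        proba = network.predict_proba(X)
    else:  # bare Network
        proba = softmax(network.forward(X, training=False))
    y_pred = proba.argmax(axis=1)
    if hasattr(network, "classes_"):
        y_pred = np.asarray(network.classes_)[y_pred]
    return metrics_report(y_true, y_pred)


# ----------------------------------------------------------------------
# fold summary statistics
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class SummaryStats:
    mean: float
    sd: float
    ci_lower: float
    ci_upper: float

    def __iter__(self):
        return iter((self.mean, self.sd, self.ci_lower, self.ci_upper))


def summarize_folds(per_fold_values, confidence: float = 0.95) -> SummaryStats:
    """Mean, sample SD and t-based CI across folds.

    CI = mean ± t_{(1+conf)/2, n-1} × SD/√n; with five folds the
    multiplier is t_{0.975,4} = 2.776.
    """
    vals = np.asarray(list(per_fold_values), dtype=float)
    n = vals.size
    if n < 2:
        raise ValueError("need at least two fold values")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    t = float(sstats.t.ppf(0.5 + confidence / 2.0, n - 1))
    half = t * sd / np.sqrt(n)
    return SummaryStats(mean=mean, sd=sd, ci_lower=mean - half, ci_upper=mean + half)


# ----------------------------------------------------------------------
# cross-validation pipeline
# ----------------------------------------------------------------------

def cross_validate(segments: list[Segment], k: int = 5,
                   config: TrainConfig | None = None,
                   balance_target: float = 0.2,
                   classifier_params: "dict | None" = None,
                   seed: int = 0):
    """Patient-stratified k-fold cross-validation of the full pipeline.

    Per fold: the training split is balanced by noise augmentation
    (minorities lifted to ``balance_target`` of the majority), features
    are extracted, a fresh classifier is trained with class weighting
    and evaluated on the untouched validation split.

    Returns ``(reports, assignment)``.
    """
    from .model import AttentionResidualClassifier
    from .windowing import augment_to_balance

    config = config or TrainConfig()
    fx = FeatureExtractor()
    table = pd.DataFrame(
        {"patient_id": patients_of(segments), "label": [s.label.name for s in segments]}
    )
    assignment = assign_folds(table, k=k, seed=seed)

    # features of real segments are fold-independent; compute once
    X_all = fx.transform(segments)
    y_all = labels_of(segments)
    folds = np.array([assignment.fold_of(s.patient_id) for s in segments])

    reports = []
    for f in range(k):
        val_mask = folds == f
        train_segs = [s for s, m in zip(segments, val_mask) if not m]
        val_segs = [s for s, m in zip(segments, val_mask) if m]
        _check_patient_disjoint(train_segs, val_segs)

        augmented = augment_to_balance(train_segs, balance_target, seed=seed * 1000 + f)
        extra = augmented[len(train_segs):]
        X_tr = np.vstack([X_all[~val_mask]] + ([fx.transform(extra)] if extra else []))
        y_tr = np.concatenate([y_all[~val_mask], labels_of(extra)])

        params = dict(
            learning_rate=config.learning_rate, max_epochs=config.max_epochs,
            batch_size=config.batch_size, lr_factor=config.lr_factor,
            lr_patience=config.lr_patience, lr_floor=config.lr_floor,
            early_stopping_patience=config.early_stop_patience,
            random_state=config.seed + f,
        )
        params.update(classifier_params or {})
        clf = AttentionResidualClassifier(**params)
        clf.fit(X_tr, y_tr, X_val=X_all[val_mask], y_val=y_all[val_mask])

        y_pred = clf.predict(X_all[val_mask])
        reports.append(metrics_report(y_all[val_mask], y_pred))
    return reports, assignment
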