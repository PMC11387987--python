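"""Feature screening, classifier benchmarking and noise robustness.

Screening uses the two-sided Mann-Whitney U test (exact for small untied
samples, tie-corrected normal approximation otherwise) and the rank-based
per-feature AUC.  Classifiers (SVM, random forest, AdaBoost stumps, bagged
trees, single-hidden-layer neural network) are standard scikit-learn
estimators behind a small hyperparameter contract; features are z-scored
with training-split statistics inside every cross-validation iteration.

Three small-sample cross-validation protocols are provided:

* leave-one-sample-out (LOSO): one pooled confusion matrix over all held-out
  predictions (per-iteration metrics are degenerate for single test samples);
* leave-one-fold-out (LOFO): train on a few subjects per class (default 4),
  test on the rest, repeat (default 50x) and average per-repeat metrics;
* stratified k-fold (default k=5) with per-fold metrics averaged.

Noise robustness trains on clean features and recomputes the held-out
subject's features from a Gaussian-noise-contaminated copy of its series,
with noise SD expressed as a percentage of the series' own SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    RandomForestClassifier,
)
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .mfc_core import (
    Cohort,
    DegenerateInputError,
    FeatureTable,
    LABELS,
    MFCSeries,
    ValidationError,
)

__all__ = [
    "POSITIVE_LABEL",
    "HYPERPARAMETER_GRIDS",
    "MetricSet",
    "ClassifierSpec",
    "EvalReport",
    "AUCResult",
    "mann_whitney_u",
    "single_feature_auc",
    "screen_features",
    "confusion_metrics",
    "cv_leave_one_sample_out",
    "cv_leave_one_fold_out",
    "cv_stratified_kfold",
    "add_noise",
    "noise_sweep",
]

#: The outcome treated as the positive class throughout.
POSITIVE_LABEL = "improved"

#: The hyperparameter grids the classifier contract admits.
HYPERPARAMETER_GRIDS: dict[str, dict[str, list]] = {
    "svm": {"kernel": ["linear", "rbf", "polynomial"], "C": [0.01, 0.1, 1, 10, 100]},
    "random_forest": {"min_leaf": [1, 5, 10], "n_trees": list(range(5, 101))},
    "bagged_trees": {"min_leaf": [1, 5, 10], "n_trees": list(range(5, 101))},
    "adaboost": {
        "learning_rate": [0.001, 0.01, 0.1],
        "n_learners": [15, 20, 25, 30],
    },
    "ann": {"hidden_nodes": [10, 20, 50], "learning_rate": [0.1, 0.01, 0.001]},
}

_DEFAULT_PARAMS: dict[str, dict] = {
    "svm": {"kernel": "linear", "C": 1},
    "random_forest": {"min_leaf": 1, "n_trees": 50},
    "bagged_trees": {"min_leaf": 1, "n_trees": 50},
    "adaboost": {"learning_rate": 0.1, "n_learners": 20},
    "ann": {"hidden_nodes": 10, "learning_rate": 0.01},
}


# ---------------------------------------------------------------------------
# screening statistics


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns ``(U, p)`` where ``U`` is the smaller of the two one-sided U
    statistics.  The p-value is computed by exact enumeration when the
    combined sample size is at most 20 and there are no ties, and by the
    tie-corrected normal approximation (with continuity correction)
    otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    u_a = float(res.statistic)
    u_b = a.size * b.size - u_a
    return min(u_a, u_b), float(res.pvalue)


@dataclass(frozen=True)
class AUCResult:
    """Orientation-normalized per-feature AUC."""

    auc: float  # max(raw, 1 - raw), always >= 0.5
    raw: float  # P(positive sample outranks negative), ties count 1/2
    flipped: bool  # True when the reported auc is 1 - raw


def single_feature_auc(
    values: Sequence[float],
    labels: Sequence[str],
    positive: str = POSITIVE_LABEL,
) -> AUCResult:
    """Rank-based AUC of one feature: P(positive outranks negative).

    Equivalent to ``U_pos / (n_pos * n_neg)`` with ties counted one half.
    The reported value is oriented to be >= 0.5, with the flip recorded.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=object)
    pos = values[labels == positive]
    neg = values[labels != positive]
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("both classes must be present")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u_pos = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    raw = float(u_pos / (pos.size * neg.size))
    flipped = raw < 0.5
    return AUCResult(max(raw, 1.0 - raw), raw, flipped)


def screen_features(
    table: FeatureTable, positive: str = POSITIVE_LABEL
):
    """Per-feature Mann-Whitney U, p-value and oriented AUC.

    Returns a DataFrame with one row per feature, sorted as given.
    """
    import pandas as pd

    labels = np.asarray(table.labels, dtype=object)
    rows = []
    for name in table.feature_names:
        x = table.column(name)
        u, p = mann_whitney_u(x[labels == positive], x[labels != positive])
        res = single_feature_auc(x, labels, positive)
        rows.append(
            {
                "feature": name,
                "U": u,
                "p_value": p,
                "auc": res.auc,
                "auc_raw": res.raw,
                "orientation_flipped": res.flipped,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# metrics


@dataclass
class MetricSet:
    """Accuracy, sensitivity, specificity and F1 in percent; AUC in [0, 1].

    Ratios with zero denominators are reported as 0 and flagged.  The
    confusion counts are kept for bookkeeping.
    """

    acc: float
    sens: float
    spec: float
    f1: float
    auc: float
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    flags: tuple[str, ...] = ()

    def rounded(self) -> dict[str, float]:
        """Metrics at the 2-decimal reporting convention."""
        return {
            "acc": round(self.acc, 2),
            "sens": round(self.sens, 2),
            "spec": round(self.spec, 2),
            "f1": round(self.f1, 2),
            "auc": round(self.auc, 4) if np.isfinite(self.auc) else float("nan"),
        }


def confusion_metrics(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    positive: str = POSITIVE_LABEL,
    auc: float = float("nan"),
) -> MetricSet:
    """Confusion-matrix metrics from binary label sequences.

    ``acc = 100 (TP+TN)/n``, ``sens = 100 TP/(TP+FN)``,
    ``spec = 100 TN/(TN+FP)``, ``f1 = 100 * 2TP/(2TP+FP+FN)``.
    """
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValidationError("label sequences differ in length")
    for lab in (*y_true, *y_pred):
        if lab not in LABELS:
            raise ValidationError(f"label {lab!r} not in {LABELS}")
    tp = sum(t == positive and p == positive for t, p in zip(y_true, y_pred))
    fn = sum(t == positive and p != positive for t, p in zip(y_true, y_pred))
    fp = sum(t != positive and p == positive for t, p in zip(y_true, y_pred))
    tn = sum(t != positive and p != positive for t, p in zip(y_true, y_pred))
    flags = []

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            flags.append(f"{name}_undefined")
            return 0.0
        return 100.0 * num / den

    return MetricSet(
        acc=ratio(tp + tn, tp + tn + fp + fn, "acc"),
        sens=ratio(tp, tp + fn, "sens"),
        spec=ratio(tn, tn + fp, "spec"),
        f1=ratio(2 * tp, 2 * tp + fp + fn, "f1"),
        auc=auc,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        flags=tuple(flags),
    )


def _average_metrics(per_iter: list[MetricSet]) -> MetricSet:
    """Arithmetic mean of per-iteration metrics (never pooled counts)."""
    aucs = np.array([m.auc for m in per_iter], dtype=float)
    return MetricSet(
        acc=float(np.mean([m.acc for m in per_iter])),
        sens=float(np.mean([m.sens for m in per_iter])),
        spec=float(np.mean([m.spec for m in per_iter])),
        f1=float(np.mean([m.f1 for m in per_iter])),
        auc=float(np.nanmean(aucs)) if np.any(np.isfinite(aucs)) else float("nan"),
        tp=sum(m.tp for m in per_iter),
        fp=sum(m.fp for m in per_iter),
        tn=sum(m.tn for m in per_iter),
        fn=sum(m.fn for m in per_iter),
        flags=tuple(sorted({f for m in per_iter for f in m.flags})),
    )


# ---------------------------------------------------------------------------
# classifiers


@dataclass
class ClassifierSpec:
    """A classifier kind with hyperparameters from the declared grids.

    ``kind`` is one of ``svm``, ``random_forest``, ``adaboost``,
    ``bagged_trees``, ``ann``.  Parameters outside the grids are allowed only
    as explicit overrides (a warning is emitted).  :meth:`build` returns a
    ready scikit-learn estimator; determinism is controlled by the
    ``random_state`` passed at build time.
    """

    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in HYPERPARAMETER_GRIDS:
            raise ValidationError(
                f"unknown classifier kind {self.kind!r}; "
                f"choose from {sorted(HYPERPARAMETER_GRIDS)}"
            )
        merged = {**_DEFAULT_PARAMS[self.kind], **self.params}
        grid = HYPERPARAMETER_GRIDS[self.kind]
        for key, value in merged.items():
            if key in grid and value not in grid[key]:
                warnings.warn(
                    f"{self.kind}: {key}={value!r} is outside the declared grid",
                    stacklevel=2,
                )
        self.params = merged

    def describe(self) -> str:
        inner = ",".join(f"{k}={v}" for k, v in sorted(self.params.items()))
        return f"{self.kind}({inner})"

    def build(self, random_state: int | None = None):
        p = self.params
        if self.kind == "svm":
            kernel = {"polynomial": "poly"}.get(p["kernel"], p["kernel"])
            return SVC(kernel=kernel, C=p["C"], degree=3, random_state=random_state)
        if self.kind == "random_forest":
            return RandomForestClassifier(
                n_estimators=p["n_trees"],
                min_samples_leaf=p["min_leaf"],
                random_state=random_state,
            )
        if self.kind == "bagged_trees":
            return BaggingClassifier(
                estimator=DecisionTreeClassifier(min_samples_leaf=p["min_leaf"]),
                n_estimators=p["n_trees"],
                random_state=random_state,
            )
        if self.kind == "adaboost":
            return AdaBoostClassifier(
                estimator=DecisionTreeClassifier(max_depth=1),
                n_estimators=p["n_learners"],
                learning_rate=p["learning_rate"],
                random_state=random_state,
            )
        if self.kind == "ann":
            return MLPClassifier(
                hidden_layer_sizes=(p["hidden_nodes"],),
                learning_rate_init=p["learning_rate"],
                max_iter=1000,
                alpha=0.01,
                random_state=random_state,
            )
        raise AssertionError(self.kind)


def _standardize(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Z-score with training-split statistics only."""
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    return (train - mu) / sd, (test - mu) / sd


def _decision_scores(clf, X: np.ndarray) -> np.ndarray:
    if hasattr(clf, "decision_function"):
        return np.asarray(clf.decision_function(X), dtype=float)
    proba = clf.predict_proba(X)
    pos_col = list(clf.classes_).index(1)
    return np.asarray(proba[:, pos_col], dtype=float)


def _encode(labels: Sequence[str], positive: str) -> np.ndarray:
    return np.array([1 if l == positive else 0 for l in labels], dtype=int)


def _fit_eval(
    spec: ClassifierSpec,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    random_state: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit with z-scored features; return (predictions, decision scores)."""
    Xtr, Xte = _standardize(X_train, X_test)
    clf = spec.build(random_state=random_state)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MLP convergence chatter on tiny splits
        clf.fit(Xtr, y_train)
    return clf.predict(Xte), _decision_scores(clf, Xte)


@dataclass
class EvalReport:
    """Aggregated evaluation result for one (classifier, CV scheme) pair."""

    classifier: str
    cv_scheme: str
    feature_family: str
    metrics: MetricSet
    n_repeats: int
    seed: int
    per_iteration: list = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {
            "classifier": self.classifier,
            "cv_scheme": self.cv_scheme,
            "feature_family": self.feature_family,
            "noise_percent": self.extra.get("noise_percent", 0.0),
            **self.metrics.rounded(),
            "n_repeats": self.n_repeats,
            "seed": self.seed,
        }
        return row


def _check_two_classes(table: FeatureTable, min_per_class: int = 2) -> None:
    counts: dict[str, int] = {}
    for l in table.labels:
        if l is None:
            raise ValidationError("all subjects must be labelled for evaluation")
        counts[l] = counts.get(l, 0) + 1
    if len(counts) != 2:
        raise ValidationError(f"need exactly 2 classes, got {sorted(counts)}")
    for c, n in counts.items():
        if n < min_per_class:
            raise ValidationError(f"class {c!r} has {n} < {min_per_class} subjects")


def _loso(
    table: FeatureTable,
    spec: ClassifierSpec,
    seed: int,
    positive: str,
    feature_family: str,
    test_row_fn: Callable[[int], np.ndarray] | None = None,
) -> EvalReport:
    """Shared leave-one-sample-out engine.

    ``test_row_fn(i)`` may supply an alternative feature row for held-out
    subject ``i`` (used by the noise sweep); training always uses the clean
    table.
    """
    _check_two_classes(table)
    X = table.matrix
    y = _encode(table.labels, positive)
    n = X.shape[0]
    preds = np.empty(n, dtype=int)
    scores = np.empty(n, dtype=float)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if len(set(y[mask])) < 2:
            warnings.warn(f"training split without subject {i} lost a class")
        row = X[i] if test_row_fn is None else test_row_fn(i)
        pred, score = _fit_eval(spec, X[mask], y[mask], row[None, :], seed)
        preds[i], scores[i] = pred[0], score[0]
    to_label = lambda v: positive if v == 1 else next(
        l for l in set(table.labels) if l != positive
    )
    pooled_auc = float(roc_auc_score(y, scores))
    metrics = confusion_metrics(
        list(table.labels), [to_label(p) for p in preds], positive, auc=pooled_auc
    )
    per_iter = [
        {
            "subject_id": table.subject_ids[i],
            "true": table.labels[i],
            "pred": to_label(preds[i]),
            "score": float(scores[i]),
        }
        for i in range(n)
    ]
    return EvalReport(
        classifier=spec.describe(),
        cv_scheme="loso",
        feature_family=feature_family,
        metrics=metrics,
        n_repeats=n,
        seed=seed,
        per_iteration=per_iter,
    )


def cv_leave_one_sample_out(
    table: FeatureTable,
    spec: ClassifierSpec,
    seed: int = 0,
    positive: str = POSITIVE_LABEL,
    feature_family: str = "spectral",
) -> EvalReport:
    """Leave-one-sample-out cross-validation.

    Every subject is held out once; metrics come from the single pooled
    confusion matrix over all held-out predictions, and the AUC is pooled
    over the held-out decision scores.
    """
    return _loso(table, spec, seed, positive, feature_family)


def cv_leave_one_fold_out(
    table: FeatureTable,
    spec: ClassifierSpec,
    n_per_class: int = 4,
    n_repeats: int = 50,
    seed: int = 0,
    positive: str = POSITIVE_LABEL,
    feature_family: str = "spectral",
) -> EvalReport:
    """Train on ``n_per_class`` random subjects per class, test on the rest.

    The random draw is repeated ``n_repeats`` times; per-repeat metrics
    (including the per-repeat decision-score AUC) are averaged.
    """
    _check_two_classes(table, min_per_class=n_per_class + 1)
    X = table.matrix
    y = _encode(table.labels, positive)
    labels = np.asarray(table.labels, dtype=object)
    classes = sorted(set(table.labels))
    rng = np.random.default_rng(seed)
    per_iter: list[MetricSet] = []
    for rep in range(n_repeats):
        train_idx: list[int] = []
        for c in classes:
            members = np.flatnonzero(labels == c)
            train_idx.extend(rng.choice(members, size=n_per_class, replace=False))
        train_mask = np.zeros(len(y), dtype=bool)
        train_mask[train_idx] = True
        preds, scores = _fit_eval(
            spec, X[train_mask], y[train_mask], X[~train_mask], seed + rep
        )
        y_test = y[~train_mask]
        neg = next(c for c in classes if c != positive)
        to_label = lambda v: positive if v == 1 else neg
        auc = (
            float(roc_auc_score(y_test, scores))
            if len(set(y_test)) == 2
            else float("nan")
        )
        per_iter.append(
            confusion_metrics(
                [to_label(v) for v in y_test],
                [to_label(v) for v in preds],
                positive,
                auc=auc,
            )
        )
    return EvalReport(
        classifier=spec.describe(),
        cv_scheme="lofo",
        feature_family=feature_family,
        metrics=_average_metrics(per_iter),
        n_repeats=n_repeats,
        seed=seed,
        per_iteration=per_iter,
    )


def cv_stratified_kfold(
    table: FeatureTable,
    spec: ClassifierSpec,
    k: int = 5,
    seed: int = 0,
    positive: str = POSITIVE_LABEL,
    feature_family: str = "spectral",
) -> EvalReport:
    """Stratified k-fold cross-validation with per-fold metrics averaged."""
    _check_two_classes(table)
    X = table.matrix
    y = _encode(table.labels, positive)
    counts = np.bincount(y)
    k_eff = k
    if k > counts.min():
        warnings.warn(
            f"k={k} exceeds the minority class size {counts.min()}; "
            f"using k={counts.min()} so every fold keeps a minority sample"
        )
        k_eff = int(counts.min())
    classes = sorted(set(table.labels))
    neg = next(c for c in classes if c != positive)
    to_label = lambda v: positive if v == 1 else neg
    skf = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed)
    per_iter: list[MetricSet] = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(X, y)):
        preds, scores = _fit_eval(spec, X[train_idx], y[train_idx], X[test_idx], seed + fold)
        y_test = y[test_idx]
        auc = (
            float(roc_auc_score(y_test, scores))
            if len(set(y_test)) == 2
            else float("nan")
        )
        per_iter.append(
            confusion_metrics(
                [to_label(v) for v in y_test],
                [to_label(v) for v in preds],
                positive,
                auc=auc,
            )
        )
    return EvalReport(
        classifier=spec.describe(),
        cv_scheme=f"stratified{k_eff}",
        feature_family=feature_family,
        metrics=_average_metrics(per_iter),
        n_repeats=k_eff,
        seed=seed,
        per_iteration=per_iter,
    )


# ---------------------------------------------------------------------------
# noise robustness


def add_noise(
    s: MFCSeries,
    percent: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> MFCSeries:
    """Add white Gaussian noise with SD = ``percent``/100 of the series SD.

    ``percent = 0`` returns an identical copy.  Noisy values may leave the
    unit interval slightly; the copy keeps the ``normalized`` flag but skips
    the range invariant.
    """
    if percent < 0:
        raise ValidationError("noise percent must be >= 0")
    if not s.normalized:
        raise ValidationError("noise is defined on normalized series")
    if percent == 0:
        return s.replace()
    if rng is None:
        rng = np.random.default_rng(seed)
    sd = (percent / 100.0) * float(np.std(s.values, ddof=1))
    noisy = s.values + rng.normal(0.0, sd, size=s.n)
    return MFCSeries(
        s.subject_id,
        noisy,
        label=s.label,
        normalized=True,
        meta={**s.meta, "noise_percent": percent},
        check_range=False,
    )


def noise_sweep(
    cohort: Cohort,
    extractor: Callable[[MFCSeries], Mapping[str, float]],
    spec: ClassifierSpec,
    levels: Sequence[float] = (0, 10, 20, 30),
    seed: int = 0,
    positive: str = POSITIVE_LABEL,
    feature_family: str = "spectral",
) -> list[EvalReport]:
    """Leave-one-sample-out robustness sweep over noise levels.

    The model is trained on clean features; each held-out subject's feature
    row is recomputed from a noise-contaminated copy of its series.  Level 0
    reproduces the clean LOSO report exactly.
    """
    records = [(s.subject_id, s.label, dict(extractor(s))) for s in cohort]
    table = FeatureTable.from_records(records)
    names = table.feature_names
    reports = []
    for li, level in enumerate(levels):
        level_rng = np.random.default_rng(
            np.random.SeedSequence([seed, li]).generate_state(1)[0]
        )

        def test_row(i: int) -> np.ndarray:
            noisy = add_noise(cohort.series[i], level, rng=level_rng)
            feats = extractor(noisy)
            return np.array([feats[k] for k in names], dtype=float)

        rep = _loso(table, spec, seed, positive, feature_family, test_row_fn=test_row)
        rep.extra["noise_percent"] = float(level)
        reports.append(rep)
    return reports
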