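"""Classifier bench and evaluation statistics.

Seven standard classifiers (random forest, logistic regression, SVM, KNN,
decision tree, gradient boosting, XGBoost) are trained on the per-record
feature table; evaluation covers weighted classification metrics, per-class
accuracy, reconstruction error metrics (MAE/MSE/RMSE/NRMSE), bootstrap
accuracy variability, and paired McNemar tests between reconstruction arms.
The classifiers themselves are the off-the-shelf scikit-learn / XGBoost
implementations; everything statistical around them is computed here.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .errors import InvalidArgumentError, NoDiscordanceError, UndefinedMetricError
from .features import FEATURE_COLUMNS

__all__ = [
    "CLASSIFIER_KINDS", "ClassifierSpec", "EvalReport", "cross_entropy",
    "train_classifier", "classification_metrics", "reconstruction_metrics",
    "bootstrap_accuracy", "mcnemar_test", "holm_adjust", "run_comparison",
]

CLASSIFIER_KINDS = (
    "random_forest", "logistic_regression", "support_vector_machine",
    "k_nearest_neighbors", "decision_tree", "gradient_boosting",
    "extreme_gradient_boosting",
)

FEATURE_INPUT_COLUMNS = [c for c in FEATURE_COLUMNS
                         if c not in ("patient_id", "label")]


@dataclass
class ClassifierSpec:
    kind: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.kind not in CLASSIFIER_KINDS:
            raise InvalidArgumentError(
                f"unknown classifier kind {self.kind!r}; expected one of "
                f"{CLASSIFIER_KINDS}")


class _FittedClassifier:
    """Uniform predict / predict_proba facade over the fitted estimator."""

    def __init__(self, estimator, classes: np.ndarray):
        self.estimator = estimator
        self.classes = classes

    def predict(self, x: np.ndarray | pd.DataFrame) -> np.ndarray:
        x = _as_matrix(x)
        return self.classes[self.estimator.predict(x).astype(int)] \
            if self.estimator.__class__.__module__.startswith("xgboost") \
            else self.estimator.predict(x)

    def predict_proba(self, x: np.ndarray | pd.DataFrame) -> np.ndarray:
        return self.estimator.predict_proba(_as_matrix(x))


def _as_matrix(x) -> np.ndarray:
    if isinstance(x, pd.DataFrame):
        cols = [c for c in FEATURE_INPUT_COLUMNS if c in x.columns]
        x = x[cols].to_numpy(dtype=float)
    return np.asarray(x, dtype=float)


def cross_entropy(y_true_onehot: np.ndarray, y_prob: np.ndarray) -> float:
    """L = -sum_i sum_c y_ic ln p_ic, with probabilities clipped at 1e-12."""
    y = np.asarray(y_true_onehot, dtype=float)
    p = np.asarray(y_prob, dtype=float)
    if y.shape != p.shape:
        raise InvalidArgumentError("one-hot labels and probabilities must match")
    p = np.clip(p, 1e-12, 1.0)
    return float(-(y * np.log(p)).sum())


def train_classifier(spec: ClassifierSpec, features, labels) -> _FittedClassifier:
    """Fit one of the seven bench classifiers on the feature table."""
    x = _as_matrix(features)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise InvalidArgumentError("training data must contain at least two classes")
    hp = dict(spec.hyperparameters)
    kind = spec.kind
    # distance/margin-based models get feature standardization; tree
    # ensembles are scale-invariant and take the features as-is
    scaled = None
    if kind == "random_forest":
        from sklearn.ensemble import RandomForestClassifier
        est = RandomForestClassifier(random_state=spec.seed, **hp)
    elif kind == "logistic_regression":
        from sklearn.linear_model import LogisticRegression
        hp.setdefault("max_iter", 2000)
        est = LogisticRegression(random_state=spec.seed, **hp)
        scaled = True
    elif kind == "support_vector_machine":
        from sklearn.svm import SVC
        hp.setdefault("probability", True)
        est = SVC(random_state=spec.seed, **hp)
        scaled = True
    elif kind == "k_nearest_neighbors":
        from sklearn.neighbors import KNeighborsClassifier
        est = KNeighborsClassifier(**hp)
        scaled = True
    elif kind == "decision_tree":
        from sklearn.tree import DecisionTreeClassifier
        est = DecisionTreeClassifier(random_state=spec.seed, **hp)
    elif kind == "gradient_boosting":
        from sklearn.ensemble import GradientBoostingClassifier
        est = GradientBoostingClassifier(random_state=spec.seed, **hp)
    else:  # extreme_gradient_boosting
        from xgboost import XGBClassifier
        hp.setdefault("n_estimators", 100)
        est = XGBClassifier(random_state=spec.seed, verbosity=0, **hp)

    if scaled:
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler
        est = make_pipeline(StandardScaler(), est)

    classes, y_enc = np.unique(y, return_inverse=True)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        if kind == "extreme_gradient_boosting":
            est.fit(x, y_enc)
        else:
            est.fit(x, y)
    return _FittedClassifier(est, classes)


def classification_metrics(y_true, y_pred) -> dict:
    """Accuracy, support-weighted precision/recall/F1, per-class accuracy.

    Per-class accuracy is the per-class recall (diagonal of the
    row-normalized confusion matrix).
    """
    from sklearn.metrics import precision_recall_fscore_support, confusion_matrix
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) == 0 or len(y_true) != len(y_pred):
        raise InvalidArgumentError("inputs must be non-empty and equal length")
    classes = np.unique(np.concatenate([y_true, y_pred]))
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, average="weighted", zero_division=0)
    cm = confusion_matrix(y_true, y_pred, labels=classes).astype(float)
    row = cm.sum(axis=1)
    per_class = np.divide(np.diag(cm), row, out=np.full(len(classes), np.nan),
                          where=row > 0)
    return {
        "accuracy": float((y_true == y_pred).mean()),
        "precision": float(prec),
        "recall": float(rec),
        "f1": float(f1),
        "per_class_accuracy": dict(zip(classes.tolist(), per_class.tolist())),
    }


def reconstruction_metrics(x_true: np.ndarray, x_hat: np.ndarray,
                           mask: np.ndarray | None = None) -> dict:
    """MAE/MSE/RMSE and range-normalized RMSE over the selected entries."""
    x_true = np.asarray(x_true, dtype=float)
    x_hat = np.asarray(x_hat, dtype=float)
    if x_true.shape != x_hat.shape:
        raise InvalidArgumentError("true/reconstructed shape mismatch")
    if mask is not None:
        sel = np.asarray(mask, dtype=bool)
        if sel.shape != x_true.shape:
            raise InvalidArgumentError("mask shape mismatch")
        xt, xh = x_true[sel], x_hat[sel]
    else:
        xt, xh = x_true.ravel(), x_hat.ravel()
    if xt.size == 0:
        raise InvalidArgumentError("no entries selected")
    err = xh - xt
    mae = float(np.abs(err).mean())
    mse = float((err ** 2).mean())
    rmse = float(np.sqrt(mse))
    rng = float(xt.max() - xt.min())
    if rng == 0:
        raise UndefinedMetricError("NRMSE undefined: selected entries have zero range")
    return {"mae": mae, "mse": mse, "rmse": rmse, "nrmse": rmse / rng}


def bootstrap_accuracy(y_true, y_pred, n_iter: int = 1000,
                       seed: int = 0) -> tuple[float, float]:
    """Mean and sample SD of accuracy over resampled test sets."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) == 0 or len(y_true) != len(y_pred):
        raise InvalidArgumentError("inputs must be non-empty and equal length")
    if n_iter < 1:
        raise InvalidArgumentError("n_iter must be >= 1")
    correct = (y_true == y_pred).astype(float)
    n = len(correct)
    rng = np.random.Generator(np.random.MT19937(seed))
    idx = rng.integers(0, n, size=(n_iter, n))
    accs = correct[idx].mean(axis=1)
    sd = float(accs.std(ddof=1)) if n_iter > 1 else 0.0
    return float(accs.mean()), sd


def mcnemar_test(correct_a, correct_b) -> tuple[float, int, int]:
    """Paired McNemar test on per-case correctness of two classifiers.

    Returns (p_value, b, c) with b = cases A got right and B wrong,
    c = the reverse.  Exact two-sided binomial p for b + c < 25, otherwise
    the chi-square approximation with continuity correction.
    """
    a = np.asarray(correct_a, dtype=bool)
    b_arr = np.asarray(correct_b, dtype=bool)
    if a.shape != b_arr.shape:
        raise InvalidArgumentError("paired correctness vectors must match in length")
    b = int(np.sum(a & ~b_arr))
    c = int(np.sum(~a & b_arr))
    n = b + c
    if n == 0:
        raise NoDiscordanceError("no discordant pairs: McNemar test undefined")
    if n < 25:
        p = 2.0 * sp_stats.binom.cdf(min(b, c), n, 0.5)
        p = min(1.0, float(p))
    else:
        chi2 = (abs(b - c) - 1.0) ** 2 / n
        p = float(sp_stats.chi2.sf(chi2, df=1))
    return p, b, c


def holm_adjust(p_values: list[float]) -> list[float]:
    """Holm step-down adjustment, preserving input order."""
    m = len(p_values)
    order = np.argsort(p_values)
    adjusted = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p_values[i])
        adjusted[i] = min(1.0, running)
    return adjusted.tolist()


@dataclass
class EvalReport:
    """All evaluation outputs of a paired reconstruction comparison."""

    # accuracy[(arm, ratio, kind)] etc.
    metrics: dict = field(default_factory=dict)
    bootstrap: dict = field(default_factory=dict)
    per_class: dict = field(default_factory=dict)
    reconstruction: dict = field(default_factory=dict)
    mcnemar: dict = field(default_factory=dict)
    ratios: tuple = ()
    arms: tuple = ()
    classifier_kinds: tuple = ()

    def accuracy_table(self) -> pd.DataFrame:
        rows = []
        for kind in self.classifier_kinds:
            row = {"model": kind}
            for arm in self.arms:
                for ratio in self.ratios:
                    mean, sd = self.bootstrap[(arm, ratio, kind)]
                    row[f"{arm} ({int(ratio * 100)}%)"] = f"{mean:.3f} +/- {sd:.3f}"
            rows.append(row)
        return pd.DataFrame(rows)

    def mcnemar_table(self) -> pd.DataFrame:
        rows = []
        for (ratio, kind), (p, b, c, p_holm) in self.mcnemar.items():
            rows.append({"ratio": ratio, "model": kind, "p_value": p,
                         "b": b, "c": c, "p_holm": p_holm})
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        def key(k):
            return "|".join(str(p) for p in k) if isinstance(k, tuple) else str(k)
        return {
            "metrics": {key(k): v for k, v in self.metrics.items()},
            "bootstrap": {key(k): list(v) for k, v in self.bootstrap.items()},
            "reconstruction": {key(k): v for k, v in self.reconstruction.items()},
            "mcnemar": {key(k): list(v) for k, v in self.mcnemar.items()},
            "ratios": list(self.ratios),
            "arms": list(self.arms),
            "classifier_kinds": list(self.classifier_kinds),
        }


def run_comparison(reconstructors: dict, cohort: list, split,
                   missing_ratios: tuple[float, ...] = (0.10, 0.30, 0.50),
                   classifier_specs: list[ClassifierSpec] | None = None,
                   segment_len: int = 48, seed: int = 0,
                   n_bootstrap: int = 1000) -> EvalReport:
    """Mask test records, reconstruct per arm, classify, compare.

    ``reconstructors`` maps arm name -> callable(record_with_gaps, mask) ->
    reconstructed normalized ECGRecord.  ``cohort`` is a list of (normalized
    record, annotations, label); ``split`` a SplitAssignment.  Classifiers
    are trained once on the clean training-set features and applied to the
    features of every reconstruction; McNemar pairs the two arms per
    classifier and ratio.
    """
    from .features import pan_tompkins, delineate, build_feature_table
    from .wfdb_io import denormalize

    if classifier_specs is None:
        classifier_specs = [ClassifierSpec(kind=k, seed=seed)
                            for k in CLASSIFIER_KINDS]
    arms = tuple(reconstructors)

    def extract(records):
        feats, kept = [], []
        for rec in records:
            try:
                rec_mv = denormalize(rec) if rec.normalized else rec
                peaks = pan_tompkins(rec_mv.lead("II"), rec_mv.fs)
                if len(peaks) == 0:
                    continue
                ann = delineate(rec_mv, peaks)
            except InvalidArgumentError:
                continue
            feats.append((rec_mv, ann))
            kept.append(rec)
        if not feats:
            raise InvalidArgumentError("no record could be delineated")
        table = build_feature_table([f[0] for f in feats], [f[1] for f in feats])
        return table, kept

    train_recs = [r for r, _, _ in cohort
                  if split.assignment.get(r.patient_id) == "train"]
    test_recs = [r for r, _, _ in cohort
                 if split.assignment.get(r.patient_id) == "test"]
    if not train_recs or not test_recs:
        raise InvalidArgumentError("split leaves train or test empty")

    train_table, _ = extract(train_recs)
    classifiers = {spec.kind: train_classifier(
        spec, train_table, train_table["label"]) for spec in classifier_specs}

    from .synth import simulate_missing
    report = EvalReport(ratios=tuple(missing_ratios), arms=arms,
                        classifier_kinds=tuple(c.kind for c in classifier_specs))
    predictions: dict = {}
    for ratio in missing_ratios:
        masked_sets = {}
        recon_err = {arm: [] for arm in arms}
        for arm, reconstruct in reconstructors.items():
            recons = []
            for rec in test_recs:
                mask_seed = (seed + 7919 * int(round(1000 * ratio))
                             + zlib.crc32(rec.patient_id.encode()) % 100003)
                masked, mask = simulate_missing(
                    rec, ratio, "segments", segment_len, seed=mask_seed)
                recon = reconstruct(masked, mask)
                recons.append(recon)
                miss = mask.mask == 0
                if miss.any():
                    recon_err[arm].append(reconstruction_metrics(
                        rec.signal, recon.signal, miss))
            masked_sets[arm] = recons
        for arm in arms:
            errs = recon_err[arm]
            report.reconstruction[(arm, ratio)] = {
                k: float(np.mean([e[k] for e in errs])) for k in
                ("mae", "mse", "rmse", "nrmse")} if errs else {}

        for arm in arms:
            table, kept = extract(masked_sets[arm])
            y_true = np.array([r.label for r in kept])
            for kind, clf in classifiers.items():
                y_pred = clf.predict(table)
                m = classification_metrics(y_true, y_pred)
                report.metrics[(arm, ratio, kind)] = {
                    k: m[k] for k in ("accuracy", "precision", "recall", "f1")}
                report.per_class[(arm, ratio, kind)] = m["per_class_accuracy"]
                report.bootstrap[(arm, ratio, kind)] = bootstrap_accuracy(
                    y_true, y_pred, n_iter=n_bootstrap, seed=seed + 1)
                predictions[(arm, ratio, kind)] = (
                    [r.patient_id for r in kept], y_true == y_pred)

        if len(arms) == 2:
            a0, a1 = arms
            raw_ps, keys = [], []
            for kind in report.classifier_kinds:
                ids0, corr0 = predictions[(a0, ratio, kind)]
                ids1, corr1 = predictions[(a1, ratio, kind)]
                common = sorted(set(ids0) & set(ids1))
                c0 = dict(zip(ids0, corr0))
                c1 = dict(zip(ids1, corr1))
                va = np.array([c0[i] for i in common])
                vb = np.array([c1[i] for i in common])
                try:
                    p, b, c = mcnemar_test(va, vb)
                except NoDiscordanceError:
                    p, b, c = 1.0, 0, 0
                raw_ps.append(p)
                keys.append((ratio, kind))
            adj = holm_adjust(raw_ps)
            for (k, p, ph) in zip(keys, raw_ps, adj):
                kind = k[1]
                # recompute b, c for the record (cheap)
                ids0, corr0 = predictions[(a0, ratio, kind)]
                ids1, corr1 = predictions[(a1, ratio, kind)]
                common = sorted(set(ids0) & set(ids1))
                c0 = dict(zip(ids0, corr0))
                c1 = dict(zip(ids1, corr1))
                va = np.array([c0[i] for i in common])
                vb = np.array([c1[i] for i in common])
                b = int(np.sum(va & ~vb))
                c = int(np.sum(~va & vb))
                report.mcnemar[k] = (p, b, c, ph)
    return report
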