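"""Classification models, cross-validation, and the evaluation metric suite.

The central object is :class:`RepurposingClassifier`, a model built from a
labelled :class:`~kgrepurpose.features.FeatureMatrix` and a
:class:`ModelSpec`; ``fit()`` returns a :class:`RepurposingResults` that
carries the fitted estimator bound to its feature schema and exposes
prediction scores (pseudoprobability of the approved class, 0-100%),
normalized feature importances and a ``summary()`` table.
``cross_validate()`` runs repeated stratified K-fold CV and reports the
mean and standard deviation of five metrics (AUC, AUPRC, F1, accuracy,
Cohen's kappa) over all fold-level evaluations.

Module-level functions (``train``, ``predict_scores``, ``cross_validate``,
``compare_models``...) are thin wrappers over these objects.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from scipy import stats
from sklearn.base import clone
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    cohen_kappa_score,
    f1_score,
    roc_auc_score,
    roc_curve,
)
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from kgrepurpose.features import FeatureMatrix, FeatureSchema

POSITIVE_CLASS = "approved"
DEFAULT_CUTOFF = 50.0

#: Algorithms in the registry (the model-comparison row set).
ALGORITHMS: tuple[str, ...] = (
    "logistic_regression",
    "neural_network",
    "svm",
    "cart",
    "knn",
    "naive_bayes",
    "random_forest",
)

METRICS: tuple[str, ...] = ("auc", "auprc", "f1", "accuracy", "kappa")


@dataclass(frozen=True)
class ModelSpec:
    """An algorithm name, hyperparameter overrides, and a mandatory seed."""

    algorithm: str = "random_forest"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}")


def build_estimator(spec: ModelSpec):
    """Instantiate the scikit-learn estimator for a spec.

    Distance/gradient-based algorithms are wrapped in a standard-scaling
    pipeline; hyperparameter overrides apply to the final estimator step.
    Random-forest defaults: 500 trees, sqrt(p) features per split, no
    depth limit.
    """
    seed = spec.seed
    if spec.algorithm == "random_forest":
        est = RandomForestClassifier(
            n_estimators=500, max_features="sqrt", random_state=seed, n_jobs=1
        )
        scaled = False
    elif spec.algorithm == "logistic_regression":
        est, scaled = LogisticRegression(max_iter=2000, random_state=seed), True
    elif spec.algorithm == "neural_network":
        est, scaled = (
            MLPClassifier(hidden_layer_sizes=(100,), max_iter=300, random_state=seed),
            True,
        )
    elif spec.algorithm == "svm":
        # RBF SVM with probability calibration (SVMs are not probabilistic)
        est, scaled = (
            CalibratedClassifierCV(SVC(kernel="rbf", random_state=seed), ensemble=False),
            True,
        )
    elif spec.algorithm == "cart":
        est, scaled = DecisionTreeClassifier(random_state=seed), False
    elif spec.algorithm == "knn":
        est, scaled = KNeighborsClassifier(n_neighbors=5), True
    else:  # naive_bayes
        est, scaled = GaussianNB(), False
    if spec.hyperparameters:
        est.set_params(**spec.hyperparameters)
    if scaled:
        return Pipeline([("scale", StandardScaler()), ("model", est)])
    return est


def _final_estimator(fitted):
    return fitted.named_steps["model"] if isinstance(fitted, Pipeline) else fitted


# ---------------------------------------------------------------------------
# metrics


def _as_binary(labels) -> np.ndarray:
    return np.asarray([1 if l == POSITIVE_CLASS else 0 for l in labels])


def auc(scores, labels) -> float:
    """Probability that a random approved pair outranks a random terminated
    one, ties counting one half (the Mann-Whitney formulation)."""
    y = _as_binary(labels)
    if len(set(y)) < 2:
        raise ValueError("AUC requires both classes")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def auprc(scores, labels) -> float:
    """Area under the precision-recall curve (average precision)."""
    y = _as_binary(labels)
    if len(set(y)) < 2:
        raise ValueError("AUPRC requires both classes")
    return float(average_precision_score(y, np.asarray(scores, dtype=float)))


def classify(scores, cutoff: float = DEFAULT_CUTOFF) -> list[str]:
    """Label approved iff score is strictly above the cutoff (percent)."""
    return [POSITIVE_CLASS if s > cutoff else "terminated" for s in scores]


def _pred_binary(scores, cutoff: float) -> np.ndarray:
    return (np.asarray(scores, dtype=float) > cutoff).astype(int)


def f1(scores, labels, cutoff: float = DEFAULT_CUTOFF) -> float:
    return float(f1_score(_as_binary(labels), _pred_binary(scores, cutoff), zero_division=0))


def accuracy(scores, labels, cutoff: float = DEFAULT_CUTOFF) -> float:
    return float(accuracy_score(_as_binary(labels), _pred_binary(scores, cutoff)))


def kappa(scores, labels, cutoff: float = DEFAULT_CUTOFF) -> float:
    """Cohen's kappa, (p_o - p_e)/(1 - p_e), at the classification cutoff."""
    return float(cohen_kappa_score(_as_binary(labels), _pred_binary(scores, cutoff)))


def roc_points(scores, labels) -> list[tuple[float, float]]:
    """ROC curve as (FPR, TPR) points from (0,0) to (1,1); the trapezoidal
    area under these points equals :func:`auc`."""
    y = _as_binary(labels)
    if len(set(y)) < 2:
        raise ValueError("ROC requires both classes")
    fpr, tpr, _ = roc_curve(y, np.asarray(scores, dtype=float))
    return list(zip(fpr.tolist(), tpr.tolist()))


def kendall_tau_b(x, y) -> tuple[float, float]:
    """Tie-corrected Kendall rank correlation tau-b with an asymptotic
    normal p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if len(x) < 2:
        raise ValueError("need at least two observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("tau undefined for an all-tied variable")
    res = stats.kendalltau(x, y, method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def _fold_metrics(scores, labels, cutoff: float = DEFAULT_CUTOFF) -> dict[str, float]:
    return {
        "auc": auc(scores, labels),
        "auprc": auprc(scores, labels),
        "f1": f1(scores, labels, cutoff),
        "accuracy": accuracy(scores, labels, cutoff),
        "kappa": kappa(scores, labels, cutoff),
    }


# ---------------------------------------------------------------------------
# results / reports


@dataclass
class ImportanceReport:
    """Feature name -> impurity importance rescaled so the maximum is 100."""

    scores: dict[str, float]

    def top(self, k: int = 20) -> list[tuple[str, float]]:
        ordered = sorted(self.scores.items(), key=lambda kv: (-kv[1], kv[0]))
        return ordered[:k]


@dataclass
class CVReport:
    """Mean and standard deviation (%) of each metric over repeats x folds."""

    algorithm: str
    means: dict[str, float]
    sds: dict[str, float]
    fold_values: np.ndarray  # (repeats*folds, len(METRICS))
    repeats: int
    folds: int
    seed: int
    label: str = ""

    def summary(self) -> str:
        title = self.label or self.algorithm
        lines = [
            f"Cross-validation: {title}",
            f"{self.repeats} repeats x {self.folds} folds (seed {self.seed})",
            f"{'metric':<10}{'mean %':>10}{'sd %':>10}",
        ]
        for m in METRICS:
            lines.append(f"{m:<10}{self.means[m]:>10.1f}{self.sds[m]:>10.1f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "label": self.label,
            "repeats": self.repeats,
            "folds": self.folds,
            "seed": self.seed,
            "means_pct": {m: self.means[m] for m in METRICS},
            "sds_pct": {m: self.sds[m] for m in METRICS},
        }


@dataclass
class RepurposingResults:
    """A fitted classifier bound to its feature schema.

    Prediction scores are pseudoprobabilities of the approved class on a
    0-100% scale.
    """

    estimator: object
    schema: FeatureSchema
    spec: ModelSpec
    positive_class: str = POSITIVE_CLASS
    n_obs: int = 0

    def predict_scores(self, m: FeatureMatrix, method: str = "mean_probability") -> np.ndarray:
        """Score pairs in ``m``; schema must equal the training schema.

        ``mean_probability`` (default) averages per-tree (or model) class
        probabilities; ``vote`` uses the fraction of forest trees whose
        hard prediction is the approved class (random forest only).
        """
        if m.schema.names != self.schema.names:
            raise ValueError("feature matrix schema does not match the trained model")
        X = m.values.astype(float)
        final = _final_estimator(self.estimator)
        classes = list(final.classes_)
        pos = classes.index(self.positive_class)
        if method == "mean_probability":
            return 100.0 * self.estimator.predict_proba(X)[:, pos]
        if method == "vote":
            if not isinstance(final, RandomForestClassifier):
                raise ValueError("vote scoring requires a random forest")
            votes = np.stack([t.predict(X) for t in final.estimators_])
            return 100.0 * (votes == pos).mean(axis=0)
        raise ValueError(f"unknown scoring method {method!r}")

    def feature_importance(self) -> ImportanceReport:
        """Impurity-based importances normalized to a 0-100 scale."""
        final = _final_estimator(self.estimator)
        if not hasattr(final, "feature_importances_"):
            raise ValueError(
                f"algorithm {self.spec.algorithm!r} has no native feature importances"
            )
        imp = np.asarray(final.feature_importances_, dtype=float)
        top = imp.max()
        scaled = imp * (100.0 / top) if top > 0 else imp
        return ImportanceReport(dict(zip(self.schema.names, scaled.tolist())))

    def summary(self, top_k: int = 10) -> str:
        lines = [
            "Drug-disease pair classifier",
            f"algorithm: {self.spec.algorithm}   seed: {self.spec.seed}",
            f"n observations: {self.n_obs}   n features: {len(self.schema)}",
            f"positive class: {self.positive_class}",
        ]
        try:
            lines.append(f"top {top_k} features (importance, max=100):")
            for name, score in self.feature_importance().top(top_k):
                lines.append(f"  {name:<45}{score:>8.1f}")
        except ValueError:
            pass
        return "\n".join(lines)

    def plot_roc(self, m: FeatureMatrix, ax=None):
        """ROC curve of this model's scores on a labelled matrix."""
        import matplotlib.pyplot as plt

        pts = roc_points(self.predict_scores(m), [l for l in m.labels])
        if ax is None:
            _, ax = plt.subplots()
        xs, ys = zip(*pts)
        ax.plot(xs, ys)
        ax.plot([0, 1], [0, 1], ls="--", c="grey")
        ax.set_xlabel("False positive rate")
        ax.set_ylabel("True positive rate")
        return ax


class RepurposingClassifier:
    """Model object: a labelled feature matrix plus a model specification."""

    def __init__(self, matrix: FeatureMatrix, spec: ModelSpec | None = None) -> None:
        if not matrix.has_labels():
            raise ValueError("training requires labels on every row")
        if len(set(matrix.labels)) < 2:
            raise ValueError("training requires both classes")
        self.matrix = matrix
        self.spec = spec or ModelSpec()

    @classmethod
    def from_matrix(cls, matrix: FeatureMatrix, **spec_kwargs) -> "RepurposingClassifier":
        return cls(matrix, ModelSpec(**spec_kwargs))

    def fit(self) -> RepurposingResults:
        est = build_estimator(self.spec)
        est.fit(self.matrix.values.astype(float), np.asarray(self.matrix.labels))
        return RepurposingResults(
            estimator=est,
            schema=self.matrix.schema,
            spec=self.spec,
            n_obs=self.matrix.n_rows,
        )

    def cross_validate(
        self,
        repeats: int = 10,
        folds: int = 10,
        seed: int | None = None,
        cutoff: float = DEFAULT_CUTOFF,
        label: str = "",
    ) -> CVReport:
        """Repeated stratified K-fold CV; metrics per test fold, mean/sd
        over all repeats x folds fold-level values."""
        seed = self.spec.seed if seed is None else seed
        y = np.asarray(self.matrix.labels)
        counts = {c: int((y == c).sum()) for c in set(y)}
        if min(counts.values()) < folds:
            raise ValueError(f"class too small for {folds}-fold stratification: {counts}")
        X = self.matrix.values.astype(float)
        splitter = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
        template = build_estimator(self.spec)
        rows = []
        for train_idx, test_idx in splitter.split(X, y):
            est = clone(template)
            est.fit(X[train_idx], y[train_idx])
            final = _final_estimator(est)
            pos = list(final.classes_).index(POSITIVE_CLASS)
            scores = 100.0 * est.predict_proba(X[test_idx])[:, pos]
            fm = _fold_metrics(scores, y[test_idx], cutoff)
            rows.append([fm[m] for m in METRICS])
        vals = np.asarray(rows)
        return CVReport(
            algorithm=self.spec.algorithm,
            means={m: 100.0 * vals[:, i].mean() for i, m in enumerate(METRICS)},
            sds={m: 100.0 * vals[:, i].std(ddof=1) for i, m in enumerate(METRICS)},
            fold_values=vals,
            repeats=repeats,
            folds=folds,
            seed=seed,
            label=label,
        )


# ---------------------------------------------------------------------------
# functional surface


def train(m: FeatureMatrix, spec: ModelSpec) -> RepurposingResults:
    return RepurposingClassifier(m, spec).fit()


def predict_scores(
    results: RepurposingResults, m: FeatureMatrix, method: str = "mean_probability"
) -> np.ndarray:
    return results.predict_scores(m, method=method)


def feature_importance(results: RepurposingResults) -> ImportanceReport:
    return results.feature_importance()


def cross_validate(
    m: FeatureMatrix,
    spec: ModelSpec,
    repeats: int = 10,
    folds: int = 10,
    seed: int | None = None,
) -> CVReport:
    return RepurposingClassifier(m, spec).cross_validate(repeats=repeats, folds=folds, seed=seed)


def compare_models(
    m: FeatureMatrix,
    specs: list[ModelSpec],
    repeats: int = 10,
    folds: int = 10,
    seed: int = 0,
) -> list[CVReport]:
    """One CVReport per spec, all evaluated on identical fold assignments
    (the splitter seed is shared) for paired comparison."""
    if not specs:
        raise ValueError("need at least one model spec")
    return [
        RepurposingClassifier(m, spec).cross_validate(repeats=repeats, folds=folds, seed=seed)
        for spec in specs
    ]


def fold_assignments(
    labels, repeats: int, folds: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """The exact (train, test) index splits cross_validate uses for a seed."""
    y = np.asarray(labels)
    splitter = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
    return [(tr.copy(), te.copy()) for tr, te in splitter.split(np.zeros((len(y), 1)), y)]


# ---------------------------------------------------------------------------
# model artifact IO


def _schema_hash(schema: FeatureSchema) -> str:
    return hashlib.sha256("\n".join(schema.names).encode()).hexdigest()


def save_model(results: RepurposingResults, path: str | Path) -> None:
    """Serialize the fitted estimator plus a schema sidecar JSON."""
    joblib.dump({"estimator": results.estimator, "spec": results.spec, "n_obs": results.n_obs}, path)
    sidecar = Path(str(path) + ".schema.json")
    with open(sidecar, "w") as fh:
        json.dump({**results.schema.to_dict(), "sha256": _schema_hash(results.schema)}, fh, indent=1)


def load_model(path: str | Path) -> RepurposingResults:
    """Load a model artifact, verifying the schema hash."""
    payload = joblib.load(path)
    with open(Path(str(path) + ".schema.json")) as fh:
        raw = json.load(fh)
    schema = FeatureSchema(names=tuple(raw["names"]), provenance=raw["provenance"])
    if raw.get("sha256") != _schema_hash(schema):
        raise ValueError("schema sidecar hash mismatch; artifact corrupted")
    return RepurposingResults(
        estimator=payload["estimator"],
        schema=schema,
        spec=payload["spec"],
        n_obs=payload.get("n_obs", 0),
    )
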