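"""Classifier training and evaluation for inducer/non-inducer prediction.

The protocol: exhaustive grid search over a per-algorithm hyperparameter grid,
scored by mean ROC AUC over 5 stratified cross-validation folds on the
training split only; the best configuration is refit on all training rows and
evaluated once on the held-out split. Metrics are the standard confusion-based
bundle (sensitivity, specificity, accuracy, Matthews correlation coefficient)
plus the rank-based AUC. Accuracy is reported on the 0-100 scale, the rest on
their natural scales.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.feature_selection import RFE
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import mutual_info_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, LinearSVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .descriptors import FeatureMatrix
from .io import PeptideDataset

ALGORITHMS = ("DT", "RF", "KNN", "MLP", "ET", "SVR", "XGB", "LASSO")

# Documented default grids; kept deliberately small so a full search stays
# tractable on desk-scale data. Tree counts and depths are the knobs that
# matter most for the ensemble methods on composition descriptors.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "DT": {"max_depth": [None, 5, 10], "min_samples_leaf": [1, 5]},
    "RF": {"n_estimators": [100, 250, 500], "max_depth": [None, 5, 10]},
    "ET": {"n_estimators": [100, 250, 500], "max_depth": [None, 5, 10]},
    "KNN": {"n_neighbors": [3, 5, 11], "weights": ["uniform", "distance"]},
    "MLP": {"hidden_layer_sizes": [(32,), (64,)], "alpha": [1e-4, 1e-2]},
    "SVR": {"C": [0.1, 1.0, 10.0], "gamma": ["scale"]},
    "XGB": {"n_estimators": [100, 250], "max_depth": [3, 6]},
    "LASSO": {"C": [0.01, 0.1, 1.0, 10.0]},
}


def _base_estimator(algorithm: str, seed: int):
    if algorithm == "DT":
        return DecisionTreeClassifier(random_state=seed)
    if algorithm == "RF":
        return RandomForestClassifier(random_state=seed, n_jobs=1)
    if algorithm == "ET":
        return ExtraTreesClassifier(random_state=seed, n_jobs=1)
    if algorithm == "KNN":
        return KNeighborsClassifier()
    if algorithm == "MLP":
        return MLPClassifier(random_state=seed, max_iter=500)
    if algorithm == "SVR":
        # RBF support-vector machine used as a classifier through a
        # probability-calibrated margin.
        return SVC(kernel="rbf", probability=True, random_state=seed)
    if algorithm == "XGB":
        return XGBClassifier(
            random_state=seed,
            eval_metric="logloss",
            n_jobs=1,
            verbosity=0,
        )
    if algorithm == "LASSO":
        # L1-penalised logistic regression: the sparse linear baseline.
        return LogisticRegression(
            penalty="l1", solver="liblinear", random_state=seed, max_iter=2000
        )
    raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")


_SCALED = {"KNN", "MLP", "SVR", "LASSO"}


@dataclass
class ModelSpec:
    """Algorithm choice plus the search protocol parameters."""

    algorithm: str
    grid: Optional[dict[str, list]] = None
    cv_folds: int = 5
    scoring: str = "roc_auc"
    seed: int = 42

    def __post_init__(self) -> None:
        self.algorithm = self.algorithm.upper()
        if self.algorithm not in ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}"
            )
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.grid is None:
            self.grid = dict(DEFAULT_GRIDS[self.algorithm])
        if not self.grid:
            raise ValueError("hyperparameter grid must be non-empty")


@dataclass
class TrainedPredictor:
    """A fitted classifier with the metadata needed to reapply it."""

    spec: ModelSpec
    feature_set: str
    feature_names: list[str]
    estimator: object
    best_params: dict
    cv_score: float

    def predict_proba(self, features: FeatureMatrix | pd.DataFrame) -> np.ndarray:
        """Positive-class probability for each row, aligned to training columns."""
        frame = features.frame if isinstance(features, FeatureMatrix) else features
        X = frame[self.feature_names].to_numpy(dtype=float)
        return self.estimator.predict_proba(X)[:, 1]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """Sensitivity/specificity/AUC/MCC on natural scales; accuracy in percent."""

    sensitivity: float
    specificity: float
    accuracy: float
    mcc: float
    auc: float

    def to_row(self) -> dict[str, float]:
        return {
            "Sens": self.sensitivity,
            "Spec": self.specificity,
            "ACC": self.accuracy,
            "AUC": self.auc,
            "MCC": self.mcc,
        }


def train(
    features: FeatureMatrix,
    labels: Sequence[int] | np.ndarray,
    spec: ModelSpec,
) -> TrainedPredictor:
    """Grid-search a classifier under stratified k-fold CV, refit the best.

    Cross-validation uses only the rows given here; held-out evaluation is the
    caller's responsibility. Deterministic for a fixed ``spec.seed``.
    """
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels must contain both classes")
    X = features.frame.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    if X.shape[0] < spec.cv_folds:
        raise ValueError("fewer rows than CV folds")
    # canonical row order (by id, then features) so the seeded fold shuffle —
    # and hence the whole search — is invariant to input row order
    ids = features.frame.index.to_numpy(dtype=str)
    order = np.lexsort((y, ids))
    X, y = X[order], y[order]

    base = _base_estimator(spec.algorithm, spec.seed)
    if spec.algorithm in _SCALED:
        est = Pipeline([("scale", StandardScaler()), ("clf", base)])
        grid = {f"clf__{k}": v for k, v in spec.grid.items()}
    else:
        est = base
        grid = spec.grid
    cv = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed)
    search = GridSearchCV(est, grid, scoring=spec.scoring, cv=cv, n_jobs=1, refit=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        search.fit(X, y)
    best_params = {k.removeprefix("clf__"): v for k, v in search.best_params_.items()}
    return TrainedPredictor(
        spec=spec,
        feature_set=features.feature_set,
        feature_names=list(features.frame.columns),
        estimator=search.best_estimator_,
        best_params=best_params,
        cv_score=float(search.best_score_),
    )


def confusion(
    scores: Sequence[float],
    labels: Sequence[int],
    threshold: float = 0.5,
) -> ConfusionCounts:
    """Threshold probabilities into calls; a score equal to the threshold is
    a positive call."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.size == 0 or s.shape != y.shape:
        raise ValueError("scores and labels must be non-empty and aligned")
    calls = s >= threshold
    return ConfusionCounts(
        tp=int(np.sum(calls & (y == 1))),
        fp=int(np.sum(calls & (y == 0))),
        tn=int(np.sum(~calls & (y == 0))),
        fn=int(np.sum(~calls & (y == 1))),
    )


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based AUC: probability a random positive outscores a random
    negative, ties counted one half (the Mann-Whitney statistic)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(s)
    u = float(np.sum(ranks[y == 1])) - n1 * (n1 + 1) / 2.0
    return u / (n1 * n0)


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any denominator factor is 0."""
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / float(np.sqrt(denom))


def metrics(
    c: ConfusionCounts,
    scores: Optional[Sequence[float]] = None,
    labels: Optional[Sequence[int]] = None,
) -> MetricsReport:
    """The full evaluation bundle from a confusion table (+ scores for AUC).

    Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), accuracy =
    100*(TP+TN)/total; undefined ratios (empty class) are reported as 0.
    """
    if c.total == 0:
        raise ValueError("empty confusion table")
    sens = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    spec = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else 0.0
    acc = 100.0 * (c.tp + c.tn) / c.total
    auc = roc_auc(scores, labels) if scores is not None else float("nan")
    return MetricsReport(
        sensitivity=sens, specificity=spec, accuracy=acc, mcc=mcc(c), auc=auc
    )


def evaluate(
    predictor: TrainedPredictor,
    features: FeatureMatrix,
    labels: Sequence[int],
    threshold: float = 0.5,
) -> MetricsReport:
    """Score a feature matrix and report the full metrics bundle."""
    scores = predictor.predict_proba(features)
    return metrics(confusion(scores, labels, threshold), scores, labels)


# ---------------------------------------------------------------------------
# feature selection


def _discretize(X: np.ndarray, bins: int = 10) -> np.ndarray:
    out = np.empty_like(X, dtype=int)
    for j in range(X.shape[1]):
        col = X[:, j]
        edges = np.quantile(col, np.linspace(0, 1, bins + 1)[1:-1])
        out[:, j] = np.searchsorted(edges, col, side="right")
    return out


def _mrmr(X: np.ndarray, y: np.ndarray, names: list[str], k: int) -> list[str]:
    Xd = _discretize(X)
    relevance = np.array(
        [mutual_info_score(Xd[:, j], y) for j in range(Xd.shape[1])]
    )
    selected: list[int] = []
    redundancy = np.zeros(Xd.shape[1])
    remaining = set(range(Xd.shape[1]))
    while len(selected) < k:
        if selected:
            last = selected[-1]
            for j in remaining:
                redundancy[j] += mutual_info_score(Xd[:, j], Xd[:, last])
            score = {
                j: relevance[j] - redundancy[j] / len(selected) for j in remaining
            }
        else:
            score = {j: relevance[j] for j in remaining}
        best = max(sorted(remaining), key=lambda j: score[j])
        selected.append(best)
        remaining.discard(best)
    return [names[j] for j in selected]


def _l1_select(X: np.ndarray, y: np.ndarray, names: list[str], k: int, seed: int) -> list[str]:
    Xs = StandardScaler().fit_transform(X)
    c = 0.1
    coefs = None
    for _ in range(12):  # grow the penalty budget until >= k features survive
        clf = LinearSVC(penalty="l1", dual=False, C=c, max_iter=5000, random_state=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(Xs, y)
        coefs = np.abs(clf.coef_.ravel())
        if int(np.sum(coefs > 0)) >= k:
            break
        c *= 3.0
    order = np.argsort(-coefs, kind="stable")
    return [names[j] for j in order[:k]]


def select_features(
    matrix: FeatureMatrix,
    labels: Sequence[int],
    method: str,
    k: int,
    seed: int = 42,
) -> list[str]:
    """Pick the top-k feature names by one of four selection strategies.

    ``mRMR`` greedily maximises relevance minus mean redundancy (mutual
    information on decile-discretized columns); ``L1`` ranks by the absolute
    coefficients of an L1-penalised linear classifier; ``RFE`` recursively
    eliminates 10% of features per step with an extra-trees ranker;
    ``importance`` ranks by impurity-based importances of an extra-trees
    ensemble (a transparent stand-in for model-explanation scores).
    """
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("feature selection needs both classes")
    names = list(matrix.frame.columns)
    if k > len(names):
        raise ValueError(f"k={k} exceeds {len(names)} columns")
    X = matrix.frame.to_numpy(dtype=float)
    method = method.lower()
    if method == "mrmr":
        return _mrmr(X, y, names, k)
    if method == "l1":
        return _l1_select(X, y, names, k, seed)
    if method == "rfe":
        est = ExtraTreesClassifier(n_estimators=100, random_state=seed, n_jobs=1)
        rfe = RFE(est, n_features_to_select=k, step=0.1)
        rfe.fit(X, y)
        return [n for n, keep in zip(names, rfe.support_) if keep]
    if method == "importance":
        est = ExtraTreesClassifier(n_estimators=250, random_state=seed, n_jobs=1)
        est.fit(X, y)
        order = np.argsort(-est.feature_importances_, kind="stable")
        return [names[j] for j in order[:k]]
    raise ValueError("method must be one of mRMR, L1, RFE, importance")


def subset_features(matrix: FeatureMatrix, names: Sequence[str]) -> FeatureMatrix:
    """Restrict a feature matrix to a selected column list (order preserved)."""
    return FeatureMatrix(matrix.feature_set, matrix.frame[list(names)])


# ---------------------------------------------------------------------------
# persistence

_BUNDLE_VERSION = 1


def save_model(predictor: TrainedPredictor, path) -> None:
    joblib.dump({"version": _BUNDLE_VERSION, "predictor": predictor}, path)


def load_model(path) -> TrainedPredictor:
    bundle = joblib.load(path)
    if bundle.get("version") != _BUNDLE_VERSION:
        raise ValueError(f"unsupported model bundle version: {bundle.get('version')}")
    return bundle["predictor"]


# ---------------------------------------------------------------------------
# similarity-search annotation (external blastp-short)


@dataclass
class SimilarityResult:
    """Per-query top-hit annotation plus the Table-style hit bookkeeping."""

    assignments: pd.DataFrame  # columns: id, hit_id, hit_label
    correct_positive: int
    incorrect_positive: int
    correct_negative: int
    incorrect_negative: int
    no_hit: int

    @property
    def total_hits(self) -> int:
        return (
            self.correct_positive
            + self.incorrect_positive
            + self.correct_negative
            + self.incorrect_negative
        )

    def confusion(self) -> ConfusionCounts:
        return ConfusionCounts(
            tp=self.correct_positive,
            fp=self.incorrect_positive,
            tn=self.correct_negative,
            fn=self.incorrect_negative,
        )


def tabulate_hits(assignments: pd.DataFrame, query: PeptideDataset) -> SimilarityResult:
    """Book-keep top-hit labels against query labels (Table-style layout).

    'Correct positive' counts positive-labeled queries whose top hit is
    positive; 'incorrect positive' counts queries annotated positive whose
    true label is negative; likewise for negatives.
    """
    label_of = {r.id: r.label for r in query}
    cp = ip = cn = inn = nh = 0
    for _, row in assignments.iterrows():
        truth = label_of.get(row["id"])
        hit = row["hit_label"]
        if hit is None or (isinstance(hit, float) and np.isnan(hit)):
            nh += 1
        elif hit == "positive":
            if truth == "positive":
                cp += 1
            else:
                ip += 1
        else:
            if truth == "negative":
                cn += 1
            else:
                inn += 1
    return SimilarityResult(assignments, cp, ip, cn, inn, nh)


def similarity_annotate(
    query: PeptideDataset,
    db: PeptideDataset,
    evalue: float = 1e-3,
    blastp: str = "blastp",
    makeblastdb: str = "makeblastdb",
) -> SimilarityResult:
    """Annotate queries by the label of their top short-peptide BLAST hit.

    Builds a protein database from ``db``, runs ``blastp -task blastp-short``
    at the given e-value, discards self-hits (query id equal to subject id)
    and assigns each query the label of its first remaining hit, or 'no hit'.
    Requires the NCBI BLAST+ tools on PATH.
    """
    for tool in (blastp, makeblastdb):
        if shutil.which(tool) is None:
            raise RuntimeError(
                f"{tool!r} not found on PATH; install NCBI BLAST+ or pass an "
                "explicit executable path"
            )
    db_labels = {r.id: r.label for r in db}
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        db_fa = tmp / "db.fasta"
        q_fa = tmp / "query.fasta"
        with open(db_fa, "w") as fh:
            for r in db:
                fh.write(f">{r.id}\n{r.sequence}\n")
        with open(q_fa, "w") as fh:
            for r in query:
                fh.write(f">{r.id}\n{r.sequence}\n")
        subprocess.run(
            [makeblastdb, "-in", str(db_fa), "-dbtype", "prot"],
            check=True,
            capture_output=True,
        )
        proc = subprocess.run(
            [
                blastp,
                "-task",
                "blastp-short",
                "-query",
                str(q_fa),
                "-db",
                str(db_fa),
                "-evalue",
                str(evalue),
                "-outfmt",
                "6 qseqid sseqid evalue bitscore",
            ],
            check=True,
            capture_output=True,
            text=True,
        )
    first_hit: dict[str, str] = {}
    for line in proc.stdout.splitlines():
        parts = line.split("\t")
        if len(parts) < 2:
            raise RuntimeError(f"malformed BLAST output line: {line!r}")
        qid, sid = parts[0], parts[1]
        if qid == sid or qid in first_hit:
            continue
        first_hit[qid] = sid
    rows = []
    for r in query:
        sid = first_hit.get(r.id)
        rows.append(
            {
                "id": r.id,
                "hit_id": sid,
                "hit_label": db_labels.get(sid) if sid is not None else None,
            }
        )
    return tabulate_hits(pd.DataFrame(rows), query)
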