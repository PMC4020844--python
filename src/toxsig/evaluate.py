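"""Classifier battery, output scaling and nested cross-validation.

Six classifiers consume z-scored signature features (compounds x genes):
linear SVM, KNN, nearest shrunken centroids (PAM), Random Forest, weighted
voting and Gaussian Naive Bayes.  Every classifier emits a score in [0, 1],
higher = more primary-class-like:

* SVM: logistic map 1 / (1 + exp(-slope * d)) of the signed decision value;
* weighted voting: prediction strength PS in [-1, 1] mapped by (PS + 1) / 2;
* KNN: x / k, the fraction of primary-class nearest neighbors;
* PAM, Random Forest, Naive Bayes: native primary-class probability.

Evaluation uses nested stratified 3x3-fold cross-validation: within each
outer fold the signature is re-extracted on the training compounds only
(no leakage), features are z-scored on the training compounds, and
hyperparameters are tuned by an inner 3-fold CV maximizing AUC.  Per-fold
ROC curves are combined by threshold averaging and binary calls use a
Youden-optimal cutoff per classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .data import (
    CompoundLabelSet,
    FoldChangeMatrix,
    Signature,
    StandardizedFeatureMatrix,
    safe_zscore_features,
)
from .rankers import soft_threshold
from .sr import SRConfig, extract_sr_signature

ALGORITHMS = ("svm", "knn", "pam", "rf", "wv", "nb")

#: inner-CV hyperparameter grids; data-driven for PAM (quantiles of |d_gk|)
SVM_C_GRID = (0.1, 1.0, 10.0, 100.0)
KNN_K_GRID = (1, 3, 5)
PAM_DELTA_QUANTILES = 10
RF_N_TREES = 500


class WeightedVotingModel:
    """Golub's weighted voting classifier.

    Each signature gene casts a vote v_g = a_g (x_g - b_g) where a_g is the
    signed Golub ratio fitted on the training features and b_g the midpoint
    of the class means.  Prediction strength PS = (V_win - V_lose) /
    (V_win + V_lose) lies in [-1, 1]; positive PS favours the primary class.
    """

    def fit(self, X: np.ndarray, y: np.ndarray) -> "WeightedVotingModel":
        x1, x2 = X[y == 1], X[y == 0]
        mu1, mu2 = x1.mean(axis=0), x2.mean(axis=0)
        sd1 = x1.std(axis=0, ddof=1)
        sd2 = x2.std(axis=0, ddof=1)
        denom = sd1 + sd2
        denom = np.where(denom > 0, denom, np.finfo(float).tiny)
        self.a_ = (mu1 - mu2) / denom
        self.b_ = (mu1 + mu2) / 2.0
        return self

    def prediction_strength(self, X: np.ndarray) -> np.ndarray:
        votes = self.a_ * (X - self.b_)
        v_win = np.clip(votes, 0.0, None).sum(axis=1)
        v_lose = np.clip(-votes, 0.0, None).sum(axis=1)
        total = v_win + v_lose
        with np.errstate(invalid="ignore"):
            ps = np.where(total > 0, (v_win - v_lose) / np.where(total > 0, total, 1.0), 0.0)
        return ps


def weighted_voting_score(model: WeightedVotingModel, x: np.ndarray) -> float:
    """Prediction strength of a single feature vector, in [-1, 1]."""
    return float(model.prediction_strength(np.atleast_2d(x))[0])


class PAMClassifier:
    """Nearest shrunken centroid classifier with class posteriors.

    Centroids are shrunken toward the overall mean by soft-thresholding the
    standardized centroid distances d_gk with Delta; posteriors come from
    the Gaussian discriminant score with class priors taken from the
    training proportions.
    """

    def __init__(self, delta: float = 0.0):
        self.delta = delta

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PAMClassifier":
        n, _ = X.shape
        classes = (0, 1)
        grand = X.mean(axis=0)
        ss = np.zeros(X.shape[1])
        centroids, m_k, n_k = {}, {}, {}
        for c in classes:
            xc = X[y == c]
            n_k[c] = len(xc)
            centroids[c] = xc.mean(axis=0)
            ss += ((xc - centroids[c]) ** 2).sum(axis=0)
            m_k[c] = np.sqrt(1.0 / n_k[c] - 1.0 / n)
        s = np.sqrt(ss / (n - len(classes)))
        s0 = float(np.median(s))
        self.s_, self.s0_ = s, s0
        self.shrunken_ = {}
        self.d_ = {}
        for c in classes:
            d = (centroids[c] - grand) / (m_k[c] * (s + s0))
            self.d_[c] = d
            self.shrunken_[c] = grand + m_k[c] * (s + s0) * soft_threshold(d, self.delta)
        self.priors_ = {c: n_k[c] / n for c in classes}
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        # discriminant: squared standardized distance minus 2 log prior
        scores = {}
        for c in (0, 1):
            dist = (((X - self.shrunken_[c]) / (self.s_ + self.s0_)) ** 2).sum(axis=1)
            scores[c] = -0.5 * dist + np.log(self.priors_[c])
        stacked = np.column_stack([scores[0], scores[1]])
        stacked -= stacked.max(axis=1, keepdims=True)
        expd = np.exp(stacked)
        return expd / expd.sum(axis=1, keepdims=True)

    def delta_grid(self) -> np.ndarray:
        magnitudes = np.abs(np.concatenate([self.d_[0], self.d_[1]]))
        qs = np.linspace(0.0, 0.9, PAM_DELTA_QUANTILES)
        return np.unique(np.quantile(magnitudes, qs))


def scale_output(algorithm: str, raw: np.ndarray | float, slope: float = 1.0,
                 knn_k: int | None = None) -> np.ndarray | float:
    """Map a classifier's raw output into [0, 1] (see module docstring)."""
    raw_arr = np.asarray(raw, dtype=float)
    if algorithm == "svm":
        out = 1.0 / (1.0 + np.exp(-slope * raw_arr))
    elif algorithm == "wv":
        out = (raw_arr + 1.0) / 2.0
    elif algorithm == "knn":
        if knn_k is None:
            raise ValueError("knn scaling needs the neighbor count k")
        if np.any(raw_arr > knn_k) or np.any(raw_arr < 0):
            raise ValueError("KNN raw output must satisfy 0 <= x <= k")
        out = raw_arr / knn_k
    elif algorithm in ("pam", "rf", "nb"):
        out = raw_arr  # native probabilities
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    return out if np.ndim(raw) else float(out)


@dataclass
class TrainedClassifier:
    """A fitted classifier plus its feature scaling and output map."""

    algorithm: str
    model: object
    scaler: StandardizedFeatureMatrix
    hyperparams: dict
    svm_slope: float = 1.0

    def _raw_to_scaled(self, X: np.ndarray) -> np.ndarray:
        alg, model = self.algorithm, self.model
        if alg == "svm":
            return scale_output("svm", model.decision_function(X), self.svm_slope)
        if alg == "wv":
            return scale_output("wv", model.prediction_strength(X))
        if alg == "knn":
            k = self.hyperparams["k"]
            pos = model.predict_proba(X)[:, list(model.classes_).index(1)]
            return scale_output("knn", pos * k, knn_k=k)
        if alg == "pam":
            return model.predict_proba(X)[:, 1]
        # rf, nb
        return model.predict_proba(X)[:, list(model.classes_).index(1)]

    def score_features(self, features: pd.DataFrame) -> np.ndarray:
        return self._raw_to_scaled(features.to_numpy())

    def score_compounds(
        self, matrix: FoldChangeMatrix, compound_ids: Sequence[str]
    ) -> pd.Series:
        feats = self.scaler.transform(matrix, compound_ids)
        return pd.Series(self.score_features(feats), index=list(compound_ids))


def train_classifier(
    algorithm: str,
    features: StandardizedFeatureMatrix,
    y: np.ndarray,
    hyperparams: dict | None = None,
    seed: int | None = None,
    svm_slope: float = 1.0,
) -> TrainedClassifier:
    """Fit one of the six algorithms on z-scored training features."""
    hyperparams = dict(hyperparams or {})
    X = features.features.to_numpy()
    y = np.asarray(y, dtype=int)
    if len(set(y)) < 2 or (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("degenerate training data: need >= 2 compounds per class")
    if algorithm == "svm":
        hyperparams.setdefault("C", 1.0)
        model = SVC(kernel="linear", C=hyperparams["C"], tol=1e-6).fit(X, y)
    elif algorithm == "knn":
        hyperparams.setdefault("k", 3)
        k = min(hyperparams["k"], len(y))
        hyperparams["k"] = k
        model = KNeighborsClassifier(n_neighbors=k).fit(X, y)
    elif algorithm == "pam":
        hyperparams.setdefault("delta", 0.0)
        model = PAMClassifier(delta=hyperparams["delta"]).fit(X, y)
    elif algorithm == "rf":
        hyperparams.setdefault("n_estimators", RF_N_TREES)
        model = RandomForestClassifier(
            n_estimators=hyperparams["n_estimators"], random_state=seed
        ).fit(X, y)
    elif algorithm == "wv":
        model = WeightedVotingModel().fit(X, y)
    elif algorithm == "nb":
        model = GaussianNB().fit(X, y)
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    return TrainedClassifier(
        algorithm=algorithm,
        model=model,
        scaler=features,
        hyperparams=hyperparams,
        svm_slope=svm_slope,
    )


@dataclass
class ROCCurve:
    """(threshold, FPR, TPR) triples in decreasing threshold order, with AUC."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    @classmethod
    def from_scores(cls, scores: np.ndarray, y: np.ndarray) -> "ROCCurve":
        scores = np.asarray(scores, dtype=float)
        y = np.asarray(y, dtype=int)
        fpr, tpr, thr = roc_curve(y, scores, drop_intermediate=False)
        return cls(thresholds=thr, fpr=fpr, tpr=tpr, auc=float(roc_auc_score(y, scores)))

    def at_thresholds(self, queries: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Step-function lookup: the operating point of rule ``score >= t``."""
        # thresholds are decreasing; find, per query, the last stored t >= query
        idx = np.searchsorted(-self.thresholds, -np.asarray(queries), side="right") - 1
        idx = np.clip(idx, 0, len(self.thresholds) - 1)
        return self.fpr[idx], self.tpr[idx]


def threshold_average_roc(curves: Sequence[ROCCurve]) -> ROCCurve:
    """Average FPR and TPR across folds at each threshold of the merged grid."""
    if not curves:
        raise ValueError("need at least one curve")
    merged = np.unique(np.concatenate([c.thresholds for c in curves]))[::-1]
    fprs, tprs = zip(*(c.at_thresholds(merged) for c in curves))
    fpr = np.mean(fprs, axis=0)
    tpr = np.mean(tprs, axis=0)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=merged, fpr=fpr, tpr=tpr, auc=auc)


def optimal_cutoff(scores: np.ndarray, y: np.ndarray) -> float:
    """Threshold maximizing Youden's J = TPR - FPR (ties -> lower threshold).

    For perfectly separated scores this is the midpoint of the gap between
    the classes; for all-identical scores it degenerates to the minimum
    score (J = 0 everywhere).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(set(y.tolist())) < 2:
        raise ValueError("both classes must be present")
    candidates = np.unique(scores)
    n1 = (y == 1).sum()
    n0 = (y == 0).sum()
    best_j, best_c = -np.inf, candidates[0]
    for c in candidates:  # rule: score >= c is a primary call
        pred = scores >= c
        j = (pred & (y == 1)).sum() / n1 - (pred & (y == 0)).sum() / n0
        if j > best_j + 1e-12:
            best_j, best_c = j, c
    below = candidates[candidates < best_c]
    if len(below):
        return float((best_c + below[-1]) / 2.0)
    return float(best_c)


@dataclass
class CVPlan:
    """Stratified outer folds plus the seed driving the inner splits."""

    outer: list[tuple[list[str], list[str]]]  # (train_ids, test_ids)
    k_inner: int
    seed: int | None


def make_cv_plan(
    labels: CompoundLabelSet,
    compound_ids: Sequence[str],
    k_outer: int = 3,
    k_inner: int = 3,
    seed: int | None = None,
) -> CVPlan:
    ids, y = labels.analysis_view(compound_ids)
    splitter = StratifiedKFold(n_splits=k_outer, shuffle=True, random_state=seed)
    outer = []
    ids_arr = np.asarray(ids)
    for train_idx, test_idx in splitter.split(ids_arr, y):
        outer.append((list(ids_arr[train_idx]), list(ids_arr[test_idx])))
    return CVPlan(outer=outer, k_inner=k_inner, seed=seed)


def _extract_fold_signature(
    matrix: FoldChangeMatrix,
    labels: CompoundLabelSet,
    train_ids: list[str],
    source,
    seed: int | None,
    sr_config: SRConfig | None,
    efs_params: dict | None,
) -> Signature:
    if isinstance(source, Signature):
        return source
    sub = matrix.subset_compounds(train_ids)
    if source == "sr":
        return extract_sr_signature(sub, labels, sr_config or SRConfig())
    if source == "efs":
        from .efs import run_efs  # local import to avoid a cycle

        return run_efs(sub, labels, seed=seed, **(efs_params or {})).signature
    raise ValueError(f"unknown signature source {source!r}")


def _tune_hyperparams(
    algorithm: str,
    matrix: FoldChangeMatrix,
    labels: CompoundLabelSet,
    genes: list[str],
    train_ids: list[str],
    k_inner: int,
    seed: int | None,
) -> dict:
    """Inner stratified CV over the algorithm's grid, maximizing mean AUC."""
    if algorithm == "svm":
        grid = [{"C": c} for c in SVM_C_GRID]
    elif algorithm == "knn":
        grid = [{"k": k} for k in KNN_K_GRID]
    elif algorithm == "pam":
        ids, y = labels.analysis_view(train_ids)
        feats, _ = safe_zscore_features(matrix, genes, ids)
        probe = PAMClassifier(0.0).fit(feats.features.to_numpy(), y)
        grid = [{"delta": float(d)} for d in probe.delta_grid()]
    else:
        return {}
    if len(grid) == 1:
        return grid[0]
    ids, y = labels.analysis_view(train_ids)
    ids_arr = np.asarray(ids)
    n_splits = min(k_inner, int(min((y == 1).sum(), (y == 0).sum())))
    if n_splits < 2:
        return grid[0]
    splitter = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    best_auc, best_params = -np.inf, grid[0]
    folds = list(splitter.split(ids_arr, y))
    for params in grid:
        aucs = []
        for tr, te in folds:
            tr_ids, te_ids = list(ids_arr[tr]), list(ids_arr[te])
            y_tr, y_te = y[tr], y[te]
            if len(set(y_te.tolist())) < 2 or min((y_tr == 1).sum(), (y_tr == 0).sum()) < 2:
                continue
            try:
                feats, _ = safe_zscore_features(matrix, genes, tr_ids)
                clf = train_classifier(algorithm, feats, y_tr, params, seed=seed)
                scores = clf.score_compounds(matrix, te_ids)
                aucs.append(roc_auc_score(y_te, scores.to_numpy()))
            except ValueError:
                continue
        mean_auc = np.mean(aucs) if aucs else -np.inf
        if mean_auc > best_auc + 1e-12:
            best_auc, best_params = mean_auc, params
    return best_params


def evaluate_fold(
    matrix: FoldChangeMatrix,
    labels: CompoundLabelSet,
    train_ids: list[str],
    test_ids: list[str],
    signature_source,
    algorithms: Sequence[str],
    k_inner: int = 3,
    seed: int | None = None,
    sr_config: SRConfig | None = None,
    efs_params: dict | None = None,
) -> dict:
    """Extract signature, tune, train and score one outer fold.

    Uses only the training compounds for signature extraction, feature
    scaling, tuning and fitting; test compounds are touched only at scoring
    time.  Returns per-algorithm test scores, the tuned hyperparameters and
    the fold signature.
    """
    signature = _extract_fold_signature(
        matrix, labels, train_ids, signature_source, seed, sr_config, efs_params
    )
    tr_ids, y_tr = labels.analysis_view(train_ids)
    te_ids, y_te = labels.analysis_view(test_ids)
    out: dict = {"signature": signature, "algorithms": {}, "test_ids": te_ids,
                 "y_test": y_te}
    for algorithm in algorithms:
        params = _tune_hyperparams(
            algorithm, matrix, labels, signature.gene_ids, tr_ids, k_inner, seed
        )
        feats, _ = safe_zscore_features(matrix, signature.gene_ids, tr_ids)
        clf = train_classifier(algorithm, feats, y_tr, params, seed=seed)
        scores = clf.score_compounds(matrix, te_ids)
        out["algorithms"][algorithm] = {
            "params": params,
            "scores": scores,
            "classifier": clf,
        }
    return out


@dataclass
class ClassifierEvaluation:
    """Cross-validated performance of one algorithm."""

    algorithm: str
    fold_curves: list[ROCCurve]
    fold_aucs: list[float]
    mean_auc: float
    sd_auc: float
    averaged_curve: ROCCurve | None
    compound_scores: pd.Series
    cutoff: float
    calls: pd.Series          # 1 = primary-class call at the optimal cutoff
    tuned: list[dict]


@dataclass
class EvaluationReport:
    """Nested-CV evaluation across classifiers."""

    per_classifier: dict[str, ClassifierEvaluation]
    plan: CVPlan
    fold_signatures: list[Signature]
    provenance: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            "Nested cross-validation evaluation",
            "=" * 46,
            f"outer folds: {len(self.plan.outer)}, inner folds: {self.plan.k_inner}, "
            f"seed: {self.plan.seed}",
            "",
            "classifier   mean AUC     sd    threshold-avg AUC",
            "-" * 50,
        ]
        for name, ev in self.per_classifier.items():
            avg = ev.averaged_curve.auc if ev.averaged_curve else float("nan")
            lines.append(
                f"{name:<10}   {ev.mean_auc:>7.3f}  {ev.sd_auc:>6.3f}   {avg:>10.3f}"
            )
        return "\n".join(lines)

    def auc_table(self) -> pd.DataFrame:
        rows = [
            {
                "algorithm": name,
                "mean_auc": ev.mean_auc,
                "sd_auc": ev.sd_auc,
                "threshold_avg_auc": (
                    ev.averaged_curve.auc if ev.averaged_curve else np.nan
                ),
            }
            for name, ev in self.per_classifier.items()
        ]
        return pd.DataFrame(rows)


def nested_cv_evaluate(
    matrix: FoldChangeMatrix,
    labels: CompoundLabelSet,
    signature_source,
    algorithms: Sequence[str] = ALGORITHMS,
    k_outer: int = 3,
    k_inner: int = 3,
    seed: int | None = None,
    sr_config: SRConfig | None = None,
    efs_params: dict | None = None,
) -> EvaluationReport:
    """Nested stratified k_outer x k_inner CV of the full signature pipeline.

    ``signature_source`` is ``"sr"``, ``"efs"`` (re-extraction inside every
    outer training fold) or a fixed :class:`Signature`.  Outer test folds
    with a single class contribute no AUC (logged as NaN and excluded).
    """
    plan = make_cv_plan(labels, matrix.compound_ids, k_outer, k_inner, seed)
    fold_results = []
    for f, (train_ids, test_ids) in enumerate(plan.outer):
        fold_seed = None if seed is None else seed + 1000 * (f + 1)
        fold_results.append(
            evaluate_fold(
                matrix, labels, train_ids, test_ids, signature_source,
                algorithms, k_inner, fold_seed, sr_config, efs_params,
            )
        )
    per_classifier: dict[str, ClassifierEvaluation] = {}
    for algorithm in algorithms:
        curves, aucs, tuned = [], [], []
        all_scores: list[pd.Series] = []
        all_y: list[np.ndarray] = []
        for res in fold_results:
            entry = res["algorithms"][algorithm]
            scores, y_te = entry["scores"], res["y_test"]
            all_scores.append(scores)
            all_y.append(y_te)
            tuned.append(entry["params"])
            if len(set(y_te.tolist())) < 2:
                continue
            curves.append(ROCCurve.from_scores(scores.to_numpy(), y_te))
            aucs.append(curves[-1].auc)
        pooled = pd.concat(all_scores)
        pooled_y = np.concatenate(all_y)
        cutoff = optimal_cutoff(pooled.to_numpy(), pooled_y)
        per_classifier[algorithm] = ClassifierEvaluation(
            algorithm=algorithm,
            fold_curves=curves,
            fold_aucs=aucs,
            mean_auc=float(np.mean(aucs)) if aucs else float("nan"),
            sd_auc=float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0,
            averaged_curve=threshold_average_roc(curves) if curves else None,
            compound_scores=pooled,
            cutoff=cutoff,
            calls=(pooled >= cutoff).astype(int),
            tuned=tuned,
        )
    provenance = {
        "signature_source": (
            "fixed" if isinstance(signature_source, Signature) else signature_source
        ),
        "algorithms": list(algorithms),
        "k_outer": k_outer,
        "k_inner": k_inner,
        "seed": seed,
    }
    return EvaluationReport(
        per_classifier=per_classifier,
        plan=plan,
        fold_signatures=[r["signature"] for r in fold_results],
        provenance=provenance,
    )


class NestedCVEvaluation:
    """Model-style interface: configure on data, ``fit(seed)`` runs nested CV."""

    def __init__(
        self,
        matrix: FoldChangeMatrix,
        labels: CompoundLabelSet,
        signature_source="sr",
        algorithms: Sequence[str] = ALGORITHMS,
        k_outer: int = 3,
        k_inner: int = 3,
        sr_config: SRConfig | None = None,
        efs_params: dict | None = None,
    ):
        self.matrix = matrix
        self.labels = labels
        self.signature_source = signature_source
        self.algorithms = tuple(algorithms)
        self.k_outer = k_outer
        self.k_inner = k_inner
        self.sr_config = sr_config
        self.efs_params = efs_params

    def fit(self, seed: int | None = None) -> EvaluationReport:
        return nested_cv_evaluate(
            self.matrix,
            self.labels,
            self.signature_source,
            algorithms=self.algorithms,
            k_outer=self.k_outer,
            k_inner=self.k_inner,
            seed=seed,
            sr_config=self.sr_config,
            efs_params=self.efs_params,
        )
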