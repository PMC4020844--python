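"""Base gene-scoring and ranking algorithms.

These are the individual feature selection methods that can be combined by
the ensemble pipeline: Golub's signal-to-noise ratio, linear-SVM weights,
nearest-shrunken-centroid (PAM) scores, SVM-based recursive feature
elimination, and three statistical tests (t-test, Wilcoxon rank-sum,
permutation test).  Each produces either a per-gene informativeness score
(higher = more informative) or directly a total ranking of all genes.

Determinism: ties are always broken by lexicographic gene ID and every
stochastic step takes an explicit seed, so rankings are bit-for-bit
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC

from .data import CompoundLabelSet, FoldChangeMatrix

#: score assigned to genes that had to be excluded from a model-based ranker
#: (zero variance on the training compounds); strictly below any |weight|
_DROPPED_SCORE = -1.0


@dataclass
class ClassMeanStats:
    """Per-gene class means and sample SDs of the fold-changes."""

    mu1: pd.Series
    mu2: pd.Series
    sd1: pd.Series
    sd2: pd.Series
    n1: int
    n2: int


@dataclass
class GeneScores:
    """Per-gene informativeness scores (higher = more informative).

    ``signed`` keeps the raw signed statistic where one exists (e.g. the
    Golub ratio r_g, needed by the weighted-voting classifier).
    """

    scores: pd.Series
    method: str
    signed: pd.Series | None = None
    flags: dict = field(default_factory=dict)


@dataclass
class GeneRanking:
    """Total ordering of the gene universe; rank 1 = most informative."""

    order: list[str]
    method: str = ""

    def __post_init__(self) -> None:
        self.order = list(self.order)
        if len(set(self.order)) != len(self.order):
            raise ValueError("ranking contains duplicate genes")

    def __len__(self) -> int:
        return len(self.order)

    @property
    def ranks(self) -> pd.Series:
        return pd.Series(
            np.arange(1, len(self.order) + 1), index=self.order, name="rank"
        )

    def top(self, k: int) -> list[str]:
        return self.order[:k]


def scores_to_ranking(scores: GeneScores | pd.Series) -> GeneRanking:
    """Sort descending by score; ties broken by lexicographic gene ID."""
    if isinstance(scores, GeneScores):
        series, method = scores.scores, scores.method
    else:
        series, method = scores, ""
    if not np.isfinite(series.to_numpy()).all():
        raise ValueError("scores must be finite")
    frame = pd.DataFrame({"score": series})
    frame["gene"] = frame.index
    frame = frame.sort_values(["score", "gene"], ascending=[False, True])
    return GeneRanking(list(frame.index), method=method)


def _two_class_blocks(
    matrix: FoldChangeMatrix, labels: CompoundLabelSet
) -> tuple[np.ndarray, np.ndarray, list[str], np.ndarray]:
    """(X1, X2, analysis compound ids, y) with X_j genes x n_j."""
    ids, y = labels.analysis_view(matrix.compound_ids)
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError("need at least 2 compounds in each class for ranking")
    values = matrix.data.loc[:, ids].to_numpy()
    return values[:, y == 1], values[:, y == 0], ids, y


def class_mean_stats(
    matrix: FoldChangeMatrix, labels: CompoundLabelSet
) -> ClassMeanStats:
    x1, x2, _, _ = _two_class_blocks(matrix, labels)
    index = matrix.data.index
    return ClassMeanStats(
        mu1=pd.Series(x1.mean(axis=1), index=index),
        mu2=pd.Series(x2.mean(axis=1), index=index),
        sd1=pd.Series(x1.std(axis=1, ddof=1), index=index),
        sd2=pd.Series(x2.std(axis=1, ddof=1), index=index),
        n1=x1.shape[1],
        n2=x2.shape[1],
    )


def golub_scores(matrix: FoldChangeMatrix, labels: CompoundLabelSet) -> GeneScores:
    """Golub signal-to-noise ratio r_g = (mu1 - mu2) / (sd1 + sd2).

    The informativeness score is |r_g| (direction-agnostic); the signed
    ratio is retained for weighted voting.  Genes with sd1 + sd2 = 0 get
    score 0 if the class means agree, otherwise one more than the largest
    finite score (a perfect separator with zero within-class spread); such
    genes are flagged.
    """
    st = class_mean_stats(matrix, labels)
    denom = (st.sd1 + st.sd2).to_numpy()
    diff = (st.mu1 - st.mu2).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, diff / np.where(denom > 0, denom, 1.0), 0.0)
    score = np.abs(r)
    degenerate = (denom == 0) & (diff != 0)
    flags = {}
    if degenerate.any():
        top = score[~degenerate].max() if (~degenerate).any() else 0.0
        score[degenerate] = top + 1.0
        r[degenerate] = np.sign(diff[degenerate]) * (top + 1.0)
        flags["zero_denominator_genes"] = list(matrix.data.index[degenerate])
    index = matrix.data.index
    return GeneScores(
        scores=pd.Series(score, index=index),
        signed=pd.Series(r, index=index),
        method="golub",
        flags=flags,
    )


def stat_test_scores(
    matrix: FoldChangeMatrix,
    labels: CompoundLabelSet,
    method: str = "t_test",
    n_perm: int = 1000,
    seed: int | None = None,
) -> GeneScores:
    """Two-sided per-gene test p-values turned into scores (score = 1 - p).

    ``method`` is one of ``t_test`` (pooled-variance two-sample t),
    ``wilcoxon`` (rank-sum, exact for small samples without ties) or
    ``permutation`` (label permutation of |difference of class means| with
    add-one smoothing: p = (1 + #{perm >= obs}) / (1 + n_perm)).
    Constant genes get p = 1, i.e. score 0.
    """
    x1, x2, ids, y = _two_class_blocks(matrix, labels)
    if method == "t_test":
        with np.errstate(divide="ignore", invalid="ignore"):
            res = stats.ttest_ind(x1, x2, axis=1, equal_var=True)
        p = np.nan_to_num(np.asarray(res.pvalue), nan=1.0)
    elif method == "wilcoxon":
        res = stats.mannwhitneyu(x1, x2, axis=1, alternative="two-sided")
        p = np.asarray(res.pvalue)
    elif method == "permutation":
        p = _permutation_pvalues(
            matrix.data.loc[:, ids].to_numpy(), y, n_perm=n_perm, seed=seed
        )
    else:
        raise ValueError(f"unknown test method {method!r}")
    p = np.clip(p, 0.0, 1.0)
    return GeneScores(
        scores=pd.Series(1.0 - p, index=matrix.data.index), method=method
    )


def _permutation_pvalues(
    values: np.ndarray, y: np.ndarray, n_perm: int, seed: int | None
) -> np.ndarray:
    rng = np.random.default_rng(seed)
    n1 = int(y.sum())
    observed = np.abs(
        values[:, y == 1].mean(axis=1) - values[:, y == 0].mean(axis=1)
    )
    count = np.zeros(values.shape[0], dtype=int)
    chunk = 200  # bounded memory at genome scale
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        stat = np.empty((values.shape[0], b))
        for j in range(b):
            perm = rng.permutation(values.shape[1])
            in1 = perm[:n1]
            in2 = perm[n1:]
            stat[:, j] = np.abs(
                values[:, in1].mean(axis=1) - values[:, in2].mean(axis=1)
            )
        count += (stat >= observed[:, None] - 1e-12).sum(axis=1)
        done += b
    return (1.0 + count) / (1.0 + n_perm)


def _zscored_design(
    matrix: FoldChangeMatrix, labels: CompoundLabelSet
) -> tuple[np.ndarray, np.ndarray, list[str], np.ndarray]:
    """Compounds x genes z-scored design for margin-based rankers.

    Zero-variance genes are excluded from the fit; a boolean mask marks the
    kept genes.  Raises on fully degenerate input.
    """
    ids, y = labels.analysis_view(matrix.compound_ids)
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError("need at least 2 compounds in each class for ranking")
    X = matrix.data.loc[:, ids].to_numpy().T  # compounds x genes
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("degenerate training data: all genes have zero variance")
    Z = (X[:, keep] - mu[keep]) / sd[keep]
    return Z, keep, ids, y


def _linear_svm_weights(Z: np.ndarray, y: np.ndarray, C: float) -> np.ndarray:
    model = SVC(kernel="linear", C=C, tol=1e-6)
    model.fit(Z, y)
    return model.coef_.ravel()


def svm_weight_scores(
    matrix: FoldChangeMatrix, labels: CompoundLabelSet, C: float = 1.0
) -> GeneScores:
    """|w_g| of a linear two-class SVM fitted on z-scored fold-changes.

    Genes constant across the training compounds cannot be z-scored and are
    assigned a score strictly below every |w| so they end up last.
    """
    Z, keep, _, y = _zscored_design(matrix, labels)
    w = _linear_svm_weights(Z, y, C)
    score = np.full(matrix.shape[0], _DROPPED_SCORE)
    score[keep] = np.abs(w)
    flags = {}
    if (~keep).any():
        flags["zero_variance_genes"] = list(matrix.data.index[~keep])
    return GeneScores(
        scores=pd.Series(score, index=matrix.data.index), method="svm", flags=flags
    )


def _pam_statistics(
    x1: np.ndarray, x2: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Unshrunken PAM statistics d_gk for the two classes.

    d_gk = (xbar_gk - xbar_g) / (m_k (s_g + s0)) with s_g the pooled
    within-class SD, s0 the median of the s_g, and m_k = sqrt(1/n_k - 1/n)
    (the standard error factor of xbar_k - xbar under equal variance).
    """
    n1, n2 = x1.shape[1], x2.shape[1]
    n = n1 + n2
    grand = (x1.sum(axis=1) + x2.sum(axis=1)) / n
    c1 = x1.mean(axis=1)
    c2 = x2.mean(axis=1)
    ss = ((x1 - c1[:, None]) ** 2).sum(axis=1) + ((x2 - c2[:, None]) ** 2).sum(axis=1)
    s = np.sqrt(ss / (n - 2))
    s0 = float(np.median(s))
    m1 = np.sqrt(1.0 / n1 - 1.0 / n)
    m2 = np.sqrt(1.0 / n2 - 1.0 / n)
    d1 = (c1 - grand) / (m1 * (s + s0))
    d2 = (c2 - grand) / (m2 * (s + s0))
    return d1, d2, s, np.full_like(s, s0)


def soft_threshold(d: np.ndarray, delta: float) -> np.ndarray:
    return np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)


def pam_scores(
    matrix: FoldChangeMatrix, labels: CompoundLabelSet, delta: float = 0.0
) -> GeneScores:
    """Nearest-shrunken-centroid score: max_k |d'_gk| after soft-thresholding."""
    x1, x2, _, _ = _two_class_blocks(matrix, labels)
    d1, d2, _, _ = _pam_statistics(x1, x2)
    score = np.maximum(
        np.abs(soft_threshold(d1, delta)), np.abs(soft_threshold(d2, delta))
    )
    return GeneScores(scores=pd.Series(score, index=matrix.data.index), method="pam")


def rfe_ranking(
    matrix: FoldChangeMatrix,
    labels: CompoundLabelSet,
    C: float = 1.0,
    drop_fraction: float = 0.1,
) -> GeneRanking:
    """SVM recursive feature elimination.

    Repeatedly fits a linear SVM on the surviving (z-scored) genes and
    removes the floor(drop_fraction x remaining) genes (at least 1) with the
    smallest |w|.  The final ranking is the reverse elimination order;
    within one batch genes are ordered by |w| descending, ties by gene ID.
    Constant genes are eliminated first (worst ranks).
    """
    if not 0.0 < drop_fraction < 1.0:
        raise ValueError("drop_fraction must be in (0, 1)")
    Z, keep, _, y = _zscored_design(matrix, labels)
    genes = np.asarray(matrix.gene_ids)
    # zero-variance genes leave the ranking immediately, worst first by ID
    eliminated: list[str] = sorted(genes[~keep], reverse=True)
    remaining = list(np.flatnonzero(keep))
    col_of = {g_idx: j for j, g_idx in enumerate(np.flatnonzero(keep))}
    while remaining:
        w = np.abs(_linear_svm_weights(Z[:, [col_of[g] for g in remaining]], y, C))
        n_drop = max(1, int(np.floor(drop_fraction * len(remaining))))
        n_drop = min(n_drop, len(remaining))
        # drop the weakest first; among equal weights drop the larger ID first
        # (two stable sorts: ID descending, then weight ascending)
        order = sorted(
            range(len(remaining)), key=lambda j: genes[remaining[j]], reverse=True
        )
        order = sorted(order, key=lambda j: w[j])
        batch = [remaining[j] for j in order[:n_drop]]
        eliminated.extend(genes[g] for g in batch)
        batch_set = set(batch)
        remaining = [g for g in remaining if g not in batch_set]
        if len(set(y)) < 2:  # pragma: no cover - guarded upstream
            break
    return GeneRanking(list(reversed(eliminated)), method="rfe")


def rank_genes(
    matrix: FoldChangeMatrix,
    labels: CompoundLabelSet,
    method: str,
    seed: int | None = None,
    **params,
) -> GeneRanking:
    """Dispatch a named ranking method and return a total GeneRanking.

    Methods: golub, t_test (alias ttest), wilcoxon, permutation, svm, pam, rfe.
    """
    method = {"ttest": "t_test"}.get(method, method)
    if method == "golub":
        return scores_to_ranking(golub_scores(matrix, labels))
    if method in ("t_test", "wilcoxon", "permutation"):
        return scores_to_ranking(
            stat_test_scores(matrix, labels, method=method, seed=seed, **params)
        )
    if method == "svm":
        return scores_to_ranking(svm_weight_scores(matrix, labels, **params))
    if method == "pam":
        return scores_to_ranking(pam_scores(matrix, labels, **params))
    if method == "rfe":
        return rfe_ranking(matrix, labels, **params)
    raise ValueError(f"unknown ranking method {method!r}")


RANKING_METHODS = ("golub", "t_test", "wilcoxon", "permutation", "svm", "pam", "rfe")
DEFAULT_ENSEMBLE = ("golub", "svm", "pam", "rfe")
STATISTICAL_ENSEMBLE = ("t_test", "wilcoxon", "permutation")
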