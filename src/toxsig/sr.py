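"""Specificity Ratio (SR) signature extraction.

Golub's signal-to-noise ratio contrasts class means, so it also selects
genes that are deregulated only in the *secondary* class.  The Specificity
Ratio instead contrasts class-wise mean *absolute* fold-changes,

    s_g = (m_1g - m_2g) / (sigma*_1g + sigma*_2g),

where m_jg = (1/n_j) sum_i |f_gi| is the mean absolute fold-change of gene g
in class j, and sigma*_jg are moderated standard deviations of the absolute
fold-changes obtained by shrinking each gene's variance toward the median
variance of its class (the shrink-t scheme):

    v*_g   = lambda * v0 + (1 - lambda) * v_g,        v0 = median_g(v_g)
    lambda = min(1,  sum_g Varhat(v_g) / sum_g (v_g - v0)^2)
    Varhat(v_g) = n / (n-1)^3 * sum_i (w_ig - wbar_g)^2,  w_ig = (x_ig - xbar_g)^2.

A large s_g means gene g is strongly deregulated (in either direction) in
the primary class but quiet in the secondary class.  Because |f| discards
the direction, a candidate gene may still be up-regulated by some primary
compounds and down-regulated by others; a per-gene ROC filter removes such
inconsistent genes: q_g = max(AUC_g, 1 - AUC_g) of the raw fold-changes
against the class labels must reach a cutoff theta (default 0.9).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import CompoundLabelSet, FoldChangeMatrix, Signature


@dataclass
class ClassAbsStats:
    """Per-gene mean and sample variance of |fold-change|, per class."""

    mean_abs_primary: pd.Series
    mean_abs_secondary: pd.Series
    var_abs_primary: pd.Series
    var_abs_secondary: pd.Series
    n_primary: int
    n_secondary: int


@dataclass
class ShrinkageEstimate:
    """Variance shrinkage toward the median for one class.

    ``forced`` flags the n = 2 degenerate case where the variance-of-variance
    estimate needs n >= 3 and lambda is pinned at full pooling.
    """

    variances: pd.Series       # raw per-gene sample variances v_g
    target: float              # v0 = median of v_g
    pooling: float             # lambda in [0, 1]
    sd_star: pd.Series         # moderated SDs sqrt(lambda v0 + (1-lambda) v_g)
    forced: bool = False


@dataclass
class SpecificityScores:
    scores: pd.Series          # s_g, signed
    shrinkage_primary: ShrinkageEstimate
    shrinkage_secondary: ShrinkageEstimate


@dataclass
class SRConfig:
    """Preselection size and ROC-consistency cutoff for SR extraction."""

    preselect_n: int = 100
    roc_cutoff: float = 0.9

    def __post_init__(self) -> None:
        if self.preselect_n < 1:
            raise ValueError("preselect_n must be >= 1")
        if not 0.5 <= self.roc_cutoff <= 1.0:
            raise ValueError("roc_cutoff must be in [0.5, 1]")


def _abs_blocks(
    matrix: FoldChangeMatrix, labels: CompoundLabelSet
) -> tuple[np.ndarray, np.ndarray]:
    ids, y = labels.analysis_view(matrix.compound_ids)
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError("need at least 2 compounds in each class")
    values = matrix.data.loc[:, ids].to_numpy()
    return np.abs(values[:, y == 1]), np.abs(values[:, y == 0])


def mean_abs_foldchange(
    matrix: FoldChangeMatrix, labels: CompoundLabelSet
) -> ClassAbsStats:
    """Class-wise mean and sample variance (n-1) of the absolute fold-changes."""
    a1, a2 = _abs_blocks(matrix, labels)
    index = matrix.data.index
    return ClassAbsStats(
        mean_abs_primary=pd.Series(a1.mean(axis=1), index=index),
        mean_abs_secondary=pd.Series(a2.mean(axis=1), index=index),
        var_abs_primary=pd.Series(a1.var(axis=1, ddof=1), index=index),
        var_abs_secondary=pd.Series(a2.var(axis=1, ddof=1), index=index),
        n_primary=a1.shape[1],
        n_secondary=a2.shape[1],
    )


def shrink_standard_deviations(abs_fc: pd.DataFrame) -> ShrinkageEstimate:
    """Moderated SDs for one class of absolute fold-changes (genes x compounds).

    With only n = 2 compounds the variance of the variance cannot be
    estimated and lambda is forced to 1 (full pooling to the median).
    """
    x = abs_fc.to_numpy(dtype=float)
    n = x.shape[1]
    if n < 2:
        raise ValueError("need at least 2 compounds per class")
    v = x.var(axis=1, ddof=1)
    v0 = float(np.median(v))
    forced = n < 3
    if forced:
        lam = 1.0
    else:
        w = (x - x.mean(axis=1, keepdims=True)) ** 2
        var_hat = n / (n - 1) ** 3 * ((w - w.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        denom = float(((v - v0) ** 2).sum())
        lam = 1.0 if denom == 0.0 else min(1.0, float(var_hat.sum()) / denom)
    sd_star = np.sqrt(lam * v0 + (1.0 - lam) * v)
    return ShrinkageEstimate(
        variances=pd.Series(v, index=abs_fc.index),
        target=v0,
        pooling=lam,
        sd_star=pd.Series(sd_star, index=abs_fc.index),
        forced=forced,
    )


def specificity_scores(
    matrix: FoldChangeMatrix, labels: CompoundLabelSet, pooled: bool = False
) -> SpecificityScores:
    """s_g = (m_1g - m_2g) / (sigma*_1g + sigma*_2g).

    Shrinkage is estimated independently per class by default; ``pooled``
    estimates a single lambda/target from both classes' absolute
    fold-changes jointly (same moderated SD structure, shared target).
    """
    ids, y = labels.analysis_view(matrix.compound_ids)
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError("need at least 2 compounds in each class")
    abs_all = matrix.data.loc[:, ids].abs()
    abs1 = abs_all.loc[:, np.asarray(y) == 1]
    abs2 = abs_all.loc[:, np.asarray(y) == 0]
    if pooled:
        centred = pd.concat(
            [abs1.sub(abs1.mean(axis=1), axis=0), abs2.sub(abs2.mean(axis=1), axis=0)],
            axis=1,
        )
        shared = shrink_standard_deviations(centred)
        sh1 = sh2 = shared
    else:
        sh1 = shrink_standard_deviations(abs1)
        sh2 = shrink_standard_deviations(abs2)
    denom = sh1.sd_star + sh2.sd_star
    if (denom == 0.0).any():
        raise ValueError("degenerate variance structure: sigma*_1 + sigma*_2 = 0")
    s = (abs1.mean(axis=1) - abs2.mean(axis=1)) / denom
    return SpecificityScores(scores=s, shrinkage_primary=sh1, shrinkage_secondary=sh2)


def gene_roc_scores(
    matrix: FoldChangeMatrix, labels: CompoundLabelSet
) -> pd.DataFrame:
    """Per-gene pair-counting AUC of fold-changes against the class labels.

    AUC_g = (#{(i in c1, i' in c2): f_gi > f_gi'} + 0.5 #ties) / (n1 n2),
    computed via midranks.  Returns a frame with columns ``auc`` (raw, for
    the regular labels) and ``q`` = max(AUC, 1 - AUC), the score under the
    better of regular/inverted labels.
    """
    ids, y = labels.analysis_view(matrix.compound_ids)
    n1 = int(y.sum())
    n2 = int(len(y) - n1)
    if n1 < 1 or n2 < 1:
        raise ValueError("need at least 1 compound in each class")
    values = matrix.data.loc[:, ids].to_numpy()
    ranks = stats.rankdata(values, axis=1)
    r1 = ranks[:, np.asarray(y) == 1].sum(axis=1)
    auc = (r1 - n1 * (n1 + 1) / 2.0) / (n1 * n2)
    frame = pd.DataFrame({"auc": auc}, index=matrix.data.index)
    frame["q"] = np.maximum(frame["auc"], 1.0 - frame["auc"])
    return frame


def extract_sr_signature(
    matrix: FoldChangeMatrix,
    labels: CompoundLabelSet,
    config: SRConfig | None = None,
    pooled_shrinkage: bool = False,
) -> Signature:
    """Rank by s_g, preselect the top genes, keep the ROC-consistent ones.

    The returned signature is ordered by descending s_g (signed: the method
    deliberately prefers primary-class-specific deregulation) and carries
    the fitted lambda per class, the cutoff and the preselection size in its
    provenance.
    """
    config = config or SRConfig()
    if config.preselect_n > matrix.shape[0]:
        raise ValueError("preselect_n exceeds the number of genes")
    spec = specificity_scores(matrix, labels, pooled=pooled_shrinkage)
    order = pd.DataFrame({"s": spec.scores})
    order["gene"] = order.index
    order = order.sort_values(["s", "gene"], ascending=[False, True])
    preselected = order.head(config.preselect_n)
    roc = gene_roc_scores(matrix, labels)
    kept = preselected[roc.loc[preselected.index, "q"] >= config.roc_cutoff]
    if kept.empty:
        raise ValueError(
            "no gene passed the ROC-consistency filter; lower roc_cutoff"
        )
    provenance = {
        "method": "sr",
        "preselect_n": config.preselect_n,
        "roc_cutoff": config.roc_cutoff,
        "pooled_shrinkage": pooled_shrinkage,
        "lambda_primary": spec.shrinkage_primary.pooling,
        "lambda_secondary": spec.shrinkage_secondary.pooling,
        "primary_class": labels.primary,
        "secondary_class": labels.secondary,
    }
    return Signature(list(kept.index), kept["s"].to_numpy(), provenance=provenance)


@dataclass
class SRResults:
    """Fitted Specificity Ratio model: scores, filter diagnostics, signature."""

    signature: Signature
    scores: SpecificityScores
    roc: pd.DataFrame
    config: SRConfig

    def summary(self) -> str:
        sig = self.signature
        lines = [
            "Specificity Ratio signature extraction",
            "=" * 54,
            f"preselected genes:      {self.config.preselect_n}",
            f"ROC cutoff theta:       {self.config.roc_cutoff}",
            f"lambda (primary class): {self.scores.shrinkage_primary.pooling:.4f}",
            f"lambda (secondary):     {self.scores.shrinkage_secondary.pooling:.4f}",
            f"signature size:         {len(sig)}",
            "",
            "rank  gene            s_g        q_g",
            "-" * 54,
        ]
        for rank, gene, s in zip(sig.ranks, sig.gene_ids, sig.scores):
            lines.append(
                f"{rank:>4}  {gene:<14}  {s:>8.4f}  {self.roc.loc[gene, 'q']:>6.3f}"
            )
        return "\n".join(lines)


class SpecificityRatio:
    """Model-style interface: configure on data, ``fit()`` returns SRResults."""

    def __init__(
        self,
        matrix: FoldChangeMatrix,
        labels: CompoundLabelSet,
        preselect_n: int = 100,
        roc_cutoff: float = 0.9,
        pooled_shrinkage: bool = False,
    ):
        self.matrix = matrix
        self.labels = labels
        self.config = SRConfig(preselect_n=preselect_n, roc_cutoff=roc_cutoff)
        self.pooled_shrinkage = pooled_shrinkage

    def fit(self) -> SRResults:
        signature = extract_sr_signature(
            self.matrix, self.labels, self.config, self.pooled_shrinkage
        )
        spec = specificity_scores(self.matrix, self.labels, pooled=self.pooled_shrinkage)
        roc = gene_roc_scores(self.matrix, self.labels)
        return SRResults(signature=signature, scores=spec, roc=roc, config=self.config)
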