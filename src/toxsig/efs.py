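"""Ensemble Feature Selection (EFS).

The pipeline draws B stratified 90% subsamples ("bootstraps") of the
training compounds, applies each configured ranking method to every
subsample, and merges the resulting M x B gene rankings by summing ranks
(genes sorted ascending by rank-sum give the consensus ranking).  The
signature size is chosen by evaluating, for a grid of candidate sizes, a
fast KNN classifier trained on each per-(method, bootstrap) signature and
scored on the held-out 10% out-of-bag compounds; a cubic smoothing spline
through mean out-of-bag ROC versus size is maximized analytically.

The default method ensemble is {golub, svm, pam, rfe}; the statistical
tests ensemble or a combination can be selected instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PPoly, make_smoothing_spline
from sklearn.metrics import roc_auc_score
from sklearn.neighbors import KNeighborsClassifier

from . import stability
from .data import (
    CompoundLabelSet,
    FoldChangeMatrix,
    Signature,
    safe_zscore_features,
)
from .rankers import DEFAULT_ENSEMBLE, GeneRanking, rank_genes


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class BootstrapPlan:
    """B stratified without-replacement subsamples of the training compounds."""

    resamples: list[tuple[list[str], list[str]]]  # (in_bag, out_of_bag)
    seed: int | None
    in_frac: float
    class_counts: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.resamples)


def make_bootstraps(
    labels: CompoundLabelSet,
    training_ids: Sequence[str],
    B: int = 25,
    in_frac: float = 0.9,
    seed: int | None = None,
) -> BootstrapPlan:
    """Draw B stratified in-bag/out-of-bag splits of the training compounds.

    Per-class in-bag counts are round(in_frac * class size) (half-up),
    adjusted by +-1 to hit the global count round(in_frac * n_train).  Each
    class must keep >= 2 in-bag and >= 1 out-of-bag compounds.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if not 0.0 < in_frac < 1.0:
        raise ValueError("in_frac must be in (0, 1)")
    ids, y = labels.analysis_view(training_ids)
    by_class = {1: [c for c, yi in zip(ids, y) if yi == 1],
                0: [c for c, yi in zip(ids, y) if yi == 0]}
    total_target = _round_half_up(in_frac * len(ids))
    counts = {cls: _round_half_up(in_frac * len(members))
              for cls, members in by_class.items()}
    # reconcile per-class rounding with the global target
    while sum(counts.values()) > total_target:
        cls = max(counts, key=lambda c: (counts[c], c))
        counts[cls] -= 1
    while sum(counts.values()) < total_target:
        cls = min(counts, key=lambda c: (counts[c] - len(by_class[c]), c))
        counts[cls] += 1
    for cls, members in by_class.items():
        if counts[cls] < 2 or counts[cls] > len(members) - 1:
            raise ValueError(
                "infeasible stratified subsampling: a class would keep "
                f"{counts[cls]} of {len(members)} compounds in-bag; "
                "use a smaller in_frac"
            )
    rng = np.random.default_rng(seed)
    resamples = []
    for _ in range(B):
        in_bag: list[str] = []
        for cls in (1, 0):
            members = by_class[cls]
            chosen = rng.choice(len(members), size=counts[cls], replace=False)
            in_bag.extend(members[i] for i in sorted(chosen))
        in_set = set(in_bag)
        out_of_bag = [c for c in ids if c not in in_set]
        resamples.append((sorted(in_bag, key=ids.index), out_of_bag))
    class_counts = {
        labels.primary: counts[1],
        labels.secondary: counts[0],
    }
    return BootstrapPlan(resamples, seed=seed, in_frac=in_frac, class_counts=class_counts)


def default_size_grid(
    min_size: int = 2, max_size: int = 100, points: int = 11
) -> list[int]:
    """Linearly spaced candidate signature sizes, rounded and deduplicated."""
    if points < 1:
        raise ValueError("points must be >= 1")
    if min_size == max_size:
        return [int(min_size)]
    grid = np.round(np.linspace(min_size, max_size, points)).astype(int)
    return sorted(set(int(s) for s in grid))


@dataclass
class SizePerformanceCurve:
    """Out-of-bag ROC per (method, bootstrap, size) with per-size aggregates.

    ``cells`` is tidy with columns method, bootstrap, size, roc (NaN where
    the out-of-bag set contained a single class); aggregation excludes
    missing cells.
    """

    cells: pd.DataFrame

    def aggregate(self) -> pd.DataFrame:
        grouped = self.cells.dropna(subset=["roc"]).groupby("size")["roc"]
        out = grouped.agg(mean_roc="mean", sd_roc="std", n_cells="count")
        return out.reset_index()

    def by_method(self) -> pd.DataFrame:
        grouped = (
            self.cells.dropna(subset=["roc"]).groupby(["method", "size"])["roc"]
        )
        return grouped.agg(mean_roc="mean", sd_roc="std").reset_index()


def bootstrap_rankings(
    matrix: FoldChangeMatrix,
    labels: CompoundLabelSet,
    plan: BootstrapPlan,
    methods: Sequence[str] = DEFAULT_ENSEMBLE,
    seed: int | None = None,
    **ranker_params,
) -> dict[tuple[str, int], GeneRanking]:
    """One total gene ranking per (method, bootstrap), on in-bag compounds only."""
    out: dict[tuple[str, int], GeneRanking] = {}
    streams = np.random.SeedSequence(seed).spawn(len(methods) * len(plan))
    i = 0
    for method in methods:
        for b, (in_bag, _) in enumerate(plan.resamples):
            sub = matrix.subset_compounds(in_bag)
            child_seed = int(streams[i].generate_state(1)[0] % (2**31))
            i += 1
            out[(method, b)] = rank_genes(
                sub, labels, method, seed=child_seed, **ranker_params
            )
    return out


def evaluate_signature_sizes(
    matrix: FoldChangeMatrix,
    labels: CompoundLabelSet,
    plan: BootstrapPlan,
    rankings: dict[tuple[str, int], GeneRanking],
    grid: Sequence[int],
    knn_k: int = 3,
) -> SizePerformanceCurve:
    """Out-of-bag KNN ROC for every (method, bootstrap, size) combination.

    For each cell the top-``size`` genes of the in-bag ranking are z-scored
    on the in-bag compounds, a KNN (continuous output: fraction of primary
    neighbors, x/k) is trained in-bag and scored on the out-of-bag
    compounds against their labels.
    """
    rows = []
    for (method, b), ranking in rankings.items():
        in_bag, out_of_bag = plan.resamples[b]
        oob_ids, oob_y = labels.analysis_view(out_of_bag)
        in_ids, in_y = labels.analysis_view(in_bag)
        for size in grid:
            if len(set(oob_y)) < 2:
                rows.append({"method": method, "bootstrap": b,
                             "size": int(size), "roc": np.nan})
                continue
            genes = ranking.top(int(size))
            feats, _ = safe_zscore_features(matrix, genes, in_ids)
            k = min(knn_k, len(in_ids))
            model = KNeighborsClassifier(n_neighbors=k)
            model.fit(feats.features.to_numpy(), in_y)
            scores = model.predict_proba(
                feats.transform(matrix, oob_ids).to_numpy()
            )[:, list(model.classes_).index(1)]
            rows.append({
                "method": method,
                "bootstrap": b,
                "size": int(size),
                "roc": float(roc_auc_score(oob_y, scores)),
            })
    return SizePerformanceCurve(pd.DataFrame(rows))


def optimal_size(curve: SizePerformanceCurve | pd.DataFrame) -> int:
    """Signature size maximizing a GCV cubic smoothing spline of mean ROC.

    The spline is fitted to (size, mean out-of-bag ROC); its maximizer over
    the grid range is located from the derivative roots together with a
    unit-step integer grid and returned as the nearest integer.  Ties (flat
    or monotone-plateau splines) resolve to the smallest size.  With fewer
    than 4 defined sizes the argmax of the raw means is returned.
    """
    agg = curve.aggregate() if isinstance(curve, SizePerformanceCurve) else curve
    agg = agg.dropna(subset=["mean_roc"]).sort_values("size")
    sizes = agg["size"].to_numpy(dtype=float)
    means = agg["mean_roc"].to_numpy(dtype=float)
    if len(sizes) == 0:
        raise ValueError("no defined sizes in the performance curve")
    if len(sizes) < 4:
        best = np.flatnonzero(means >= means.max() - 1e-12)[0]
        return int(sizes[best])
    try:
        spline = make_smoothing_spline(sizes, means)
    except ValueError:
        # GCV spline needs more support points than some small grids offer
        best = np.flatnonzero(means >= means.max() - 1e-12)[0]
        return int(sizes[best])
    lo, hi = float(sizes[0]), float(sizes[-1])
    candidates = list(np.arange(math.ceil(lo), math.floor(hi) + 1, dtype=float))
    candidates += [lo, hi]
    try:
        dpoly = PPoly.from_spline(spline.derivative())
        roots = dpoly.roots(extrapolate=False)
        candidates += [float(r) for r in np.atleast_1d(roots)
                       if np.isfinite(r) and lo <= r <= hi]
    except Exception:  # degenerate spline; integer grid still covers the range
        pass
    candidates = sorted(set(candidates))
    values = spline(candidates)
    best_val = float(np.max(values))
    best_x = min(x for x, v in zip(candidates, values) if v >= best_val - 1e-10)
    return int(np.clip(_round_half_up(best_x), lo, hi))


@dataclass
class ConsensusRanking:
    """Rank-sum aggregation of many total rankings over one gene universe."""

    rank_sums: pd.Series
    order: list[str]
    n_rankings: int

    def top(self, k: int) -> list[str]:
        return self.order[:k]


def merge_rankings(rankings: Sequence[GeneRanking]) -> ConsensusRanking:
    """Sum ranks across rankings; sort ascending, ties by gene ID."""
    if not rankings:
        raise ValueError("need at least one ranking")
    universe = set(rankings[0].order)
    for r in rankings[1:]:
        if set(r.order) != universe:
            diff = sorted(universe.symmetric_difference(set(r.order)))
            raise ValueError(f"rankings cover different gene universes: {diff[:10]}")
    sums = sum((r.ranks for r in rankings), start=pd.Series(0, index=sorted(universe)))
    frame = pd.DataFrame({"rank_sum": sums})
    frame["gene"] = frame.index
    frame = frame.sort_values(["rank_sum", "gene"], ascending=[True, True])
    return ConsensusRanking(
        rank_sums=sums.sort_index(), order=list(frame.index), n_rankings=len(rankings)
    )


@dataclass
class EFSResults:
    """Fitted EFS pipeline: consensus ranking, size curve, final signature."""

    signature: Signature
    consensus: ConsensusRanking
    optimal_size: int
    curve: SizePerformanceCurve
    stability: pd.DataFrame           # method, size, mean_ki
    plan: BootstrapPlan
    provenance: dict

    def summary(self) -> str:
        agg = self.curve.aggregate()
        lines = [
            "Ensemble Feature Selection",
            "=" * 54,
            f"methods:          {', '.join(self.provenance['methods'])}",
            f"bootstraps:       {len(self.plan)} @ in-bag fraction "
            f"{self.plan.in_frac}",
            f"seed:             {self.provenance['seed']}",
            f"optimal size k*:  {self.optimal_size}",
            "",
            "size   mean OOB ROC   sd",
            "-" * 30,
        ]
        for _, row in agg.iterrows():
            sd = 0.0 if np.isnan(row["sd_roc"]) else row["sd_roc"]
            lines.append(f"{int(row['size']):>4}   {row['mean_roc']:>10.3f}   {sd:.3f}")
        lines += ["", "final signature (rank, gene, rank-sum):", "-" * 40]
        for rank, gene, s in zip(
            self.signature.ranks, self.signature.gene_ids, self.signature.scores
        ):
            lines.append(f"{rank:>4}  {gene:<16} {s:>10.0f}")
        return "\n".join(lines)


def run_efs(
    matrix: FoldChangeMatrix,
    labels: CompoundLabelSet,
    training_ids: Sequence[str] | None = None,
    methods: Sequence[str] = DEFAULT_ENSEMBLE,
    B: int = 25,
    in_frac: float = 0.9,
    grid: Sequence[int] | None = None,
    knn_k: int = 3,
    seed: int | None = None,
    **ranker_params,
) -> EFSResults:
    """Full EFS pipeline on the training compounds.

    Draws the bootstrap plan, ranks genes per (method, bootstrap), evaluates
    the size grid on out-of-bag compounds, picks the optimal size k* via the
    smoothing spline, merges all M x B rankings into the consensus, and
    returns the top-k* consensus genes as the final signature (scored by
    rank-sum; smaller is better).  Per-method stability (mean Kuncheva index
    of top-k sets across bootstraps) is reported for each grid size.
    """
    training_ids = list(training_ids) if training_ids is not None else matrix.compound_ids
    grid = list(grid) if grid is not None else default_size_grid()
    max_grid = max(grid)
    if max_grid > matrix.shape[0]:
        raise ValueError("size grid exceeds the number of genes")
    plan = make_bootstraps(labels, training_ids, B=B, in_frac=in_frac, seed=seed)
    rankings = bootstrap_rankings(
        matrix, labels, plan, methods=methods, seed=seed, **ranker_params
    )
    curve = evaluate_signature_sizes(matrix, labels, plan, rankings, grid, knn_k=knn_k)
    k_star = optimal_size(curve)
    consensus = merge_rankings(list(rankings.values()))
    top = consensus.top(k_star)
    by_method = {
        m: [rankings[(m, b)] for b in range(len(plan))] for m in methods
    }
    stab = stability.stability_curve(by_method, grid, n=matrix.shape[0])
    provenance = {
        "method": "efs",
        "methods": list(methods),
        "B": B,
        "in_frac": in_frac,
        "grid": [int(s) for s in grid],
        "knn_k": knn_k,
        "seed": seed,
        "optimal_size": int(k_star),
        "primary_class": labels.primary,
        "secondary_class": labels.secondary,
    }
    signature = Signature(
        top,
        consensus.rank_sums.loc[top].to_numpy(dtype=float),
        provenance=provenance,
    )
    return EFSResults(
        signature=signature,
        consensus=consensus,
        optimal_size=int(k_star),
        curve=curve,
        stability=stab,
        plan=plan,
        provenance=provenance,
    )


class EnsembleFeatureSelection:
    """Model-style interface: configure on data, ``fit(seed)`` returns EFSResults."""

    def __init__(
        self,
        matrix: FoldChangeMatrix,
        labels: CompoundLabelSet,
        methods: Sequence[str] = DEFAULT_ENSEMBLE,
        n_bootstraps: int = 25,
        in_frac: float = 0.9,
        grid: Sequence[int] | None = None,
        knn_k: int = 3,
        training_ids: Sequence[str] | None = None,
        **ranker_params,
    ):
        self.matrix = matrix
        self.labels = labels
        self.methods = tuple(methods)
        self.n_bootstraps = n_bootstraps
        self.in_frac = in_frac
        self.grid = list(grid) if grid is not None else None
        self.knn_k = knn_k
        self.training_ids = list(training_ids) if training_ids is not None else None
        self.ranker_params = ranker_params

    def fit(self, seed: int | None = None) -> EFSResults:
        return run_efs(
            self.matrix,
            self.labels,
            training_ids=self.training_ids,
            methods=self.methods,
            B=self.n_bootstraps,
            in_frac=self.in_frac,
            grid=self.grid,
            knn_k=self.knn_k,
            seed=seed,
            **self.ranker_params,
        )
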