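"""Synthetic compound-treatment fold-change data with planted structure.

The generator emulates the shape of a short-term rodent toxicogenomics
study: ~9 primary-class (e.g. NGC) and ~11 secondary-class (e.g. NC)
compounds, thousands of genes, and several planted gene populations:

* ``primary_specific`` - deregulated (one fixed sign and magnitude per
  gene) in every primary compound, background noise in secondary ones;
  these are the genes a signature should recover;
* ``secondary_specific`` - the mirrored confounders, deregulated only in
  the secondary class (a direction-blind ranking like |Golub| admits
  them; the Specificity Ratio should not);
* ``shared`` - deregulated equally in both classes (uninformative);
* ``inconsistent`` - strong effect in the primary class but with a fresh
  random sign per compound (caught by the per-gene ROC filter);
* ``null`` - i.i.d. background noise everywhere.

Per-gene effect magnitudes are drawn once from U(effect_low, effect_high)
log2 units; per-compound measurement noise is Normal(0, noise_sd) on
affected cells and Normal(0, background_sd) elsewhere.  Everything is
deterministic under the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .data import (
    CompoundLabelSet,
    ExpressionDesign,
    FoldChangeMatrix,
    Signature,
)

ROLES = ("primary_specific", "secondary_specific", "shared", "inconsistent", "null")


@dataclass
class SimulationConfig:
    """Study-shape parameters of the synthetic dataset (defaults mirror the
    9-vs-11 compound setting with 50 planted primary-specific genes,
    effects ~ U(1, 2) log2 and noise SD 0.3)."""

    n_genes: int = 5000
    n_primary: int = 9
    n_secondary: int = 11
    n_primary_specific: int = 50
    n_secondary_specific: int = 10
    n_shared: int = 25
    n_inconsistent: int = 25
    effect_low: float = 1.0
    effect_high: float = 2.0
    noise_sd: float = 0.3
    background_sd: float = 0.3
    primary_class: str = "NGC"
    secondary_class: str = "NC"
    seed: int | None = None

    def __post_init__(self) -> None:
        planted = (
            self.n_primary_specific + self.n_secondary_specific
            + self.n_shared + self.n_inconsistent
        )
        if planted > self.n_genes:
            raise ValueError("planted gene sets exceed n_genes")
        if self.noise_sd <= 0 or self.background_sd <= 0:
            raise ValueError("noise SDs must be > 0")
        if self.effect_low < 0 or self.effect_high < self.effect_low:
            raise ValueError("need 0 <= effect_low <= effect_high")
        if self.n_primary < 2 or self.n_secondary < 2:
            raise ValueError("need at least 2 compounds per class")


@dataclass
class GroundTruth:
    """Planted role and signed effect of every gene."""

    roles: dict[str, str]
    effects: dict[str, float]  # 0.0 for null genes; per-compound signs for
                               # inconsistent genes are not recorded

    def genes_with_role(self, role: str) -> set[str]:
        return {g for g, r in self.roles.items() if r == role}


def simulate_tox_dataset(
    config: SimulationConfig | None = None, seed: int | None = None
) -> tuple[FoldChangeMatrix, CompoundLabelSet, GroundTruth]:
    """Generate (fold-change matrix, labels, ground truth) per the config."""
    config = config or SimulationConfig()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    G = config.n_genes
    width = len(str(G))
    genes = [f"g{i + 1:0{width}d}" for i in range(G)]
    compounds = (
        [f"P{i + 1:02d}" for i in range(config.n_primary)]
        + [f"S{i + 1:02d}" for i in range(config.n_secondary)]
    )
    labels = CompoundLabelSet(
        {
            **{c: config.primary_class for c in compounds[: config.n_primary]},
            **{c: config.secondary_class for c in compounds[config.n_primary:]},
        },
        primary=config.primary_class,
        secondary=config.secondary_class,
    )
    # scatter the planted roles over random gene positions
    perm = rng.permutation(G)
    blocks = {
        "primary_specific": config.n_primary_specific,
        "secondary_specific": config.n_secondary_specific,
        "shared": config.n_shared,
        "inconsistent": config.n_inconsistent,
    }
    roles = {g: "null" for g in genes}
    cursor = 0
    members: dict[str, list[int]] = {}
    for role, count in blocks.items():
        idx = perm[cursor: cursor + count]
        members[role] = list(idx)
        for i in idx:
            roles[genes[i]] = role
        cursor += count

    n1, n2 = config.n_primary, config.n_secondary
    values = rng.normal(0.0, config.background_sd, size=(G, n1 + n2))
    effects = {g: 0.0 for g in genes}

    def draw_effects(count: int) -> np.ndarray:
        signs = rng.choice([-1.0, 1.0], size=count)
        mags = rng.uniform(config.effect_low, config.effect_high, size=count)
        return signs * mags

    idx = np.asarray(members["primary_specific"], dtype=int)
    if len(idx):
        eff = draw_effects(len(idx))
        values[idx, :n1] = eff[:, None] + rng.normal(0, config.noise_sd, (len(idx), n1))
        for i, e in zip(idx, eff):
            effects[genes[i]] = float(e)

    idx = np.asarray(members["secondary_specific"], dtype=int)
    if len(idx):
        eff = draw_effects(len(idx))
        values[idx, n1:] = eff[:, None] + rng.normal(0, config.noise_sd, (len(idx), n2))
        for i, e in zip(idx, eff):
            effects[genes[i]] = float(e)

    idx = np.asarray(members["shared"], dtype=int)
    if len(idx):
        eff = draw_effects(len(idx))
        values[idx, :] = eff[:, None] + rng.normal(
            0, config.noise_sd, (len(idx), n1 + n2)
        )
        for i, e in zip(idx, eff):
            effects[genes[i]] = float(e)

    idx = np.asarray(members["inconsistent"], dtype=int)
    if len(idx):
        mags = rng.uniform(config.effect_low, config.effect_high, size=len(idx))
        # decoys must actually mix directions: redraw near-constant sign
        # patterns so the planted "inconsistent" role is guaranteed
        min_minority = 2 if n1 >= 4 else 1
        signs = rng.choice([-1.0, 1.0], size=(len(idx), n1))
        for row in range(len(idx)):
            while min((signs[row] > 0).sum(), (signs[row] < 0).sum()) < min_minority:
                signs[row] = rng.choice([-1.0, 1.0], size=n1)
        values[idx, :n1] = signs * mags[:, None] + rng.normal(
            0, config.noise_sd, (len(idx), n1)
        )
        for i, m in zip(idx, mags):
            effects[genes[i]] = float(m)

    matrix = FoldChangeMatrix.from_arrays(values, genes, compounds)
    truth = GroundTruth(roles=roles, effects=effects)
    return matrix, labels, truth


def simulate_expression_design(
    config: SimulationConfig | None = None,
    seed: int | None = None,
    n_replicates: int = 3,
    replicate_sd: float = 0.25,
    baseline_mean: float = 8.0,
    baseline_sd: float = 1.5,
) -> tuple[ExpressionDesign, CompoundLabelSet, GroundTruth]:
    """Expression-level variant: treated/control replicate samples per compound.

    Per-gene baselines are drawn once; control samples scatter around the
    baseline and treated samples around baseline + planted fold-change, so
    averaging replicates and differencing recovers (noisily) the planted
    fold-change matrix.  Exists to exercise the design -> fold-change path.
    """
    config = config or SimulationConfig()
    if seed is None:
        seed = config.seed
    matrix, labels, truth = simulate_tox_dataset(config, seed=seed)
    rng = np.random.default_rng(None if seed is None else seed + 1)
    baseline = rng.normal(baseline_mean, baseline_sd, size=matrix.shape[0])
    columns: dict[str, np.ndarray] = {}
    records = []
    fc = matrix.values
    for j, cid in enumerate(matrix.compound_ids):
        for r in range(n_replicates):
            sid = f"{cid}_ctl{r + 1}"
            columns[sid] = baseline + rng.normal(0, replicate_sd, size=len(baseline))
            records.append({"sample_id": sid, "compound_id": cid, "role": "control"})
        for r in range(n_replicates):
            sid = f"{cid}_trt{r + 1}"
            columns[sid] = (
                baseline + fc[:, j] + rng.normal(0, replicate_sd, size=len(baseline))
            )
            records.append({"sample_id": sid, "compound_id": cid, "role": "treated"})
    expression = pd.DataFrame(columns, index=matrix.gene_ids)
    samples = pd.DataFrame(records).set_index("sample_id")
    return ExpressionDesign(expression, samples), labels, truth


@dataclass
class RecoveryMetrics:
    precision: float
    recall: float
    contamination: float
    n_signature: int
    n_planted: int


def recovery_metrics(
    signature: Signature | list[str], truth: GroundTruth
) -> RecoveryMetrics:
    """Precision/recall of a signature against the planted primary-specific
    genes, plus contamination by secondary-specific confounders."""
    genes = list(signature.gene_ids) if isinstance(signature, Signature) else list(signature)
    unknown = [g for g in genes if g not in truth.roles]
    if unknown:
        raise ValueError(f"signature genes absent from ground truth: {unknown[:5]}")
    planted = truth.genes_with_role("primary_specific")
    confounders = truth.genes_with_role("secondary_specific")
    hits = sum(1 for g in genes if g in planted)
    precision = hits / len(genes) if genes else 0.0
    recall = hits / len(planted) if planted else 0.0
    contamination = (
        sum(1 for g in genes if g in confounders) / len(genes) if genes else 0.0
    )
    return RecoveryMetrics(
        precision=precision,
        recall=recall,
        contamination=contamination,
        n_signature=len(genes),
        n_planted=len(planted),
    )
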