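"""Core data containers and I/O.

The universal input of every analysis in this package is a matrix of log2
fold-changes with genes in rows and compounds (treatment groups) in columns,
``f[g, i]`` being the log2 ratio of treated vs. matched vehicle-control
expression of gene ``g`` under compound ``i``.  Compounds carry a class label
(NGC = nongenotoxic carcinogen, NC = non-carcinogen, GC = genotoxic
carcinogen, or UNDEFINED); signature extraction and classification always
contrast a *primary* class (default NGC) against a *secondary* class
(default NC).

File formats are plain TSV: fold-change matrices with a header of compound
IDs and a first column of gene IDs; label tables with columns
``compound_id`` and ``class``; signatures with columns ``rank``, ``gene_id``,
``score`` plus a JSON provenance sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

VALID_CLASSES = ("NGC", "NC", "GC", "UNDEFINED")


class FoldChangeMatrix:
    """Log2 fold-change matrix, genes in rows and compounds in columns.

    Thin wrapper around a pandas DataFrame that enforces unique IDs and
    finite numeric values.
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.duplicated().any():
            dup = data.index[data.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup}")
        if data.columns.duplicated().any():
            dup = data.columns[data.columns.duplicated()][0]
            raise ValueError(f"duplicate compound id {dup}")
        try:
            values = data.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric fold-change value: {exc}") from exc
        if not np.isfinite(values).all():
            g, c = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite fold-change for gene {data.index[g]!r}, "
                f"compound {data.columns[c]!r}"
            )
        self._data = pd.DataFrame(
            values, index=data.index.astype(str), columns=data.columns.astype(str)
        )

    @classmethod
    def from_arrays(
        cls,
        values: np.ndarray,
        gene_ids: Sequence[str],
        compound_ids: Sequence[str],
    ) -> "FoldChangeMatrix":
        return cls(pd.DataFrame(values, index=list(gene_ids), columns=list(compound_ids)))

    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def gene_ids(self) -> list[str]:
        return list(self._data.index)

    @property
    def compound_ids(self) -> list[str]:
        return list(self._data.columns)

    @property
    def values(self) -> np.ndarray:
        return self._data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self._data.shape

    def subset_compounds(self, compound_ids: Sequence[str]) -> "FoldChangeMatrix":
        missing = [c for c in compound_ids if c not in self._data.columns]
        if missing:
            raise KeyError(f"unknown compound ids: {missing}")
        return FoldChangeMatrix(self._data.loc[:, list(compound_ids)])

    def subset_genes(self, gene_ids: Sequence[str]) -> "FoldChangeMatrix":
        missing = [g for g in gene_ids if g not in self._data.index]
        if missing:
            raise KeyError(f"unknown gene ids: {missing}")
        return FoldChangeMatrix(self._data.loc[list(gene_ids), :])

    def equals(self, other: "FoldChangeMatrix") -> bool:
        return self._data.equals(other._data)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        g, c = self.shape
        return f"FoldChangeMatrix({g} genes x {c} compounds)"


def read_foldchange_matrix(path: str | Path) -> FoldChangeMatrix:
    """Read a genes x compounds TSV (header: compound IDs, first column: gene IDs)."""
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise ValueError(f"duplicate gene id {dup}")
    # a short row leaves trailing NaN cells; a long row fails in read_csv itself
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.any().any():
        g, c = np.argwhere(bad.to_numpy())[0]
        cell = raw.iat[g, c]
        where = f"row {raw.index[g]!r}, column {raw.columns[c]!r}"
        if cell is None or (isinstance(cell, float) and np.isnan(cell)):
            raise ValueError(f"ragged row: missing value at {where}")
        raise ValueError(f"non-numeric cell {cell!r} at {where}")
    return FoldChangeMatrix(numeric)


def write_foldchange_matrix(matrix: FoldChangeMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="gene_id")


class CompoundLabelSet:
    """Compound class labels plus the designated primary/secondary contrast."""

    def __init__(
        self,
        labels: Mapping[str, str],
        primary: str = "NGC",
        secondary: str = "NC",
    ):
        for cid, cls in labels.items():
            if cls not in VALID_CLASSES:
                raise ValueError(
                    f"invalid class {cls!r} for compound {cid!r}; "
                    f"expected one of {VALID_CLASSES}"
                )
        if primary == secondary:
            raise ValueError("primary and secondary class must differ")
        self.labels: dict[str, str] = dict(labels)
        self.primary = primary
        self.secondary = secondary

    def class_of(self, compound_id: str) -> str:
        try:
            return self.labels[compound_id]
        except KeyError:
            raise KeyError(f"compound {compound_id!r} has no class label") from None

    def members(self, class_label: str) -> list[str]:
        return [c for c, cls in self.labels.items() if cls == class_label]

    def analysis_view(self, compound_ids: Sequence[str]) -> tuple[list[str], np.ndarray]:
        """Restrict to primary/secondary compounds, preserving order.

        Returns the retained compound IDs and a 0/1 response vector
        (1 = primary class).  Every compound must be labelled.
        """
        ids, y = [], []
        for cid in compound_ids:
            cls = self.class_of(cid)
            if cls == self.primary:
                ids.append(cid)
                y.append(1)
            elif cls == self.secondary:
                ids.append(cid)
                y.append(0)
        return ids, np.asarray(y, dtype=int)

    def class_sizes(self, compound_ids: Sequence[str]) -> tuple[int, int]:
        """(n1, n2) = number of primary / secondary compounds among ``compound_ids``."""
        _, y = self.analysis_view(compound_ids)
        return int(y.sum()), int((1 - y).sum())

    def swapped(self) -> "CompoundLabelSet":
        """Same labels with primary and secondary class exchanged."""
        return CompoundLabelSet(self.labels, primary=self.secondary, secondary=self.primary)


def read_labels(
    path: str | Path, primary: str = "NGC", secondary: str = "NC"
) -> CompoundLabelSet:
    table = pd.read_csv(path, sep="\t", dtype=str)
    if not {"compound_id", "class"} <= set(table.columns):
        raise ValueError("label table must have columns 'compound_id' and 'class'")
    return CompoundLabelSet(
        dict(zip(table["compound_id"], table["class"])), primary, secondary
    )


def write_labels(labels: CompoundLabelSet, path: str | Path) -> None:
    pd.DataFrame(
        {"compound_id": list(labels.labels), "class": list(labels.labels.values())}
    ).to_csv(path, sep="\t", index=False)


@dataclass
class ExpressionDesign:
    """Log2 expression matrix (genes x samples) plus a treated/control design.

    ``samples`` maps sample IDs to (compound_id, role) with role in
    {"treated", "control"}; every compound needs at least one sample of each
    role so per-compound fold-changes can be formed against its own controls.
    """

    expression: pd.DataFrame
    samples: pd.DataFrame  # index: sample_id; columns: compound_id, role

    def __post_init__(self) -> None:
        if not {"compound_id", "role"} <= set(self.samples.columns):
            raise ValueError("design table needs columns 'compound_id' and 'role'")
        bad = set(self.samples["role"]) - {"treated", "control"}
        if bad:
            raise ValueError(f"invalid sample roles: {sorted(bad)}")
        missing = set(self.samples.index) - set(self.expression.columns)
        if missing:
            raise ValueError(f"samples missing from expression matrix: {sorted(missing)}")
        for cid, group in self.samples.groupby("compound_id"):
            roles = set(group["role"])
            if roles != {"treated", "control"}:
                lacking = {"treated", "control"} - roles
                raise ValueError(f"compound {cid!r} has no {lacking.pop()} samples")


def compute_foldchanges(design: ExpressionDesign) -> FoldChangeMatrix:
    """Mean(log2 treated) - mean(log2 control) per gene and compound."""
    columns = {}
    for cid, group in design.samples.groupby("compound_id", sort=False):
        treated = group.index[group["role"] == "treated"]
        control = group.index[group["role"] == "control"]
        columns[cid] = (
            design.expression[treated].mean(axis=1)
            - design.expression[control].mean(axis=1)
        )
    return FoldChangeMatrix(pd.DataFrame(columns))


@dataclass
class Signature:
    """Ordered list of informative genes with scores and provenance.

    Rank 1 is the most informative gene.  ``provenance`` records the
    extraction method, its parameters and the seed so a signature file is
    self-describing and reproducible.
    """

    gene_ids: list[str]
    scores: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.gene_ids) != len(self.scores):
            raise ValueError("gene_ids and scores length mismatch")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate genes in signature")

    def __len__(self) -> int:
        return len(self.gene_ids)

    @property
    def ranks(self) -> np.ndarray:
        return np.arange(1, len(self.gene_ids) + 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rank": self.ranks, "gene_id": self.gene_ids, "score": self.scores}
        )


def _sidecar(path: str | Path) -> Path:
    return Path(str(path) + ".json")


def write_signature(signature: Signature, path: str | Path) -> None:
    """Write the rank/gene/score TSV plus the JSON provenance sidecar."""
    signature.to_frame().to_csv(path, sep="\t", index=False)
    with open(_sidecar(path), "w") as fh:
        json.dump(signature.provenance, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_signature(path: str | Path) -> Signature:
    table = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    provenance = {}
    side = _sidecar(path)
    if side.exists():
        provenance = json.loads(side.read_text())
    return Signature(
        list(table["gene_id"]), table["score"].to_numpy(), provenance=provenance
    )


@dataclass
class StandardizedFeatureMatrix:
    """Per-gene z-scored features (compounds x genes) with the fitted (mu, sigma).

    The transform is estimated on a fitting set of compounds only (sample SD,
    n-1 denominator) and the stored parameters are re-applied to any later
    compounds, so no information from held-out compounds leaks into the
    feature scaling.
    """

    features: pd.DataFrame  # compounds x genes, z-scores of the fitting set
    mu: pd.Series
    sigma: pd.Series

    @property
    def gene_ids(self) -> list[str]:
        return list(self.features.columns)

    def transform(
        self, matrix: FoldChangeMatrix, compound_ids: Sequence[str]
    ) -> pd.DataFrame:
        """Apply the stored (mu, sigma) to further compounds of ``matrix``."""
        block = matrix.data.loc[self.gene_ids, list(compound_ids)].T
        return (block - self.mu) / self.sigma


def zscore_features(
    matrix: FoldChangeMatrix,
    genes: Signature | Sequence[str],
    fit_on: Sequence[str],
) -> StandardizedFeatureMatrix:
    """Z-score signature genes using mean/SD estimated on ``fit_on`` compounds.

    Raises ValueError listing any gene with zero SD over the fitting set;
    the caller must drop those genes (they carry no scaling information).
    """
    gene_ids = list(genes.gene_ids) if isinstance(genes, Signature) else list(genes)
    fit_on = list(fit_on)
    if len(fit_on) < 2:
        raise ValueError("need at least 2 compounds to fit a z-score transform")
    block = matrix.data.loc[gene_ids, fit_on].T  # compounds x genes
    mu = block.mean(axis=0)
    sigma = block.std(axis=0, ddof=1)
    zero = sigma[sigma == 0.0]
    if len(zero):
        raise ValueError(f"zero standard deviation for genes: {list(zero.index)}")
    return StandardizedFeatureMatrix((block - mu) / sigma, mu, sigma)


def safe_zscore_features(
    matrix: FoldChangeMatrix,
    genes: Signature | Sequence[str],
    fit_on: Sequence[str],
) -> tuple[StandardizedFeatureMatrix, list[str]]:
    """Like :func:`zscore_features` but silently drops zero-SD genes.

    Returns the standardized features and the list of dropped genes.  Used
    inside resampling loops where a constant gene in a small bag is routine.
    """
    gene_ids = list(genes.gene_ids) if isinstance(genes, Signature) else list(genes)
    block = matrix.data.loc[gene_ids, list(fit_on)].T
    sigma = block.std(axis=0, ddof=1)
    dropped = list(sigma.index[sigma == 0.0])
    kept = [g for g in gene_ids if g not in set(dropped)]
    if not kept:
        raise ValueError("all candidate genes have zero variance on the fitting set")
    return zscore_features(matrix, kept, fit_on), dropped
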