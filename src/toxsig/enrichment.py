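"""Hypergeometric gene-set over-representation with BH FDR control.

Given a signature of n genes (counted within the gene-set universe) of
which m fall into a set of size M, with the universe holding N genes, the
upper-tail hypergeometric p-value is

    p = sum_{i=m}^{min(n, M)} C(M, i) C(N-M, n-i) / C(N, n).

The universe defaults to the union of all set members (the quantity the
formula conditions on); an assayed-genes universe can be supplied instead.
p-values are corrected across sets by Benjamini-Hochberg; significance is
called at q < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import Signature

SIGNIFICANCE_LEVEL = 0.05


@dataclass
class GeneSetCollection:
    """Named gene sets; the universe is the union of all members."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str]

    def __post_init__(self) -> None:
        if not self.sets:
            raise ValueError("collection is empty")
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    @property
    def universe(self) -> set[str]:
        out: set[str] = set()
        for members in self.sets.values():
            out |= members
        return out

    def __len__(self) -> int:
        return len(self.sets)


def load_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: ``name<TAB>description<TAB>gene1<TAB>gene2...``."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3 or not any(g.strip() for g in fields[2:]):
            raise ValueError(f"empty gene set at line {lineno}")
        name, description = fields[0], fields[1]
        sets[name] = {g for g in fields[2:] if g.strip()}
        descriptions[name] = description
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = []
    for name, members in collection.sets.items():
        desc = collection.descriptions.get(name, "")
        lines.append("\t".join([name, desc, *sorted(members)]))
    Path(path).write_text("\n".join(lines) + "\n")


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (capped at 1)."""
    p = np.asarray(list(pvalues), dtype=float)
    if len(p) == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeometric_enrichment(
    signature: Signature | Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Upper-tail hypergeometric test of every set against the signature.

    Signature genes outside the universe are dropped from n.  Returns a
    frame indexed by set name with columns M, m, n, N, p, q, significant,
    sorted ascending by p (ties by name).
    """
    genes = set(
        signature.gene_ids if isinstance(signature, Signature) else signature
    )
    uni = set(universe) if universe is not None else collection.universe
    if not uni:
        raise ValueError("empty universe")
    in_universe = genes & uni
    n = len(in_universe)
    if n == 0:
        raise ValueError("no signature genes in universe")
    N = len(uni)
    rows = []
    for name, members in collection.sets.items():
        members_in = members & uni
        M = len(members_in)
        m = len(in_universe & members_in)
        # P(X >= m) for X ~ Hypergeom(N, M, n)
        p = float(stats.hypergeom.sf(m - 1, N, M, n))
        rows.append({"set": name, "M": M, "m": m, "n": n, "N": N, "p": min(p, 1.0)})
    frame = pd.DataFrame(rows).set_index("set")
    frame["q"] = bh_fdr(frame["p"])
    frame["significant"] = frame["q"] < SIGNIFICANCE_LEVEL
    return frame.sort_index(kind="stable").sort_values("p", kind="stable")
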