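"""Kuncheva stability index for feature subsets.

The Kuncheva index (KI) measures the consistency of two equal-sized feature
subsets A and B drawn from a universe of n features:

    KI(A, B) = (r - k^2/n) / (k - k^2/n),   r = |A n B|, k = |A| = |B|.

The k^2/n term corrects for chance overlap: KI is 1 for identical subsets,
0 in expectation for independently drawn subsets, and reaches its minimum
-1 for disjoint subsets with k = n/2.  For m > 2 subsets the index is
averaged over all m(m-1)/2 unordered pairs.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


def kuncheva_index(a: Iterable[str], b: Iterable[str], n: int) -> float:
    """Chance-corrected overlap of two equal-sized subsets of an n-universe."""
    a, b = set(a), set(b)
    k = len(a)
    if len(b) != k:
        raise ValueError(f"subsets must have equal size (got {k} and {len(b)})")
    if k == 0 or k >= n:
        raise ValueError("subset size must satisfy 0 < k < n (zero denominator)")
    r = len(a & b)
    correction = k * k / n
    return (r - correction) / (k - correction)


def mean_kuncheva(subsets: Sequence[Iterable[str]], n: int) -> float:
    """Average KI over all unordered pairs of m >= 2 subsets."""
    subsets = [set(s) for s in subsets]
    if len(subsets) < 2:
        raise ValueError("need at least two subsets")
    pairs = [kuncheva_index(a, b, n) for a, b in combinations(subsets, 2)]
    return float(np.mean(pairs))


def stability_curve(
    rankings_by_method: dict[str, Sequence],
    sizes: Sequence[int],
    n: int,
) -> pd.DataFrame:
    """Mean KI of top-k gene sets across resamples, per method and size.

    ``rankings_by_method`` maps a method name to its per-bootstrap
    GeneRanking objects (anything with a ``top(k)`` method).  Returns a tidy
    frame with columns method, size, mean_ki.
    """
    rows = []
    for method, rankings in rankings_by_method.items():
        if len(rankings) < 2:  # KI needs at least a pair of subsets
            continue
        for k in sizes:
            if not 0 < k < n:
                continue
            tops = [r.top(k) for r in rankings]
            rows.append(
                {"method": method, "size": int(k), "mean_ki": mean_kuncheva(tops, n)}
            )
    return pd.DataFrame(rows, columns=["method", "size", "mean_ki"])
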