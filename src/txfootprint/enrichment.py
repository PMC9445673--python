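"""Category over-representation with Benjamini-Yekutieli FDR control.

For a query gene list and an annotation collection over a background
universe of N genes, each category of size K is scored by the one-sided
upper-tail hypergeometric probability P(X >= k) of the observed overlap k
out of a query of size n.  Raw p-values are adjusted across categories with
the Benjamini-Yekutieli step-up, which controls the false discovery rate
under arbitrary dependence between categories (annotation categories overlap
heavily, so the BH independence assumption is not safe here).  The
descriptive "normed frequency" (k/n)/(K/N) -- the category's frequency in
the query relative to its frequency in the background, 1 meaning no
enrichment -- is reported alongside.

The background defaults to the union of the collection's categories; an
explicit whole-genome universe can be supplied instead, and every category
and query is restricted to it before counting.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .setops import NamedGeneSet, read_gmt


def hypergeom_upper(N: int, K: int, n: int, k: int) -> float:
    """One-sided upper tail P(X >= k), X ~ Hypergeometric(N, K, n).

    Computed via scipy's survival function, which works in log space
    internally and is stable for large N.  Parameter domain is checked
    strictly: k must lie in the support [max(0, n+K-N), min(n, K)].
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K <= N and 0 <= n <= N, got N={N}, K={K}, n={n}")
    lo, hi = max(0, n + K - N), min(n, K)
    if not lo <= k <= hi:
        raise ValueError(f"k={k} outside support [{lo}, {hi}] for N={N}, K={K}, n={n}")
    if k <= lo:  # whole support, incl. degenerate draws scipy maps to NaN
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def yekutieli_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjusted p-values, in input order.

    Equivalent to sorting ascending, setting q_i = p_(i) * m * c(m) / i with
    c(m) the m-th harmonic number, enforcing monotonicity from the largest
    rank down, and capping at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_by")[1]


def normed_frequency(k: int, n: int, K: int, N: int) -> float:
    """(k/n) / (K/N): query frequency over background frequency of a category."""
    if n <= 0 or K <= 0:
        raise ValueError(f"need n > 0 and K > 0, got n={n}, K={K}")
    return (k / n) / (K / N)


@dataclass(frozen=True)
class GeneSetCollection:
    """Named annotation categories over an explicit background universe.

    Categories are restricted to the background at construction; the
    background must be nonempty.
    """

    categories: dict[str, frozenset[str]]
    background: frozenset[str]
    descriptions: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if not self.background:
            raise ValueError("background universe must be nonempty")
        for name, members in self.categories.items():
            extra = members - self.background
            if extra:
                raise ValueError(
                    f"category {name!r} has {len(extra)} members outside the background; "
                    "use from_sets() to restrict"
                )

    @staticmethod
    def from_sets(sets: Iterable[NamedGeneSet],
                  background: Iterable[str] | None = None) -> "GeneSetCollection":
        """Build a collection; background defaults to the union of the sets."""
        sets = list(sets)
        if background is None:
            bg = frozenset().union(*(s.genes for s in sets)) if sets else frozenset()
        else:
            bg = frozenset(background)
        cats = {s.name: s.genes & bg for s in sets}
        return GeneSetCollection(cats, bg)

    @staticmethod
    def from_gmt(path: str | Path, background: Iterable[str] | None = None) -> "GeneSetCollection":
        return GeneSetCollection.from_sets(read_gmt(path), background)


def enrich(query: NamedGeneSet, collection: GeneSetCollection,
           q: float = 0.05, depletion: bool = False) -> pd.DataFrame:
    """Score every category for over-representation in the query.

    Returns one row per category with the full contingency (N, K, n, k), the
    raw one-sided hypergeometric p, the Yekutieli-adjusted p, the normed
    frequency and a significance flag at p_adj < q.  Sorted by p_adj, ties
    broken by category name.  ``depletion=True`` flips to the lower tail.
    """
    if not 0 < q < 1:
        raise ValueError(f"q must lie in (0, 1), got {q}")
    restricted = query.genes & collection.background
    if not restricted:
        raise ValueError(
            f"query {query.name!r} has no genes in the background universe "
            f"({len(query.genes)} genes before restriction)"
        )
    N = len(collection.background)
    n = len(restricted)
    rows = []
    for name in sorted(collection.categories):
        members = collection.categories[name]
        K = len(members)
        k = len(restricted & members)
        if depletion:
            p_raw = float(hypergeom.cdf(k, N, K, n))
        else:
            p_raw = hypergeom_upper(N, K, n, k)
        nf = normed_frequency(k, n, K, N) if K > 0 else float("nan")
        rows.append((name, N, K, n, k, p_raw, nf))
    df = pd.DataFrame(
        rows, columns=["category", "N", "K", "n", "k", "p_raw", "normed_frequency"]
    )
    df["p_adj"] = yekutieli_adjust(df["p_raw"].to_numpy())
    df["significant"] = df["p_adj"] < q
    df = df.sort_values(["p_adj", "category"], kind="stable").reset_index(drop=True)
    return df[
        ["category", "N", "K", "n", "k", "p_raw", "p_adj", "normed_frequency", "significant"]
    ]
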