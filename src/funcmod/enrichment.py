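"""Hypergeometric over-representation analysis of gene sets against a term database.

The point mass is computed with exact integer arithmetic; the upper tail
P(X >= k) is the enrichment p-value. q-values are Benjamini-Hochberg adjusted
within each query, and tables are filtered at p < alpha_p AND q < alpha_q.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from math import comb

import pandas as pd
from statsmodels.stats.multitest import multipletests

from .datatypes import GeneUniverse, OmicsGeneSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyCounts:
    """Counts for one 2x2 over-representation problem.

    N: population size, M: population members with the attribute,
    n: number of draws, k: hits among the draws.
    """

    N: int
    M: int
    n: int
    k: int

    def __post_init__(self) -> None:
        if not (0 <= self.M <= self.N and 0 <= self.n <= self.N):
            raise ValueError(f"invalid counts: M={self.M}, n={self.n} must lie in [0, N={self.N}]")
        if not (0 <= self.k <= min(self.M, self.n)):
            raise ValueError(f"invalid counts: k={self.k} must lie in [0, min(M={self.M}, n={self.n})]")


def hypergeom_pmf(counts: ContingencyCounts) -> float:
    """P(X = k) = C(M,k) C(N-M, n-k) / C(N,n), exact."""
    N, M, n, k = counts.N, counts.M, counts.n, counts.k
    if n - k > N - M:  # impossible draw composition
        return 0.0
    num = comb(M, k) * comb(N - M, n - k)
    return float(Fraction(num, comb(N, n)))


def hypergeom_upper_tail(counts: ContingencyCounts) -> float:
    """P(X >= k), exact sum of the point masses over k' = k .. min(M, n)."""
    N, M, n, k = counts.N, counts.M, counts.n, counts.k
    total = 0
    for kp in range(k, min(M, n) + 1):
        if n - kp > N - M:
            continue
        total += comb(M, kp) * comb(N - M, n - kp)
    return float(Fraction(total, comb(N, n)))


def bh_adjust(pvalues) -> pd.Series | list[float]:
    """Benjamini-Hochberg step-up adjusted p-values."""
    import numpy as np

    p = pd.Series(pvalues, dtype=float)
    if p.empty:
        return p
    q = multipletests(p.to_numpy(), method="fdr_bh")[1]
    return pd.Series(np.asarray(q), index=p.index)


def enrich_terms(
    query: OmicsGeneSet,
    terms: dict[str, list[str]],
    universe: GeneUniverse,
    alpha_p: float = 0.05,
    alpha_q: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric enrichment of one query set against every term.

    Returns the filtered EnrichmentTable as a DataFrame with columns
    term, source, N, M, n, k, p, q, hit_genes; sorted by p ascending with
    ties broken by term id. Terms with k = 0 get p = 1 and participate in
    the BH adjustment before filtering.
    """
    uni = universe.as_set()
    qgenes = set(query.genes) & uni
    dropped = len(query.genes) - len(qgenes)
    if dropped:
        logger.warning("query %s: dropped %d gene(s) outside the universe", query.name, dropped)
    N, n = len(universe), len(qgenes)

    rows = []
    for term_id in sorted(terms):
        tgenes = set(terms[term_id]) & uni
        hits = sorted(qgenes & tgenes)
        counts = ContingencyCounts(N=N, M=len(tgenes), n=n, k=len(hits))
        p = 1.0 if counts.k == 0 else hypergeom_upper_tail(counts)
        rows.append(
            {
                "term": term_id,
                "source": query.name,
                "N": N,
                "M": counts.M,
                "n": counts.n,
                "k": counts.k,
                "p": p,
                "hit_genes": ";".join(hits),
            }
        )
    table = pd.DataFrame(rows, columns=["term", "source", "N", "M", "n", "k", "p", "hit_genes"])
    if n == 0:
        logger.warning("query %s is empty after intersection with the universe", query.name)
        table["q"] = pd.Series(dtype=float)
        return table.iloc[0:0][["term", "source", "N", "M", "n", "k", "p", "q", "hit_genes"]]

    table["q"] = bh_adjust(table["p"]).to_numpy()
    table = table[(table["p"] < alpha_p) & (table["q"] < alpha_q)]
    table = table.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)
    return table[["term", "source", "N", "M", "n", "k", "p", "q", "hit_genes"]]


def write_enrichment_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_enrichment_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["hit_genes"] = df["hit_genes"].fillna("")
    return df
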