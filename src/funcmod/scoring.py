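"""Sample-level scoring: ssGSEA, gene-trait correlation, and preranked GSEA.

Implements the lineage-plasticity procedure: single-sample scoring of a gene
set against each sample's expression ranking, Pearson gene-significance
correlation with positive-value retention, and preranked GSEA with a
gene-label permutation null and leading-edge extraction.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import OmicsGeneSet  # noqa: F401  (accepted as gene_set input)

logger = logging.getLogger(__name__)


@dataclass
class ScoringConfig:
    alpha: float = 0.25          # ssGSEA rank-weight exponent
    gsea_weight: float = 1.0     # GSEA running-sum weight exponent
    n_perm: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


@dataclass
class RankedSignature:
    """Genes ordered by score descending; ties broken by gene id ascending."""

    genes: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.scores):
            raise ValueError("genes and scores must align")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("signature genes must be unique")
        order = np.lexsort((np.asarray(self.genes, dtype=object), -np.asarray(self.scores, dtype=float)))
        self.genes = [self.genes[i] for i in order]
        self.scores = np.asarray(self.scores, dtype=float)[order]

    @classmethod
    def from_series(cls, s: pd.Series) -> "RankedSignature":
        return cls(list(s.index), s.to_numpy(dtype=float))

    def to_series(self) -> pd.Series:
        return pd.Series(self.scores, index=self.genes, name="score")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class ESResult:
    """One preranked GSEA outcome."""

    ES: float
    NES: float
    p: float
    leading_edge: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# running-sum machinery

def _running_sum_extremum(hit_pos: np.ndarray, hit_w: np.ndarray, n_total: int):
    """Extremum of the GSEA running sum from sorted 0-based hit positions.

    Returns (ES, index of the extremal hit, side) where side is +1 if the
    extremum occurs just after a hit (positive-ES convention) and -1 if just
    before one. The running sum visits hit increments hit_w/sum(hit_w) and
    miss decrements 1/(n_total - n_hits); its extrema can only occur at these
    breakpoints, so scanning them is exact and O(n_hits).
    """
    m = len(hit_pos)
    W = hit_w.sum()
    if W <= 0:
        hit_w = np.ones(m)
        W = float(m)
    miss_dec = 1.0 / (n_total - m)
    idx = np.arange(1, m + 1)
    cum = np.cumsum(hit_w) / W
    after = cum - (hit_pos + 1 - idx) * miss_dec
    before = np.concatenate(([0.0], cum[:-1])) - (hit_pos - (idx - 1)) * miss_dec
    i_a = int(np.argmax(after))
    i_b = int(np.argmin(before))
    if abs(after[i_a]) >= abs(before[i_b]):
        return float(after[i_a]), i_a, +1
    return float(before[i_b]), i_b, -1


def _batch_es(pos: np.ndarray, w: np.ndarray, n_total: int) -> np.ndarray:
    """ES values for B hit-position sets at once (rows pre-sorted ascending)."""
    B, m = pos.shape
    W = w.sum(axis=1, keepdims=True)
    W = np.where(W <= 0, m, W)
    miss_dec = 1.0 / (n_total - m)
    idx = np.arange(1, m + 1)[None, :]
    cum = np.cumsum(w, axis=1) / W
    after = cum - (pos + 1 - idx) * miss_dec
    before = np.concatenate((np.zeros((B, 1)), cum[:, :-1]), axis=1) - (pos - (idx - 1)) * miss_dec
    hi = after.max(axis=1)
    lo = before.min(axis=1)
    return np.where(np.abs(hi) >= np.abs(lo), hi, lo)


# ---------------------------------------------------------------------------
# ssGSEA

def ssgsea_score(expr: pd.DataFrame, gene_set, config: ScoringConfig | None = None) -> pd.Series:
    """Per-sample single-sample GSEA scores, min-max normalized to [0, 1].

    Per sample, genes are ranked by expression descending (rank values
    N..1); the score is the integral of the weighted-hit ECDF minus the
    miss ECDF over all positions. Absent gene-set genes are dropped with a
    warning; no overlap is an error.
    """
    config = config or ScoringConfig()
    genes = list(getattr(gene_set, "genes", gene_set))
    present = [g for g in genes if g in expr.index]
    if not present:
        raise ValueError("gene set has no overlap with expression rows")
    if len(present) < len(genes):
        logger.warning("ssgsea: dropped %d gene(s) absent from expression", len(genes) - len(present))
    if len(present) >= len(expr.index):
        raise ValueError("gene set covers all expression rows; misses undefined")

    G = len(expr.index)
    m = len(present)
    in_set = np.asarray(expr.index.isin(present))
    gene_key = np.asarray(expr.index, dtype=object)
    rank_values = np.arange(G, 0, -1, dtype=float)
    weights_all = np.abs(rank_values) ** config.alpha
    X = expr.to_numpy(dtype=float)

    raw = np.empty(expr.shape[1])
    for s in range(expr.shape[1]):
        order = np.lexsort((gene_key, -X[:, s]))
        hits = in_set[order]
        w = np.where(hits, weights_all, 0.0)
        W = w.sum()
        p_hit = np.cumsum(w) / W
        p_miss = np.cumsum(~hits) / (G - m)
        raw[s] = float(np.sum(p_hit - p_miss))

    lo, hi = raw.min(), raw.max()
    norm = np.full_like(raw, 0.5) if hi == lo else (raw - lo) / (hi - lo)
    return pd.Series(norm, index=expr.columns, name="ssgsea")


# ---------------------------------------------------------------------------
# gene-trait correlation

def gene_trait_correlation(expr: pd.DataFrame, trait: pd.Series) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation of each gene's expression with a per-sample trait.

    Returns (retained, full): the retained table keeps genes with r > 0
    sorted descending; the full table records every gene (NaN r for
    zero-variance genes) for audit.
    """
    if len(trait) != expr.shape[1]:
        raise ValueError("trait length must equal sample count")
    t = trait.reindex(expr.columns).to_numpy(dtype=float)
    X = expr.to_numpy(dtype=float)
    n = len(t)
    xc = X - X.mean(axis=1, keepdims=True)
    tc = t - t.mean()
    sx = np.sqrt((xc**2).sum(axis=1))
    st = np.sqrt((tc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ tc) / (sx * st)
    r[sx == 0] = np.nan
    if st == 0:
        r[:] = np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt((n - 2) / np.clip(1 - r**2, 1e-300, None))
    p = 2 * stats.t.sf(np.abs(tstat), df=max(n - 2, 1))
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    full = pd.DataFrame({"gene": expr.index, "r": r, "p": p}).set_index("gene")
    retained = full[full["r"] > 0].sort_values("r", ascending=False, kind="mergesort")
    return retained, full


# ---------------------------------------------------------------------------
# preranked GSEA

def preranked_gsea(
    signature: RankedSignature,
    gene_set,
    config: ScoringConfig | None = None,
    rng: np.random.Generator | None = None,
) -> ESResult:
    """Weighted running-sum GSEA with a gene-label permutation null.

    The null resamples size-matched random gene sets from the signature;
    p compares the observed ES against same-sign null ES values and NES
    divides by their mean magnitude.
    """
    config = config or ScoringConfig()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    genes = list(getattr(gene_set, "genes", gene_set))
    N = len(signature)
    hit_mask = np.isin(np.asarray(signature.genes, dtype=object), np.asarray(list(set(genes)), dtype=object))
    pos = np.flatnonzero(hit_mask)
    m = len(pos)
    if m == 0:
        raise ValueError("gene set has no overlap with the signature")
    if m >= N:
        raise ValueError("gene set covers the whole signature")

    weights_all = np.abs(signature.scores) ** config.gsea_weight
    es, i_ext, side = _running_sum_extremum(pos.astype(float), weights_all[pos], N)
    if es > 0:
        lead_pos = pos[: i_ext + 1] if side > 0 else pos[:i_ext]
    elif es < 0:
        lead_pos = pos[i_ext:]
    else:
        lead_pos = pos[:0]
    leading_edge = [signature.genes[i] for i in lead_pos]

    null_pos = np.sort(
        np.array([rng.choice(N, size=m, replace=False) for _ in range(config.n_perm)]), axis=1
    )
    null_es = _batch_es(null_pos.astype(float), weights_all[null_pos], N)

    same_sign = null_es > 0 if es >= 0 else null_es < 0
    n_same = int(same_sign.sum())
    if n_same == 0:
        p = 1.0 / (1.0 + config.n_perm)
        denom = np.abs(null_es).mean() if config.n_perm else np.nan
    else:
        exceed = int((np.abs(null_es[same_sign]) >= abs(es)).sum())
        p = (1.0 + exceed) / (1.0 + n_same)
        denom = np.abs(null_es[same_sign]).mean()
    nes = es / denom if denom > 0 else np.nan
    return ESResult(ES=es, NES=float(nes), p=float(p), leading_edge=leading_edge)


# ---------------------------------------------------------------------------
# end-to-end plasticity procedure

def rank_genes_by_group_difference(expr: pd.DataFrame, high: list, low: list) -> RankedSignature:
    """Difference of group means per gene, as a ranked signature."""
    diff = expr[high].mean(axis=1) - expr[low].mean(axis=1)
    return RankedSignature.from_series(diff)


def plasticity_pipeline(
    expr: pd.DataFrame,
    plasticity_sets: list,
    module_genes,
    pathway_sets: dict[str, list[str]],
    config: ScoringConfig | None = None,
) -> dict:
    """ssGSEA plasticity score -> positive gene-trait correlation -> median
    split -> preranked GSEA of each pathway set, with leading edges.
    """
    config = config or ScoringConfig()
    if expr.shape[1] < 4:
        raise ValueError("need >= 4 samples for a high/low split")
    union: list[str] = []
    seen = set()
    for gs in plasticity_sets:
        for g in getattr(gs, "genes", gs):
            if g not in seen:
                seen.add(g)
                union.append(g)
    score = ssgsea_score(expr, union, config)
    retained, full = gene_trait_correlation(expr.loc[expr.index.intersection(list(module_genes))], score)

    med = score.median()
    high = list(score.index[score > med])
    low = list(score.index[score <= med])
    if not high or not low:
        # all-tied scores: fall back to a deterministic half split
        cols = list(score.index)
        high, low = cols[: len(cols) // 2], cols[len(cols) // 2 :]
    signature = rank_genes_by_group_difference(expr, high, low)

    rng = np.random.default_rng(config.seed)
    gsea = {}
    for name in sorted(pathway_sets):
        genes = [g for g in pathway_sets[name] if g in set(signature.genes)]
        if not genes:
            logger.warning("pathway set %s has no overlap with the signature; skipped", name)
            continue
        gsea[name] = preranked_gsea(signature, genes, config, rng=rng)
    return {
        "plasticity_score": score,
        "correlation_retained": retained,
        "correlation_full": full,
        "high_samples": high,
        "low_samples": low,
        "signature": signature,
        "gsea": gsea,
    }
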