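"""Transcription-factor analyses: knockdown-signature over-representation of a
target gene list, and regulon-based activity scoring from a ranked signature.

Activity uses a signed rank-mean statistic: signature scores are converted to
rank fractions in (0, 1); a regulon's statistic is the mean over targets of
mode * (2 * rank_fraction - 1), compared against an empirical null of
size-matched random target sets with random signs.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GeneUniverse
from .enrichment import ContingencyCounts, bh_adjust, hypergeom_upper_tail
from .scoring import RankedSignature

logger = logging.getLogger(__name__)


@dataclass
class Regulon:
    tf: str
    targets: list[str]
    modes: list[float]

    def __post_init__(self) -> None:
        if len(self.targets) != len(self.modes):
            raise ValueError(f"regulon {self.tf}: modes must align to targets")
        if len(set(self.targets)) != len(self.targets):
            raise ValueError(f"regulon {self.tf}: duplicate targets")

    @classmethod
    def from_mode_dict(cls, tf: str, modes: dict[str, float]) -> "Regulon":
        return cls(tf, list(modes), [modes[g] for g in modes])


@dataclass
class KnockdownSignature:
    tf: str
    affected: list[str]

    def __post_init__(self) -> None:
        if len(set(self.affected)) != len(self.affected):
            raise ValueError(f"signature {self.tf}: duplicate genes")


def tf_knockdown_enrichment(
    signatures: list[KnockdownSignature],
    target_set: list[str],
    universe: GeneUniverse,
    min_hits: int = 14,
) -> pd.DataFrame:
    """Per-TF hypergeometric over-representation of target_set among the
    genes affected by each TF knockdown.

    Sorted by k descending then p ascending; ``passes_filter`` marks TFs with
    k > min_hits.
    """
    targets = set(target_set) & universe.as_set()
    if set(target_set) - universe.as_set():
        raise ValueError("target_set must be a subset of the universe")
    N, M = len(universe), len(targets)
    rows = []
    for sig in signatures:
        affected = set(sig.affected) & universe.as_set()
        k = len(affected & targets)
        counts = ContingencyCounts(N=N, M=M, n=len(affected), k=k)
        p = 1.0 if k == 0 else hypergeom_upper_tail(counts)
        rows.append({"tf": sig.tf, "k": k, "n_affected": len(affected), "p": p})
    table = pd.DataFrame(rows, columns=["tf", "k", "n_affected", "p"])
    if table.empty:
        table["q"] = pd.Series(dtype=float)
        table["passes_filter"] = pd.Series(dtype=bool)
        return table
    table["q"] = bh_adjust(table["p"]).to_numpy()
    table["passes_filter"] = table["k"] > min_hits
    return table.sort_values(["k", "p", "tf"], ascending=[False, True, True], kind="mergesort").reset_index(drop=True)


def regulon_activity(
    signature: RankedSignature,
    regulons: list[Regulon],
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-TF activity from the signed rank-mean statistic with an empirical
    null; positive z = activated, negative z = repressed.

    Regulons with fewer than 3 targets present in the signature are skipped
    with a warning. Null target sets are shared across regulons of equal
    usable size (the null depends only on size).
    """
    rng = np.random.default_rng(seed)
    genes = np.asarray(signature.genes, dtype=object)
    rf = stats.rankdata(signature.scores, method="average") / (len(genes) + 1.0)
    centered = 2.0 * rf - 1.0
    gene_pos = {g: i for i, g in enumerate(genes)}

    usable = []
    for reg in regulons:
        idx, modes = [], []
        for g, m in zip(reg.targets, reg.modes):
            if g in gene_pos:
                idx.append(gene_pos[g])
                modes.append(m)
        if len(idx) < 3:
            logger.warning("regulon %s: only %d usable target(s); skipped", reg.tf, len(idx))
            continue
        usable.append((reg.tf, np.asarray(idx), np.asarray(modes, dtype=float)))

    null_by_size: dict[int, tuple[float, float]] = {}
    for size in sorted({len(idx) for _, idx, _ in usable}):
        draws = rng.choice(len(genes), size=(n_perm, size), replace=True)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, size))
        null_stats = (signs * centered[draws]).mean(axis=1)
        null_by_size[size] = (float(null_stats.mean()), float(null_stats.std(ddof=1)))

    rows = []
    for tf, idx, modes in usable:
        obs = float((modes * centered[idx]).mean())
        mu, sd = null_by_size[len(idx)]
        z = (obs - mu) / sd if sd > 0 else np.nan
        p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        rows.append({"tf": tf, "activity": obs, "z": z, "p": p, "n_targets": len(idx)})
    table = pd.DataFrame(rows, columns=["tf", "activity", "z", "p", "n_targets"])
    if not table.empty:
        table["q"] = bh_adjust(table["p"].dropna()).reindex(table.index)
        table = table.sort_values(["z", "tf"], ascending=[False, True], kind="mergesort").reset_index(drop=True)
    return table
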