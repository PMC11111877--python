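"""Copy-number categorization, CNV association tests, prevalence summaries,
and mutation-stratum enrichment."""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import ContingencyCounts, bh_adjust, hypergeom_upper_tail

logger = logging.getLogger(__name__)

CATEGORY_LEVELS = (-2, -1, 0, 1, 2)


def segment_to_category(segments: pd.DataFrame) -> pd.DataFrame:
    """Discretize log2-ratio segment values into copy-number categories.

    CN = 2^(Segment + 1); then CN > 3.5 -> 2 (amplification),
    2.5 < CN <= 3.5 -> 1 (single gain), CN < 0.5 -> -2 (double deletion),
    0.5 <= CN < 1.5 -> -1 (single deletion), else 0 (normal). Boundaries:
    CN = 3.5 -> 1, CN = 2.5 -> 0, CN = 0.5 -> -1, CN = 1.5 -> 0.
    """
    vals = segments.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        bad = np.argwhere(~np.isfinite(vals))
        cells = [(segments.index[i], segments.columns[j]) for i, j in bad[:10]]
        raise ValueError(f"non-finite segment values at {cells}")
    cn = np.power(2.0, vals + 1.0)
    cat = np.select(
        [cn > 3.5, cn > 2.5, cn < 0.5, cn < 1.5],
        [2, 1, -2, -1],
        default=0,
    )
    return pd.DataFrame(cat.astype(np.int64), index=segments.index, columns=segments.columns)


def _chi2_pvalue(table: np.ndarray, rng: np.random.Generator, n_resample: int = 2000) -> float:
    """Pearson chi-square p, falling back to a Monte-Carlo permutation p when
    more than 20% of expected cells are below 5."""
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        return np.nan
    chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
    if (expected < 5).mean() <= 0.20:
        return float(p)
    # permutation null with fixed margins via label shuffling
    cats = np.repeat(np.arange(table.shape[0]), table.sum(axis=1))
    groups = np.repeat(np.arange(table.shape[1]), table.sum(axis=0))
    exceed = 0
    for _ in range(n_resample):
        perm = rng.permutation(groups)
        t = np.zeros_like(table)
        np.add.at(t, (cats, perm), 1)
        with np.errstate(invalid="ignore"):
            stat = ((t - expected) ** 2 / expected).sum()
        if stat >= chi2 - 1e-12:
            exceed += 1
    return (1.0 + exceed) / (1.0 + n_resample)


def cnv_association_tests(
    categories: pd.DataFrame,
    groups: pd.Series,
    expr: pd.DataFrame | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-gene chi-square (category x tumor/normal) and Kruskal-Wallis
    (expression across category levels) tests with BH adjustment per family.
    """
    groups = groups.reindex(categories.columns)
    if groups.isna().any():
        raise ValueError("group labels must cover all category-matrix samples")
    labels = sorted(groups.unique())
    if len(labels) < 2:
        logger.warning("single sample group; chi-square test skipped")
    rng = np.random.default_rng(seed)

    chi2_p = {}
    for gene in categories.index:
        if len(labels) < 2:
            chi2_p[gene] = np.nan
            continue
        row = categories.loc[gene]
        table = np.array(
            [[int(((row == c) & (groups == g)).sum()) for g in labels] for c in CATEGORY_LEVELS]
        )
        chi2_p[gene] = _chi2_pvalue(table, rng)

    kw_p = {}
    if expr is not None:
        shared = categories.index.intersection(expr.index)
        samples = categories.columns.intersection(expr.columns)
        for gene in shared:
            cats = categories.loc[gene, samples]
            vals = expr.loc[gene, samples]
            grps = [vals[cats == c].to_numpy() for c in CATEGORY_LEVELS]
            grps = [g for g in grps if len(g) >= 2]
            if len(grps) < 2:
                kw_p[gene] = np.nan
                continue
            try:
                kw_p[gene] = float(stats.kruskal(*grps).pvalue)
            except ValueError:  # all values identical
                kw_p[gene] = np.nan

    out = pd.DataFrame(index=categories.index)
    out["chi2_p"] = pd.Series(chi2_p)
    out["chi2_q"] = bh_adjust(out["chi2_p"].dropna()).reindex(out.index)
    out["kw_p"] = pd.Series(kw_p).reindex(out.index)
    out["kw_q"] = bh_adjust(out["kw_p"].dropna()).reindex(out.index)
    return out


def cnv_prevalence(
    categories: pd.DataFrame,
    significant_genes: list[str],
    tumor_samples: list[str],
) -> pd.DataFrame:
    """Dominant non-normal category per gene and its tumor-sample fraction.

    Ties go to the more extreme |category|, then amplification over deletion.
    All-normal genes report ("none", 0.0).
    """
    missing = set(significant_genes) - set(categories.index)
    if missing:
        raise ValueError(f"genes absent from category matrix: {sorted(missing)[:5]}")
    sub = categories.loc[significant_genes, tumor_samples]
    n_tumor = len(tumor_samples)
    rows = []
    for gene in significant_genes:
        counts = sub.loc[gene].value_counts()
        nonzero = {c: int(counts.get(c, 0)) for c in (-2, -1, 1, 2) if counts.get(c, 0) > 0}
        if not nonzero:
            rows.append({"gene": gene, "dominant_type": "none", "fraction": 0.0})
            continue
        best = max(nonzero, key=lambda c: (nonzero[c], abs(c), c))
        rows.append({"gene": gene, "dominant_type": str(best), "fraction": nonzero[best] / n_tumor})
    return pd.DataFrame(rows).set_index("gene")


def mutation_strata_enrichment(
    mutations: pd.DataFrame,
    strata: pd.Series,
    gene: str,
    stratum: str,
) -> tuple[ContingencyCounts, float]:
    """Hypergeometric enrichment of one gene's mutated samples in a stratum.

    N = all samples, M = stratum samples, n = mutated samples,
    k = mutated samples inside the stratum; p = upper-tail probability.
    """
    if gene not in mutations.index:
        raise KeyError(f"gene {gene!r} not in mutation matrix")
    strata = strata.reindex(mutations.columns)
    in_stratum = strata == stratum
    if not in_stratum.any():
        raise ValueError(f"stratum {stratum!r} is empty")
    mutated = mutations.loc[gene].astype(bool)
    counts = ContingencyCounts(
        N=mutations.shape[1],
        M=int(in_stratum.sum()),
        n=int(mutated.sum()),
        k=int((mutated & in_stratum).sum()),
    )
    return counts, hypergeom_upper_tail(counts)


# ---------------------------------------------------------------------------
# clinical stratification utilities

def gleason_grade_group(primary: int, secondary: int) -> int:
    """Grade Group 1 = Gleason <= 6; 2 = 3+4; 3 = 4+3; 4 = Gleason 8;
    5 = Gleason 9-10."""
    total = primary + secondary
    if total <= 6:
        return 1
    if (primary, secondary) == (3, 4):
        return 2
    if (primary, secondary) == (4, 3):
        return 3
    if total == 8:
        return 4
    if total in (9, 10):
        return 5
    raise ValueError(f"unmappable Gleason scores: {primary}+{secondary}")


def t_stage_class(stage: str) -> str:
    """T3-T4 -> extraprostatic extension; T2 -> intraprostatic tumor."""
    s = stage.strip().upper()
    if s.startswith(("T3", "T4")):
        return "extraprostatic"
    if s.startswith("T2"):
        return "intraprostatic"
    raise ValueError(f"unmappable T stage: {stage!r}")
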