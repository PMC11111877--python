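"""Synthetic data generators with planted structure for every pipeline stage.

One root seed drives deterministic per-stage generators, so any stage can be
regenerated in isolation. Ground-truth labels (term blocks, shifted samples,
planted CNV genes, planted mutation, planted active TF) are always returned
alongside the data.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .datatypes import GeneUniverse, OmicsGeneSet
from .scoring import RankedSignature
from .survival import RiskModel
from .tf import Regulon

SOURCE_NAMES = ("DEG", "lncRNA", "extraprostatic", "SNV", "methylation", "CNV")

# fixed stage offsets so each stage has its own reproducible generator
_STAGE_KEYS = {
    "terms": 1,
    "omics": 2,
    "expression": 3,
    "cnv": 4,
    "survival": 5,
}


@dataclass
class SimulationConfig:
    seed: int = 0
    n_genes: int = 1000
    n_terms: int = 60
    n_blocks: int = 6
    term_size_range: tuple[int, int] = (15, 40)
    within_block_jaccard: float = 0.6
    n_samples: int = 100
    signal_effect: float = 1.0
    noise_sd: float = 1.0
    cnv_amp_rate: float = 0.3
    cnv_del_rate: float = 0.2
    mutation_rate: float = 0.05
    censoring_rate: float = 0.2

    def __post_init__(self) -> None:
        for name in ("within_block_jaccard", "cnv_amp_rate", "cnv_del_rate",
                     "mutation_rate", "censoring_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must be in [0, 1]")
        if self.n_blocks > self.n_terms:
            raise ValueError("n_blocks must not exceed n_terms")
        lo, hi = self.term_size_range
        if not (0 < lo <= hi):
            raise ValueError("term_size_range must satisfy 0 < min <= max")
        if hi > self.n_genes:
            raise ValueError("term_size_range max must not exceed n_genes")
        if self.cnv_amp_rate + self.cnv_del_rate > 1.0:
            raise ValueError("cnv_amp_rate + cnv_del_rate must not exceed 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def stage_rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence((self.seed, _STAGE_KEYS[stage])))


# ---------------------------------------------------------------------------
# terms

def gen_universe_and_terms(config: SimulationConfig):
    """Universe plus n_terms term->gene mappings in n_blocks planted blocks.

    Every term in a block carries the block's shared core (sized so any pair
    meets the configured Jaccard floor); remaining members are random draws,
    so between-block overlap matches independent sampling.

    Returns (universe, terms, blocks) with blocks mapping term id -> block
    number in 1..n_blocks.
    """
    rng = config.stage_rng("terms")
    universe = GeneUniverse(tuple(f"G{i:05d}" for i in range(config.n_genes)))
    gene_arr = np.asarray(universe.genes, dtype=object)
    lo, hi = config.term_size_range
    j = config.within_block_jaccard

    per_block = [config.n_terms // config.n_blocks] * config.n_blocks
    for i in range(config.n_terms % config.n_blocks):
        per_block[i] += 1

    terms: dict[str, list[str]] = {}
    blocks: dict[str, int] = {}
    t = 0
    for b in range(1, config.n_blocks + 1):
        size = int(rng.integers(lo, hi + 1))
        core_size = size if j >= 1.0 else min(size, math.ceil(2 * size * j / (1 + j)))
        core = rng.choice(gene_arr, size=core_size, replace=False)
        rest_pool = np.asarray(sorted(set(gene_arr) - set(core)), dtype=object)
        for _ in range(per_block[b - 1]):
            extra = rng.choice(rest_pool, size=size - core_size, replace=False)
            term_id = f"TERM{t:03d}"
            terms[term_id] = sorted(np.concatenate([core, extra]).tolist())
            blocks[term_id] = b
            t += 1
    return universe, terms, blocks


# ---------------------------------------------------------------------------
# omics gene sets

DEFAULT_SOURCE_BLOCKS = {
    "DEG": (1,),
    "lncRNA": (2,),
    "extraprostatic": (3,),
    "SNV": (4,),
    "methylation": (5,),
    "CNV": (6,),
}


def gen_omics_gene_sets(
    universe: GeneUniverse,
    terms: dict[str, list[str]],
    blocks: dict[str, int],
    config: SimulationConfig,
    source_blocks: dict[str, tuple[int, ...]] | None = None,
    sample_frac: float = 0.6,
    noise_frac: float = 0.1,
) -> list[OmicsGeneSet]:
    """Six named omics sets, each sampled from its assigned blocks' term genes
    plus background noise genes, with signed per-gene logFC values."""
    source_blocks = dict(source_blocks or DEFAULT_SOURCE_BLOCKS)
    unknown = set(source_blocks) - set(SOURCE_NAMES)
    if unknown:
        raise ValueError(f"unknown source name(s): {sorted(unknown)}")
    rng = config.stage_rng("omics")
    n_blocks = config.n_blocks

    out = []
    for name in SOURCE_NAMES:
        assigned = tuple(((b - 1) % n_blocks) + 1 for b in source_blocks.get(name, (1,)))
        pool = sorted({g for t, b in blocks.items() if b in assigned for g in terms[t]})
        n_pick = max(1, int(round(sample_frac * len(pool))))
        picked = sorted(rng.choice(np.asarray(pool, dtype=object), size=n_pick, replace=False).tolist())
        bg_pool = np.asarray(sorted(set(universe.genes) - set(pool)), dtype=object)
        n_noise = int(round(noise_frac * n_pick))
        noise = sorted(rng.choice(bg_pool, size=n_noise, replace=False).tolist()) if n_noise else []
        logfc = {}
        for g in picked:
            logfc[g] = float(abs(rng.normal(2.0, 0.5)))
        for g in noise:
            logfc[g] = float(rng.normal(0.0, 1.0))
        out.append(OmicsGeneSet(name=name, genes=picked + noise, logfc=logfc))
    return out


# ---------------------------------------------------------------------------
# expression

def gen_expression_with_phenotype(
    universe: GeneUniverse,
    module_genes: list[str],
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.Series]:
    """Genes x samples Gaussian expression with +signal_effect added to
    module_genes rows in the designated half of samples."""
    if not module_genes:
        raise ValueError("module_genes must be non-empty")
    if not set(module_genes) <= universe.as_set():
        raise ValueError("module_genes must be a subset of the universe")
    rng = config.stage_rng("expression")
    S = config.n_samples
    samples = [f"S{i:04d}" for i in range(S)]
    X = rng.normal(0.0, config.noise_sd, size=(len(universe), S))
    expr = pd.DataFrame(X, index=list(universe.genes), columns=samples)
    shifted = samples[: S // 2]
    expr.loc[list(module_genes), shifted] += config.signal_effect
    labels = pd.Series(["shifted" if s in set(shifted) else "null" for s in samples],
                       index=samples, name="group")
    return expr, labels


# ---------------------------------------------------------------------------
# CNV and mutations

@dataclass
class CNVSimResult:
    segments: pd.DataFrame
    groups: pd.Series            # tumor / normal per sample
    mutations: pd.DataFrame
    strata: pd.Series            # clinical stratum per sample
    amp_genes: list[str]
    del_genes: list[str]
    mutated_gene: str
    enriched_stratum: str


def gen_cnv_and_mutations(
    universe: GeneUniverse,
    config: SimulationConfig,
    n_planted: int = 10,
    planted_mut_rate_in: float = 0.6,
    planted_mut_rate_out: float = 0.05,
) -> CNVSimResult:
    """Segment values near 0 for all samples, with planted genes whose tumor
    segments land in amplification (CN > 3.5) or deletion (CN < 0.5) ranges at
    the configured rates; a binary mutation matrix with one gene enriched in
    clinical stratum A."""
    rng = config.stage_rng("cnv")
    G = len(universe)
    n = config.n_samples
    tumors = [f"T{i:04d}" for i in range(n)]
    normals = [f"N{i:04d}" for i in range(n)]
    samples = tumors + normals
    genes = list(universe.genes)

    seg = rng.normal(0.0, 0.05, size=(G, 2 * n))
    amp_genes = genes[:n_planted]
    del_genes = genes[n_planted: 2 * n_planted]
    for gi, gene in enumerate(amp_genes):
        hit = rng.random(n) < config.cnv_amp_rate
        seg[gi, :n][hit] = rng.normal(1.3, 0.1, size=int(hit.sum()))
    for off, gene in enumerate(del_genes):
        gi = n_planted + off
        hit = rng.random(n) < config.cnv_del_rate
        seg[gi, :n][hit] = rng.normal(-2.4, 0.1, size=int(hit.sum()))
    segments = pd.DataFrame(seg, index=genes, columns=samples)
    groups = pd.Series(["tumor"] * n + ["normal"] * n, index=samples, name="group")

    strata = pd.Series(
        ["A" if i < n else "B" for i in range(2 * n)], index=samples, name="stratum"
    )
    mut = (rng.random((G, 2 * n)) < config.mutation_rate).astype(np.int64)
    mutated_gene = genes[2 * n_planted]
    gi = 2 * n_planted
    in_a = (strata == "A").to_numpy()
    mut[gi, in_a] = (rng.random(int(in_a.sum())) < planted_mut_rate_in).astype(np.int64)
    mut[gi, ~in_a] = (rng.random(int((~in_a).sum())) < planted_mut_rate_out).astype(np.int64)
    mutations = pd.DataFrame(mut, index=genes, columns=samples)

    return CNVSimResult(
        segments=segments,
        groups=groups,
        mutations=mutations,
        strata=strata,
        amp_genes=amp_genes,
        del_genes=del_genes,
        mutated_gene=mutated_gene,
        enriched_stratum="A",
    )


# ---------------------------------------------------------------------------
# survival and regulons

@dataclass
class SurvivalSimResult:
    survival: pd.DataFrame       # sample, time, event + covariate columns
    covariates: pd.DataFrame     # covariates x samples
    scores: pd.Series            # true linear scores
    regulons: list[Regulon]
    signature: RankedSignature
    active_tf: str


def gen_survival_and_regulons(
    config: SimulationConfig,
    risk_model: RiskModel | None = None,
    n_samples: int = 200,
    effect_scale: float = 1.0,
    n_regulons: int = 50,
    regulon_size: int = 20,
    tf_shift: float = 3.0,
    signature_noise: float = 1.0,
) -> SurvivalSimResult:
    """Survival times with log-hazard proportional to the linear risk score,
    plus 50 signed regulons with one planted active TF reflected in the
    returned ranked signature."""
    if config.censoring_rate >= 1.0:
        raise ValueError("censoring_rate must be < 1")
    model = risk_model or RiskModel()
    rng = config.stage_rng("survival")
    samples = [f"P{i:04d}" for i in range(n_samples)]

    X = rng.normal(0.0, 1.0, size=(len(model.covariates), n_samples))
    cov = pd.DataFrame(X, index=list(model.covariates), columns=samples)
    scores = pd.Series(np.asarray(model.coefficients) @ X, index=samples, name="score")
    hazard = np.exp(effect_scale * scores.to_numpy())
    times = rng.exponential(1.0 / hazard)
    censored = rng.random(n_samples) < config.censoring_rate
    obs_times = np.where(censored, rng.uniform(0.0, times), times)
    surv = pd.DataFrame(
        {"time": obs_times, "event": (~censored).astype(int)}, index=pd.Index(samples, name="sample")
    )
    surv = pd.concat([surv, cov.T], axis=1)
    surv.index.name = "sample"

    genes = [f"G{i:05d}" for i in range(max(config.n_genes, n_regulons * regulon_size // 2))]
    gene_arr = np.asarray(genes, dtype=object)
    regulons = []
    for r in range(n_regulons):
        targets = sorted(rng.choice(gene_arr, size=regulon_size, replace=False).tolist())
        modes = rng.choice([-1.0, 1.0], size=regulon_size).tolist()
        regulons.append(Regulon(tf=f"TF{r + 1:02d}", targets=targets, modes=modes))
    active = regulons[0]
    base = rng.normal(0.0, signature_noise, size=len(genes))
    sig = pd.Series(base, index=genes)
    for g, m in zip(active.targets, active.modes):
        sig[g] += m * tf_shift
    signature = RankedSignature.from_series(sig)

    return SurvivalSimResult(
        survival=surv,
        covariates=cov,
        scores=scores,
        regulons=regulons,
        signature=signature,
        active_tf=active.tf,
    )


# ---------------------------------------------------------------------------
# write everything to disk

def simulate_to_dir(config: SimulationConfig, outdir: str | Path) -> dict:
    """Run every generator and write all pipeline inputs under ``outdir``.

    Returns the ground-truth dictionary (also written as JSON).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    universe, terms, blocks = gen_universe_and_terms(config)
    sources = gen_omics_gene_sets(universe, terms, blocks, config)
    module6_genes = sorted({g for t, b in blocks.items() if b == config.n_blocks for g in terms[t]})
    expr, labels = gen_expression_with_phenotype(universe, module6_genes, config)
    cnv = gen_cnv_and_mutations(universe, config)
    surv = gen_survival_and_regulons(config)

    io.write_universe(universe, outdir / "universe.txt")
    io.write_gmt(terms, outdir / "terms.gmt")
    io.write_gmt({s.name: s.genes for s in sources}, outdir / "sources.gmt")
    for s in sources:
        pd.DataFrame({"gene": s.genes, "logFC": [s.logfc.get(g, 0.0) for g in s.genes]}).to_csv(
            outdir / f"source_{s.name}.tsv", sep="\t", index=False
        )
    io.write_matrix(expr, outdir / "expression.tsv")
    labels.to_frame().to_csv(outdir / "expression_groups.tsv", sep="\t")
    io.write_matrix(cnv.segments, outdir / "segments.tsv")
    io.write_matrix(cnv.mutations, outdir / "mutations.tsv")
    pd.DataFrame({"group": cnv.groups, "stratum": cnv.strata}).rename_axis("sample").to_csv(
        outdir / "clinical.tsv", sep="\t"
    )
    surv.survival.to_csv(outdir / "survival.tsv", sep="\t")
    io.write_matrix(surv.covariates, outdir / "risk_covariates.tsv")
    io.write_regulon_gmt(
        {r.tf: dict(zip(r.targets, r.modes)) for r in surv.regulons}, outdir / "regulons.gmt"
    )
    surv.signature.to_series().rename_axis("gene").to_csv(outdir / "signature.tsv", sep="\t")

    truth = {
        "seed": config.seed,
        "term_blocks": blocks,
        "module_genes": module6_genes,
        "shifted_samples": sorted(labels.index[labels == "shifted"]),
        "amp_genes": cnv.amp_genes,
        "del_genes": cnv.del_genes,
        "mutated_gene": cnv.mutated_gene,
        "enriched_stratum": cnv.enriched_stratum,
        "active_tf": surv.active_tf,
        "source_blocks": {k: list(v) for k, v in DEFAULT_SOURCE_BLOCKS.items()},
    }
    io.write_json(truth, outdir / "ground_truth.json")
    return truth
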