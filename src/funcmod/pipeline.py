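"""End-to-end orchestration: simulate -> enrich -> cluster -> plasticity ->
cnv/snv -> risk -> tf, with a checksummed JSON manifest.

Stages communicate only through files in the output directory, so any stage
can be re-run or inspected in isolation; identical config + seed reproduces
identical checksums.
"""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import clustering, cnv, enrichment, io, scoring, survival, tf
from .synthetic import SimulationConfig, simulate_to_dir

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _checksums(paths: list[Path]) -> dict[str, str]:
    return {p.name: _sha256(p) for p in sorted(paths)}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def run_all(config: dict) -> dict:
    """Execute every stage per the config; returns (and writes) the manifest."""
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    params = dict(config.get("params", {}))
    k = int(params.get("k", 6))
    alpha_p = float(params.get("alpha_p", 0.05))
    alpha_q = float(params.get("alpha_q", 0.05))
    n_perm = int(params.get("n_perm", 200))
    min_hits = int(params.get("min_hits", 14))

    manifest: dict = {"seed": seed, "params": params, "stages": []}

    def record(stage: str, outputs: list[Path], **extra) -> None:
        entry = {"stage": stage, "outputs": _checksums(outputs)}
        entry.update(extra)
        manifest["stages"].append(entry)
        logger.info("stage=%s seed=%d outputs=%d", stage, seed, len(outputs))

    # --- stage 1: inputs -------------------------------------------------
    indir = outdir / "inputs"
    if "simulate" in config:
        sim_cfg = SimulationConfig(seed=seed, **{k_: v for k_, v in (config["simulate"] or {}).items()})
        simulate_to_dir(sim_cfg, indir)
    else:
        indir = Path(config["paths"]["indir"])
    record("simulate", sorted(indir.glob("*")) if indir == outdir / "inputs" else [])

    universe = io.read_universe(indir / "universe.txt")
    terms = io.read_gmt(indir / "terms.gmt")
    truth = io.read_json(indir / "ground_truth.json") if (indir / "ground_truth.json").exists() else {}

    # --- stage 2: enrichment --------------------------------------------
    tables = []
    enrich_paths = []
    for src_path in sorted(indir.glob("source_*.tsv")):
        qset = io.read_query_set(src_path, name=src_path.stem.removeprefix("source_"))
        table = enrichment.enrich_terms(qset, terms, universe, alpha_p=alpha_p, alpha_q=alpha_q)
        out = outdir / f"enrichment_{qset.name}.tsv"
        enrichment.write_enrichment_table(table, out)
        tables.append(table)
        enrich_paths.append(out)
    record("enrich", enrich_paths, alpha_p=alpha_p, alpha_q=alpha_q)

    # --- stage 3: clustering --------------------------------------------
    dm = clustering.build_kappa_distance_matrix(tables, terms, universe)
    tree = clustering.nj_tree(dm)
    partition = clustering.cut_tree(tree, min(k, len(dm.labels)))
    sources = [io.read_query_set(p, name=p.stem.removeprefix("source_"))
               for p in sorted(indir.glob("source_*.tsv"))]
    summary = clustering.summarize_modules(partition, sources, terms, tables)

    (outdir / "tree.nwk").write_text(tree.newick() + "\n")
    pd.DataFrame(
        {"term": list(partition.term_to_module), "module": list(partition.term_to_module.values())}
    ).sort_values(["module", "term"]).to_csv(outdir / "partition.tsv", sep="\t", index=False)
    pd.DataFrame(dm.distance, index=dm.labels, columns=dm.labels).to_csv(
        outdir / "distance.tsv", sep="\t"
    )
    io.write_gmt({f"module{m}": s["genes"] for m, s in summary.items()}, outdir / "modules.gmt")
    io.write_json(
        {str(m): {"terms": s["terms"], "source_counts": s["source_counts"]} for m, s in summary.items()},
        outdir / "module_summary.json",
    )
    cluster_paths = [outdir / p for p in
                     ("tree.nwk", "partition.tsv", "distance.tsv", "modules.gmt", "module_summary.json")]
    record("cluster", cluster_paths, k=partition.n_modules)

    # --- stage 4: plasticity scoring ------------------------------------
    expr = io.read_matrix(indir / "expression.tsv")
    module_genes = truth.get("module_genes") or summary[max(summary)]["genes"]
    module_genes = [g for g in module_genes if g in expr.index]
    control = [g for g in universe.genes if g not in set(module_genes)][:50]
    sconfig = scoring.ScoringConfig(n_perm=n_perm, seed=seed)
    report = scoring.plasticity_pipeline(
        expr,
        plasticity_sets=[module_genes],
        module_genes=module_genes,
        pathway_sets={"planted_module": module_genes, "control_random": control},
        config=sconfig,
    )
    report["plasticity_score"].rename_axis("sample").to_csv(outdir / "plasticity_scores.tsv", sep="\t")
    report["correlation_full"].to_csv(outdir / "gene_trait_correlation.tsv", sep="\t")
    io.write_json(
        {
            name: {"ES": r.ES, "NES": r.NES, "p": r.p, "leading_edge": r.leading_edge}
            for name, r in report["gsea"].items()
        },
        outdir / "gsea_report.json",
    )
    score_paths = [outdir / p for p in
                   ("plasticity_scores.tsv", "gene_trait_correlation.tsv", "gsea_report.json")]
    record("score", score_paths, n_perm=n_perm)

    # --- stage 5: cnv / snv ---------------------------------------------
    segments = io.read_matrix(indir / "segments.tsv")
    mutations = io.read_matrix(indir / "mutations.tsv")
    clinical = pd.read_csv(indir / "clinical.tsv", sep="\t", index_col=0)
    categories = cnv.segment_to_category(segments)
    io.write_matrix(categories, outdir / "cnv_categories.tsv")
    tests = cnv.cnv_association_tests(categories, clinical["group"], expr=None, seed=seed)
    tests.rename_axis("gene").to_csv(outdir / "cnv_tests.tsv", sep="\t")
    sig_genes = list(tests.index[tests["chi2_q"] < 0.05])
    tumor = list(clinical.index[clinical["group"] == "tumor"])
    prevalence = cnv.cnv_prevalence(categories, sig_genes, tumor) if sig_genes else pd.DataFrame(
        columns=["dominant_type", "fraction"]
    )
    prevalence.to_csv(outdir / "cnv_prevalence.tsv", sep="\t")
    mut_gene = truth.get("mutated_gene", mutations.index[0])
    stratum = truth.get("enriched_stratum", sorted(clinical["stratum"].unique())[0])
    counts, p = cnv.mutation_strata_enrichment(mutations, clinical["stratum"], mut_gene, stratum)
    io.write_json(
        {"gene": mut_gene, "stratum": stratum, "N": counts.N, "M": counts.M,
         "n": counts.n, "k": counts.k, "p": p},
        outdir / "snv_enrichment.json",
    )
    cnv_paths = [outdir / p for p in
                 ("cnv_categories.tsv", "cnv_tests.tsv", "cnv_prevalence.tsv", "snv_enrichment.json")]
    record("cnv_snv", cnv_paths, n_significant=len(sig_genes))

    # --- stage 6: risk --------------------------------------------------
    model = survival.RiskModel()
    covariates = io.read_matrix(indir / "risk_covariates.tsv")
    scores = survival.risk_score(covariates, model)
    scores.rename_axis("sample").to_csv(outdir / "risk_scores.tsv", sep="\t")
    surv = io.read_survival(indir / "survival.tsv")
    c = survival.concordance_index(scores["score"], surv)
    io.write_json(
        {"c_index": c, "n": int(len(surv)), "events": int(surv["event"].sum())},
        outdir / "risk_cindex.json",
    )
    record("risk", [outdir / "risk_scores.tsv", outdir / "risk_cindex.json"], c_index=c)

    # --- stage 7: tf ----------------------------------------------------
    regulons = [tf.Regulon.from_mode_dict(name, modes)
                for name, modes in io.read_regulon_gmt(indir / "regulons.gmt").items()]
    sig_series = pd.read_csv(indir / "signature.tsv", sep="\t", index_col=0)["score"]
    signature = scoring.RankedSignature.from_series(sig_series)
    activity = tf.regulon_activity(signature, regulons, n_perm=n_perm, seed=seed)
    activity.to_csv(outdir / "tf_activity.tsv", sep="\t", index=False)
    target_set = [g for g in signature.genes[:20] if g in universe]
    kd = [tf.KnockdownSignature(r.tf, [g for g in r.targets if g in universe]) for r in regulons]
    kd_table = tf.tf_knockdown_enrichment(kd, target_set, universe, min_hits=min_hits)
    kd_table.to_csv(outdir / "tf_enrichment.tsv", sep="\t", index=False)
    record("tf", [outdir / "tf_activity.tsv", outdir / "tf_enrichment.tsv"],
           top_tf=activity["tf"].iloc[0] if not activity.empty else None)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
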