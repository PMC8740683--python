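"""End-to-end analysis on a synthetic study.

Chains every stage: landscape -> network -> per-individual openness
scoring against the baseline genome -> RE-level and gene-level
differential-openness tests -> coding burden and per-gene t tests ->
pathway-level combination -> comparison against the planted ground truth.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .burden import average_scores, burden as burden_matrix, burden_test, \
    filter_rare_nonsyn
from .openness import build_baseline, gene_combine, re_test, score_cohort
from .pathways import coding_term_pvalues, combine_and_rank, noncoding_term_pvalues
from .network import expression_quantiles, write_bed, write_loops
from .pathways import GeneSetCollection, write_gmt
from .simulate import SimConfig, SyntheticStudy, generate_study


@dataclass
class PipelineResult:
    re_results: pd.DataFrame
    gene_results: pd.DataFrame
    burden_p: pd.DataFrame
    term_results: pd.DataFrame
    report: dict


def run_all(
    cfg: SimConfig | None = None,
    outdir=None,
    study: SyntheticStudy | None = None,
    fdr: float = 0.01,
    write_inputs: bool = False,
) -> PipelineResult:
    """Run the full pipeline on a (generated) synthetic study.

    Writes RE, gene and term tables plus a ground-truth comparison report
    when ``outdir`` is given.
    """
    if study is None:
        study = generate_study(cfg or SimConfig())
    cfg = study.cfg
    network = study.network

    # differential openness
    baseline = build_baseline(study.cohort, mode="major_allele")
    matrix = score_cohort(
        study.cohort, study.scored_res, study.scorer, baseline
    )
    re_results = re_test(matrix, study.cohort.labels)
    tested = re_results[re_results["flag"] != "skipped"]
    gene_results = gene_combine(network, tested, k=5, fdr=fdr)

    # coding burden
    ann = average_scores(study.coding_annotations)
    rare = filter_rare_nonsyn(study.coding_cohort, ann)
    g = burden_matrix(
        study.coding_cohort, rare, gene_universe=study.landscape.genes["gene"]
    )
    burden_p = burden_test(g, study.coding_cohort.labels)

    # pathway combination
    universe = set(study.landscape.genes["gene"])
    collection = GeneSetCollection(sets=study.go_sets, universe=universe)
    noncoding_targets = set(gene_results.loc[gene_results["significant"], "gene"])
    if not noncoding_targets:
        # degenerate null run: fall back to the most significant genes so the
        # term-level machinery still executes
        noncoding_targets = set(gene_results.nsmallest(20, "p_combined")["gene"])
    nc_p, folds = noncoding_term_pvalues(noncoding_targets, collection)
    c_p = coding_term_pvalues(burden_p, collection)
    term_results = combine_and_rank(nc_p, c_p, folds)

    report = compare_to_truth(study, gene_results, burden_p, term_results)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        re_results.to_csv(outdir / "re_results.tsv", sep="\t", index=False)
        gene_results.to_csv(outdir / "gene_results.tsv", sep="\t", index=False)
        burden_p.to_csv(outdir / "burden_pvalues.tsv", sep="\t", index=False)
        term_results.to_csv(outdir / "term_results.tsv", sep="\t", index=False)
        quant = expression_quantiles(
            network, study.landscape.fpkm, [0.05, 0.1, 0.25, 0.5, 0.75, 0.9, 0.95]
        )
        quant.to_csv(outdir / "expression_quantiles.tsv", sep="\t")
        with open(outdir / "ground_truth_report.json", "w") as fh:
            json.dump(report, fh, indent=1)
        study.truth.to_json(outdir / "ground_truth.json")
        if write_inputs:
            write_study_inputs(study, outdir / "inputs")
    return PipelineResult(re_results, gene_results, burden_p, term_results, report)


def compare_to_truth(
    study: SyntheticStudy,
    gene_results: pd.DataFrame,
    burden_p: pd.DataFrame,
    term_results: pd.DataFrame,
) -> dict:
    """Planted-signal recovery metrics."""
    truth = study.truth
    sig = set(gene_results.loc[gene_results["significant"], "gene"])
    planted = set(truth.planted_genes)
    recovery = len(sig & planted) / len(planted) if planted else float("nan")

    bp = burden_p.sort_values("p", kind="stable").reset_index(drop=True)
    ranks = {g: i + 1 for i, g in enumerate(bp["gene"])}
    m = len(bp)
    planted_b = [g for g in truth.planted_burden_genes if g in ranks]
    top_decile = (
        float(np.mean([ranks[g] <= m / 10 for g in planted_b]))
        if planted_b else float("nan")
    )

    term_rank = None
    if truth.planted_term and truth.planted_term in set(term_results["term"]):
        term_rank = int(
            term_results.reset_index(drop=True)
            .index[term_results["term"] == truth.planted_term][0] + 1
        )
    return {
        "n_significant_genes": len(sig),
        "planted_gene_recovery": recovery,
        "planted_burden_top_decile": top_decile,
        "planted_term_rank": term_rank,
        "n_genes_tested": int(len(gene_results)),
    }


def write_study_inputs(study: SyntheticStudy, outdir) -> None:
    """Materialize the study as the standard on-disk formats (VCF, BEDPE,
    BED, TSV, GMT) plus the ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_loops(study.landscape.loops, outdir / "loops.bedpe")
    write_bed(study.landscape.peaks, outdir / "peaks.bed")
    write_bed(study.landscape.silencers, outdir / "silencers.bed")
    genes = study.landscape.genes
    with open(outdir / "genes.bed", "w") as fh:
        for r in genes.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene}\t0\t{r.strand}\n")
    pd.Series(study.landscape.fpkm).to_csv(
        outdir / "expression.tsv", sep="\t", header=False
    )
    study.cohort.to_vcf(outdir / "cohort.vcf", outdir / "samples.tsv")
    study.coding_cohort.to_vcf(outdir / "coding.vcf")
    study.coding_annotations.to_csv(
        outdir / "coding_annotations.tsv", sep="\t", index=False
    )
    write_gmt(study.go_sets, outdir / "gene_sets.gmt")
    study.network.to_json(outdir / "network.json")
    study.truth.to_json(outdir / "ground_truth.json")
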