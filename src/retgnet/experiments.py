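"""Study-level experiments: closed-form checks, oracle comparisons,
null calibration, planted-signal recovery, and enrichment direction.

These routines drive the package end to end under controlled synthetic
conditions and return the summary quantities of interest; the test suite
and the reproduction script both call them.
"""
from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats as sps

from .burden import average_scores, burden, burden_test, filter_rare_nonsyn
from .enrichment import (
    annotate_snps,
    bayes_factor,
    exact_grid_logml,
    fit_grid,
    make_grid,
)
from .openness import build_baseline, gene_combine, re_test, score_cohort
from .pipeline import run_all
from .simulate import (
    GwasConfig,
    SimConfig,
    build_synthetic_network,
    gen_cohort,
    gen_landscape,
    gen_openness_model,
    gen_sumstats,
    generate_study,
    planted_res_for,
)
from .stats import fisher_method


# --------------------------------------------------------------------------
# closed-form statistics
# --------------------------------------------------------------------------

def closed_form_checks() -> dict:
    """Reference statistics with their closed-form counterparts."""
    x, p_fisher_method = fisher_method([0.05, 0.05])
    chi2_closed = math.exp(-x / 2) * (1 + x / 2)

    from .pathways import poisson_term_test

    p_poisson = poisson_term_test(8, 50, 0.05)
    lam, total, term = 2.5, 0.0, math.exp(-2.5)
    for i in range(8):
        total += term
        term *= lam / (i + 1)
    poisson_series = 1.0 - total

    p_exact = float(sps.hypergeom.sf(2, 20, 3, 10))
    return {
        "fisher_method_p": p_fisher_method,
        "fisher_method_closed_form": chi2_closed,
        "poisson_term_p": p_poisson,
        "poisson_series_oracle": poisson_series,
        "fisher_exact_p": p_exact,
        "fisher_exact_expected": 120 / 1140,
    }


# --------------------------------------------------------------------------
# oracle equivalence
# --------------------------------------------------------------------------

def oracle_equivalence(seed: int = 3) -> dict:
    """Variational log marginals vs exact 2^p enumeration (p=10, identity
    and AR(1) LD, 5 grid points), and the burden matrix vs a loop-based
    recomputation."""
    cfg = SimConfig(seed=seed, gwas=GwasConfig(
        n=5000, p_snps=10, ld_block=5, ld_rho=0.4, theta0=0.05, theta=0.2,
        sigma0sq=2e-3))
    rng = np.random.default_rng(seed)
    a = (rng.uniform(size=10) < 0.5).astype(np.int8)
    stats, R, _ = gen_sumstats(cfg, a)
    grid = make_grid([0.05, 0.1], [0.0, 0.2], [2e-3], [0.0, 1.0]).iloc[:5]
    max_gap = 0.0
    elbo_le_exact = True
    for ld in (np.eye(10), R):
        fit = fit_grid(stats, ld, a, grid)
        exact = exact_grid_logml(stats, ld, a, grid)
        diff = fit.grid["logml"].to_numpy() - exact
        max_gap = max(max_gap, float(np.abs(diff).max()))
        elbo_le_exact = elbo_le_exact and bool(np.all(diff <= 1e-9))

    # burden matrix vs brute force
    study = generate_study(SimConfig(
        seed=seed, n_genes=80, n_loops=40, planted_re_count=4,
        planted_burden_genes=3, n_cases=40, n_controls=20))
    ann = average_scores(study.coding_annotations)
    rare = filter_rare_nonsyn(study.coding_cohort, ann)
    g = burden(study.coding_cohort, rare)
    d = study.coding_cohort.dosage
    burden_gap = 0.0
    for m, sample in enumerate(study.coding_cohort.samples):
        expected: dict[str, float] = {}
        for row in rare.itertuples(index=False):
            if d[row.variant_idx, m] >= 1:
                expected[row.gene] = expected.get(row.gene, 0.0) + row.s
        for gene in g.index:
            burden_gap = max(
                burden_gap, abs(float(g.loc[gene, sample]) - expected.get(gene, 0.0))
            )
    return {
        "vi_vs_exact_max_gap_nats": max_gap,
        "elbo_below_exact": elbo_le_exact,
        "burden_vs_bruteforce_max_gap": burden_gap,
    }


# --------------------------------------------------------------------------
# null calibration
# --------------------------------------------------------------------------

def _openness_only(cfg: SimConfig):
    landscape, truth = gen_landscape(cfg)
    network = build_synthetic_network(cfg, landscape)
    if cfg.planted_re_count:
        planted_res_for(cfg, landscape, network, truth)
    anchor = sorted(
        (e for e in network.elements.values() if e.source == "loop_anchor"),
        key=lambda e: e.re_id,
    )
    prom = sorted(
        (e for e in network.elements.values() if e.source == "promoter"),
        key=lambda e: e.re_id,
    )
    scored = anchor + prom
    cohort, meta = gen_cohort(cfg, scored, truth)
    scorer = gen_openness_model(cfg, scored, cohort, meta, truth)
    return landscape, network, scored, cohort, scorer


def null_calibration(n_seeds: int = 10, n_res: int = 2000,
                     base_seed: int = 0) -> dict:
    """Null cohorts (no planted effects, 200 cases / 100 controls): pooled
    RE-level combined p-values over the first ``n_res`` loop-anchor REs per
    seed, their KS distance from uniform, the fraction below 0.05, and the
    number of BH-significant genes per seed."""
    pooled = []
    genes_sig = []
    n_tested_total = 0
    for seed in range(base_seed, base_seed + n_seeds):
        cfg = SimConfig(seed=seed, n_cases=200, n_controls=100,
                        planted_re_count=0)
        _, network, scored, cohort, scorer = _openness_only(cfg)
        baseline = build_baseline(cohort)
        matrix = score_cohort(cohort, scored, scorer, baseline)
        res = re_test(matrix, cohort.labels)
        anchor_ids = [e.re_id for e in scored if e.source == "loop_anchor"][:n_res]
        sub = res[res["re_id"].isin(set(anchor_ids))]
        tested = sub[sub["flag"] != "skipped"]
        pooled.append(tested["p_combined"].to_numpy())
        n_tested_total += len(tested)
        all_tested = res[res["flag"] != "skipped"]
        genes = gene_combine(network, all_tested, k=5, fdr=0.01)
        genes_sig.append(int(genes["significant"].sum()))
    pooled = np.concatenate(pooled)
    ks = sps.kstest(pooled, "uniform")
    return {
        "ks_D": float(ks.statistic),
        "ks_p": float(ks.pvalue),
        "frac_p_below_0.05": float((pooled < 0.05).mean()),
        "n_tested_res": int(n_tested_total),
        "significant_genes_per_seed": genes_sig,
        "seeds_with_zero_significant": int(sum(g == 0 for g in genes_sig)),
        "n_seeds": n_seeds,
    }


# --------------------------------------------------------------------------
# planted recovery
# --------------------------------------------------------------------------

def planted_recovery(n_seeds: int = 10, base_seed: int = 0) -> dict:
    """Default planted configuration over seeds: fraction of planted target
    genes recovered at q<0.01, fraction of planted burden genes in the top
    decile of coding p, and the rank of the planted GO term."""
    recoveries, deciles, ranks = [], [], []
    for seed in range(base_seed, base_seed + n_seeds):
        result = run_all(SimConfig(seed=seed))
        r = result.report
        recoveries.append(r["planted_gene_recovery"])
        deciles.append(r["planted_burden_top_decile"])
        ranks.append(r["planted_term_rank"])
    return {
        "recovery_per_seed": recoveries,
        "mean_recovery": float(np.mean(recoveries)),
        "burden_top_decile_per_seed": deciles,
        "mean_burden_top_decile": float(np.mean(deciles)),
        "term_rank_per_seed": ranks,
        "seeds_term_first": int(sum(r == 1 for r in ranks)),
        "n_seeds": n_seeds,
    }


# --------------------------------------------------------------------------
# enrichment direction
# --------------------------------------------------------------------------

def enrichment_direction(n_seeds: int = 10, base_seed: int = 0) -> dict:
    """Summary statistics simulated with theta>0 on a network annotation:
    BF(M11:M0) against the same fit under a permuted annotation."""
    n = 20_000
    grid = make_grid([1e-3, 5e-3, 0.02], [0.0, 0.01, 0.03, 0.06],
                     [10 / n, 25 / n, 50 / n], [0.0])
    bfs, bfs_perm = [], []
    for seed in range(base_seed, base_seed + n_seeds):
        cfg = SimConfig(seed=seed, n_genes=300, n_loops=150,
                        planted_re_count=0)
        landscape, truth = gen_landscape(cfg)
        network = build_synthetic_network(cfg, landscape)
        landscape_span = 200_000 + cfg.n_genes * cfg.gene_spacing_bp \
            + 1_000_000 + cfg.n_loops * (cfg.anchor_size + 1000)
        # sample SNPs over 3x the landscape: the region beyond it is a
        # regulatory desert, so the annotation splits the SNPs
        rng = cfg.rng("snp-positions")
        pos = np.sort(rng.choice(3 * landscape_span, size=cfg.gwas.p_snps,
                                 replace=False))
        snps = pd.DataFrame({"chrom": "chr1", "pos": pos})
        a = annotate_snps(snps, network=network, genes=landscape.genes)
        stats, R, _ = gen_sumstats(cfg, a)
        bfs.append(bayes_factor(fit_grid(stats, R, a, grid), "M11"))
        a_perm = rng.permutation(a)
        bfs_perm.append(bayes_factor(fit_grid(stats, R, a_perm, grid), "M11"))
    wins = sum(
        (b > 1 and b > bp) for b, bp in zip(bfs, bfs_perm)
    )
    return {
        "bf_per_seed": bfs,
        "bf_permuted_per_seed": bfs_perm,
        "median_bf": float(np.median(bfs)),
        "median_bf_permuted": float(np.median(bfs_perm)),
        "seeds_network_above_permuted": int(wins),
        "n_seeds": n_seeds,
    }
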