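"""Seeded generators for every input the pipeline consumes.

The generators emulate the shapes of the real study inputs: H3K27ac-loop
calls with q-values, ATAC peaks, gene models with strand and TSS,
silencers, FPKM expression, a WGS case/control cohort (268 cases / 133
controls by default) with Hardy-Weinberg genotypes, a sparse linear
openness scorer (most individuals score exactly at the baseline), planted
case-enriched openness alleles in selected REs, planted high-burden genes
with case-private deleterious coding SNVs, GO-style gene sets with one
term enriched for the planted genes, and GWAS summary statistics drawn
from the network-modulated spike-and-slab effect-size prior with
block-AR(1) LD.

Every generator is a pure function of the configuration: one global seed
fans out to independent per-stage streams via CRC-32 of the stage name,
so stages can be regenerated independently and regeneration is
byte-identical.
"""
from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortGenotypes
from .intervals import GenomicInterval, Loop, RegulatoryElement, ValidationError
from .network import RETGNetwork, build_network, make_promoters, tile_and_classify
from .openness import LinearScorer

BASES = ("A", "C", "G", "T")


@dataclass
class GwasConfig:
    """Summary-statistics simulation: sample size, SNP count, the generating
    hyperparameters of the effect-size prior, and block-AR(1) LD."""

    n: int = 20_000
    p_snps: int = 800
    theta0: float = 0.004
    theta: float = 0.05
    sigma0sq: float = 1.5e-3  # n * sigma0^2 = 30: a typical strong GWAS hit
    sigmasq: float = 0.0
    ld_block: int = 10
    ld_rho: float = 0.3


@dataclass
class SimConfig:
    """Study-shaped synthetic-data configuration.

    Cohort sizes default to the study shape (268 cases, 133 controls).
    ``carrier_freq_case``/``carrier_freq_control`` are the per-group
    frequencies of the planted case-enriched openness-shifting allele.
    Background openness effects are sparse (``weighted_rate`` expected
    weighted variants per RE), so most individuals score exactly at the
    baseline genome.
    """

    seed: int = 0
    n_cases: int = 268
    n_controls: int = 133
    n_genes: int = 1000
    n_loops: int = 400
    anchor_size: int = 5000
    tile_size: int = 1000
    fraction_open: float = 0.6
    loop_q_above_frac: float = 0.1
    loop_gene_fraction: float = 0.4
    gene_body_bp: int = 20_000
    gene_spacing_bp: int = 60_000
    # openness model
    planted_re_count: int = 20
    planted_effect_weight: float = 0.7
    carrier_freq_case: float = 0.15
    carrier_freq_control: float = 0.03
    weighted_rate: float = 0.15
    unweighted_rate: float = 2.0
    weighted_af_max: float = 0.1
    # coding burden
    planted_burden_genes: int = 10
    coding_snvs_per_gene: float = 3.0
    planted_case_snvs: int = 12
    score_missing_rate: float = 0.05
    # gene sets
    n_go_terms: int = 50
    go_size_min: int = 10
    go_size_max: int = 60
    gwas: GwasConfig = field(default_factory=GwasConfig)

    def rng(self, stage: str) -> np.random.Generator:
        """Per-stage stream: seeded by (seed, crc32(stage))."""
        return np.random.default_rng([self.seed, zlib.crc32(stage.encode())])


@dataclass
class GroundTruth:
    """Planted signals, serialized alongside every generated dataset."""

    planted_res: list = field(default_factory=list)
    planted_genes: list = field(default_factory=list)
    planted_variants: list = field(default_factory=list)
    planted_burden_genes: list = field(default_factory=list)
    planted_term: str = ""
    gwas_params: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=str)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["planted_variants"] = [tuple(v) for v in d["planted_variants"]]
        return cls(**d)


@dataclass
class Landscape:
    """Generated regulatory landscape: gene models, loops (with q-values,
    including a fraction above the significance threshold), peaks,
    silencers and an FPKM table."""

    genes: pd.DataFrame
    loops: list
    peaks: list
    silencers: list
    fpkm: dict
    planted_loop_of_gene: dict = field(default_factory=dict)


def _truncated_beta(rng, a, b, lo, hi, size):
    x = rng.beta(a, b, size=size)
    # resample out-of-range draws; clip the stragglers
    for _ in range(20):
        bad = (x < lo) | (x > hi)
        if not bad.any():
            break
        x[bad] = rng.beta(a, b, size=bad.sum())
    return np.clip(x, lo, hi)


def gen_landscape(cfg: SimConfig) -> tuple[Landscape, GroundTruth]:
    """Gene models, loops, peaks, silencers and expression.

    Anchors are ``anchor_size`` (5 kb) wide; a ``fraction_open`` share of
    distal anchors is covered by an ATAC peak; ~``loop_q_above_frac`` of
    loops get q-values above 0.01 to exercise the significance filter.
    OpenLoop genes' FPKM is drawn from a higher log-normal (and with fewer
    exact zeros) than NonOpenLoop/NoLoop genes.
    """
    rng = cfg.rng("landscape")
    truth = GroundTruth()

    strands = rng.choice(["+", "-"], size=cfg.n_genes)
    rows = []
    for i in range(cfg.n_genes):
        body_start = 200_000 + i * cfg.gene_spacing_bp
        body_end = body_start + cfg.gene_body_bp
        tss = body_start if strands[i] == "+" else body_end
        rows.append((f"G{i:04d}", "chr1", body_start, body_end, strands[i], tss))
    genes = pd.DataFrame(
        rows, columns=["gene", "chrom", "start", "end", "strand", "tss"]
    )

    n_loop_genes = int(round(cfg.loop_gene_fraction * cfg.n_genes))
    loop_genes = list(rng.choice(genes["gene"], size=n_loop_genes, replace=False))
    if cfg.planted_re_count > 0:
        planted_genes = list(rng.choice(loop_genes, size=cfg.planted_re_count,
                                        replace=False))
    else:
        planted_genes = []
    truth.planted_genes = planted_genes

    # distal anchors in a dedicated zone beyond the gene region, one per loop
    distal_zone = 200_000 + cfg.n_genes * cfg.gene_spacing_bp + 1_000_000
    gene_info = genes.set_index("gene")

    loop_assignments = planted_genes + list(
        rng.choice(loop_genes, size=cfg.n_loops - len(planted_genes), replace=True)
    )
    loops: list[Loop] = []
    peaks: list[GenomicInterval] = []
    open_anchor: list[bool] = []
    planted_loop_of_gene: dict[str, int] = {}
    for li, gene in enumerate(loop_assignments):
        tss = int(gene_info.loc[gene, "tss"])
        prom_anchor = GenomicInterval("chr1", max(0, tss - 3000), tss + 2000)
        d0 = distal_zone + li * (cfg.anchor_size + 1000)
        distal = GenomicInterval("chr1", d0, d0 + cfg.anchor_size)
        if li < len(planted_genes):
            q = float(10 ** rng.uniform(-6, -2.5))  # planted loops always pass
            planted_loop_of_gene[gene] = li
        elif rng.uniform() < cfg.loop_q_above_frac:
            q = float(rng.uniform(0.011, 0.2))
        else:
            q = float(10 ** rng.uniform(-6, -2.5))
        loops.append(Loop(prom_anchor, distal, q))
        is_open = bool(rng.uniform() < cfg.fraction_open)
        open_anchor.append(is_open)
        if is_open:
            off = int(rng.integers(0, cfg.anchor_size - 1500))
            peaks.append(GenomicInterval("chr1", d0 + off, d0 + off + 1500))

    # silencers: overlap ~10% of distal anchors plus scattered background
    silencers = []
    for li in rng.choice(cfg.n_loops, size=max(1, cfg.n_loops // 10), replace=False):
        d0 = distal_zone + int(li) * (cfg.anchor_size + 1000)
        silencers.append(GenomicInterval("chr1", d0 + 500, d0 + 1500))
    for _ in range(20):
        s0 = int(rng.integers(0, 150_000))
        silencers.append(GenomicInterval("chr1", s0, s0 + 1000))

    # expression: OpenLoop genes higher and less often zero
    gene_open: dict[str, bool] = {}
    gene_looped: set[str] = set()
    for (gene, is_open) in zip(loop_assignments, open_anchor):
        gene_looped.add(gene)
        gene_open[gene] = gene_open.get(gene, False) or is_open
    fpkm = {}
    for gene in genes["gene"]:
        if gene in gene_looped and gene_open[gene]:
            value = 0.0 if rng.uniform() < 0.2 else float(rng.lognormal(2.0, 1.2))
        elif gene in gene_looped:
            value = 0.0 if rng.uniform() < 0.6 else float(rng.lognormal(0.0, 1.0))
        else:
            value = 0.0 if rng.uniform() < 0.5 else float(rng.lognormal(0.5, 1.0))
        fpkm[gene] = round(value, 3)

    return (
        Landscape(genes=genes, loops=loops, peaks=peaks, silencers=silencers,
                  fpkm=fpkm, planted_loop_of_gene=planted_loop_of_gene),
        truth,
    )


def significant_loops(cfg: SimConfig, landscape: Landscape, q: float = 0.01):
    return [lp for lp in landscape.loops if lp.q_value < q]


def build_synthetic_network(cfg: SimConfig, landscape: Landscape) -> RETGNetwork:
    """Network from the generated landscape at the q<0.01 loop threshold."""
    loops = significant_loops(cfg, landscape)
    res = tile_and_classify(loops, landscape.peaks, cfg.tile_size)
    promoters = make_promoters(landscape.genes)
    return build_network(loops, promoters, res, peaks=landscape.peaks)


def planted_res_for(cfg: SimConfig, landscape: Landscape,
                    network: RETGNetwork, truth: GroundTruth) -> None:
    """Mark the middle distal-anchor tile of each planted gene's loop as the
    planted RE; records re_ids into the ground truth."""
    planted = []
    for gene in truth.planted_genes:
        li = landscape.planted_loop_of_gene[gene]
        distal = landscape.loops[li].anchor2
        mid0 = distal.start + (distal.width // (2 * cfg.tile_size)) * cfg.tile_size
        candidates = [
            e for e in network.elements.values()
            if e.source == "loop_anchor" and e.interval.start == mid0
            and e.interval.chrom == distal.chrom
        ]
        if not candidates:
            raise ValidationError(f"planted tile missing for gene {gene}")
        planted.append(candidates[0].re_id)
    truth.planted_res = planted


def gen_cohort(
    cfg: SimConfig, res: list, truth: GroundTruth
) -> tuple[CohortGenotypes, pd.DataFrame]:
    """Cohort genotypes with variants placed inside the given REs.

    Background variants: alt allele frequency ~ Beta(0.5, 5) truncated to
    [0.001, 0.5]; Hardy-Weinberg genotypes shared by cases and controls.
    A sparse subset (expected ``weighted_rate`` per RE, drawn from the
    rarer end, AF <= ``weighted_af_max``) is flagged for nonzero openness
    weights. Planted REs get one extra variant whose alt allele has
    frequency ``carrier_freq_case`` in cases and ``carrier_freq_control``
    in controls. Returns the cohort plus per-variant metadata
    (re_id, weighted, planted).
    """
    rng = cfg.rng("cohort")
    n = cfg.n_cases + cfg.n_controls
    samples = [f"case{i:04d}" for i in range(cfg.n_cases)] + [
        f"ctrl{i:04d}" for i in range(cfg.n_controls)
    ]
    labels = np.array(["case"] * cfg.n_cases + ["control"] * cfg.n_controls)
    # AAA skews male; controls balanced
    sex = np.concatenate([
        np.where(rng.uniform(size=cfg.n_cases) < 0.8, "M", "F"),
        np.where(rng.uniform(size=cfg.n_controls) < 0.5, "M", "F"),
    ])

    planted_res = set(truth.planted_res)
    used_positions: set[tuple[str, int]] = set()
    v_rows, dosages, meta_rows = [], [], []
    for re in res:
        iv = re.interval
        n_w = rng.poisson(cfg.weighted_rate)
        n_u = rng.poisson(cfg.unweighted_rate)
        extra = 1 if re.re_id in planted_res else 0
        total = n_w + n_u + extra
        if total == 0:
            continue
        # REs may overlap (promoters vs promoter-side anchor tiles); keep
        # the variant site map globally collision-free
        free = [p for p in range(iv.start, iv.end)
                if (iv.chrom, p) not in used_positions]
        positions = rng.choice(free, size=min(total, len(free)), replace=False)
        positions = np.sort(positions)
        used_positions.update((iv.chrom, int(p)) for p in positions)
        kinds = ["weighted"] * n_w + ["unweighted"] * n_u + ["planted"] * extra
        rng.shuffle(kinds)
        for pos, kind in zip(positions, kinds):
            ref, alt = rng.choice(BASES, size=2, replace=False)
            if kind == "planted":
                fc, fk = cfg.carrier_freq_case, cfg.carrier_freq_control
                geno = np.concatenate([
                    rng.binomial(2, fc, cfg.n_cases),
                    rng.binomial(2, fk, cfg.n_controls),
                ]).astype(np.int8)
                truth.planted_variants.append((iv.chrom, int(pos), str(ref), str(alt)))
            else:
                hi = cfg.weighted_af_max if kind == "weighted" else 0.5
                af = float(_truncated_beta(rng, 0.5, 5.0, 0.001, hi, 1)[0])
                geno = rng.binomial(2, af, n).astype(np.int8)
            v_rows.append((iv.chrom, int(pos), str(ref), str(alt)))
            dosages.append(geno)
            meta_rows.append((re.re_id, kind == "weighted" or kind == "planted",
                              kind == "planted"))
    variants = pd.DataFrame(v_rows, columns=["chrom", "pos", "ref", "alt"])
    meta = pd.DataFrame(meta_rows, columns=["re_id", "weighted", "planted"])
    cohort = CohortGenotypes(
        samples=samples, labels=labels, sex=sex, variants=variants,
        dosage=np.vstack(dosages) if dosages else np.zeros((0, n), dtype=np.int8),
    )
    return cohort, meta


def gen_openness_model(
    cfg: SimConfig, res: list, cohort: CohortGenotypes, meta: pd.DataFrame,
    truth: GroundTruth,
) -> LinearScorer:
    """Sparse additive openness scorer.

    score(RE, variant set) = base(RE) + sum of weights of carried weighted
    variants. Background weights are signed Uniform(0.05, 0.5) snapped to
    the 1/256 grid (exactly representable in binary); the planted variant
    in each planted RE gets weight ``planted_effect_weight``. All other
    variants have weight zero.
    """
    rng = cfg.rng("openness")
    base = {
        re.re_id: float(np.round(rng.uniform(1.0, 5.0) * 256) / 256) for re in res
    }
    weights = {}
    keys = cohort.variant_keys()
    for i, (is_w, is_p) in enumerate(zip(meta["weighted"], meta["planted"])):
        if not is_w:
            continue
        if is_p:
            weights[keys[i]] = float(cfg.planted_effect_weight)
        else:
            w = rng.uniform(0.05, 0.5) * rng.choice([-1.0, 1.0])
            weights[keys[i]] = float(np.round(w * 256) / 256)
    return LinearScorer(base=base, weights=weights)


def gen_coding_scores(
    cfg: SimConfig, cohort: CohortGenotypes, genes: pd.DataFrame,
    truth: GroundTruth,
) -> tuple[CohortGenotypes, pd.DataFrame]:
    """Coding SNVs with three predictor scores, as a separate genotype set
    sharing the cohort's samples.

    Background: ~``coding_snvs_per_gene`` rare nonsynonymous SNVs per gene
    in both groups (plus occasional common and synonymous SNVs to exercise
    filtering), scores Uniform(0,1) with ``score_missing_rate`` missing per
    predictor. Planted burden genes get ``planted_case_snvs`` case-private
    SNVs with scores Uniform(0.7, 1).
    """
    rng = cfg.rng("coding")
    n = cohort.n_samples
    case_idx = np.flatnonzero(cohort.case_mask)
    if not truth.planted_burden_genes:
        pool = [g for g in genes["gene"] if g not in set(truth.planted_genes)]
        truth.planted_burden_genes = list(
            rng.choice(pool, size=cfg.planted_burden_genes, replace=False)
        )
    planted = set(truth.planted_burden_genes)

    v_rows, dosages, ann_rows = [], [], []

    def add_variant(chrom, pos, gene, consequence, score_low):
        ref, alt = rng.choice(BASES, size=2, replace=False)
        scores = rng.uniform(score_low, 1.0, size=3)
        miss = rng.uniform(size=3) < cfg.score_missing_rate
        if miss.all():
            miss[rng.integers(0, 3)] = False
        scores = [np.nan if m else round(float(s), 4) for s, m in zip(scores, miss)]
        ann_rows.append((chrom, int(pos), str(ref), str(alt), gene, consequence,
                         *scores))
        return str(ref), str(alt)

    for row in genes.itertuples(index=False):
        span = np.arange(row.start, row.end)
        n_bg = rng.poisson(cfg.coding_snvs_per_gene)
        n_common = rng.poisson(0.3)
        n_syn = rng.poisson(0.5)
        n_planted = cfg.planted_case_snvs if row.gene in planted else 0
        total = n_bg + n_common + n_syn + n_planted
        if total == 0:
            continue
        positions = np.sort(rng.choice(span, size=total, replace=False))
        kinds = (["rare"] * n_bg + ["common"] * n_common + ["syn"] * n_syn
                 + ["planted"] * n_planted)
        rng.shuffle(kinds)
        for pos, kind in zip(positions, kinds):
            if kind == "planted":
                ref, alt = add_variant(row.chrom, pos, row.gene, "nonsynonymous", 0.7)
                geno = np.zeros(n, dtype=np.int8)
                k = rng.integers(1, 4)  # 1-3 case carriers, case-private
                geno[rng.choice(case_idx, size=k, replace=False)] = 1
            else:
                if kind == "common":
                    af = float(rng.uniform(0.02, 0.2))
                    ref, alt = add_variant(row.chrom, pos, row.gene,
                                           "nonsynonymous", 0.0)
                elif kind == "syn":
                    af = float(_truncated_beta(rng, 0.5, 5.0, 0.001, 0.01, 1)[0])
                    ref, alt = add_variant(row.chrom, pos, row.gene,
                                           "synonymous", 0.0)
                else:
                    af = float(_truncated_beta(rng, 0.5, 5.0, 0.001, 0.008, 1)[0])
                    ref, alt = add_variant(row.chrom, pos, row.gene,
                                           "nonsynonymous", 0.0)
                geno = rng.binomial(2, af, n).astype(np.int8)
            v_rows.append((row.chrom, int(pos), ref, alt))
            dosages.append(geno)

    coding = CohortGenotypes(
        samples=list(cohort.samples), labels=cohort.labels.copy(),
        sex=cohort.sex.copy(),
        variants=pd.DataFrame(v_rows, columns=["chrom", "pos", "ref", "alt"]),
        dosage=np.vstack(dosages) if dosages else np.zeros((0, n), dtype=np.int8),
    )
    annotations = pd.DataFrame(
        ann_rows,
        columns=["chrom", "pos", "ref", "alt", "gene", "consequence",
                 "score1", "score2", "score3"],
    )
    return coding, annotations


def gen_go_sets(cfg: SimConfig, gene_universe, truth: GroundTruth) -> dict:
    """Random gene sets plus one term seeded with the planted genes
    (noncoding targets and burden genes)."""
    rng = cfg.rng("gosets")
    universe = sorted(gene_universe)
    sets = {}
    for t in range(cfg.n_go_terms - 1):
        size = int(rng.integers(cfg.go_size_min, cfg.go_size_max + 1))
        sets[f"GO:S{t:04d}"] = set(rng.choice(universe, size=size, replace=False))
    planted = sorted(set(truth.planted_genes) | set(truth.planted_burden_genes))
    size = max(cfg.go_size_min, len(planted) + 10)
    fillers = [g for g in universe if g not in planted]
    term = set(planted) | set(rng.choice(fillers, size=size - len(planted),
                                         replace=False))
    term_id = f"GO:S{cfg.n_go_terms - 1:04d}"
    sets[term_id] = term
    truth.planted_term = term_id
    return sets


def ar1_block_ld(p: int, block: int, rho: float) -> np.ndarray:
    """Block-diagonal LD with AR(1) correlation rho^|i-j| within blocks."""
    R = np.eye(p)
    for b0 in range(0, p, block):
        b1 = min(b0 + block, p)
        idx = np.arange(b0, b1)
        R[np.ix_(idx, idx)] = rho ** np.abs(idx[:, None] - idx[None, :])
    return R


def gen_sumstats(
    cfg: SimConfig, annotation: np.ndarray, positions: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, np.ndarray, dict]:
    """GWAS summary statistics under the effect-size prior.

    beta_j ~ pi_j N(0, sigma_j^2) + (1-pi_j) delta_0 with
    pi_j = theta0 + a_j theta, sigma_j^2 = sigma0^2 + a_j sigma^2;
    betahat ~ N(S R S^{-1} beta, S R S) with s_j = 1/sqrt(n).
    Returns (stats frame, LD matrix, generating parameters).
    """
    g = cfg.gwas
    rng = cfg.rng("sumstats")
    a = np.asarray(annotation, dtype=np.int8)
    p = len(a)
    pi = g.theta0 + a * g.theta
    if np.any((pi <= 0) | (pi >= 1)):
        raise ValidationError("generating pi outside (0,1)")
    sigma2 = g.sigma0sq + a * g.sigmasq
    include = rng.uniform(size=p) < pi
    beta = np.where(include, rng.normal(0.0, np.sqrt(sigma2)), 0.0)

    R = ar1_block_ld(p, g.ld_block, g.ld_rho)
    se = np.full(p, 1.0 / np.sqrt(g.n))
    L = np.linalg.cholesky(R + 1e-12 * np.eye(p))
    mean = se * (R @ (beta / se))  # S R S^{-1} beta
    betahat = mean + se * (L @ rng.standard_normal(p))

    if positions is None:
        stats = pd.DataFrame({
            "snp_id": [f"rs{j:05d}" for j in range(p)],
            "chrom": "chr1",
            "pos": np.arange(p) * 1000,
        })
    else:
        stats = positions.copy()
    stats["betahat"] = betahat
    stats["se"] = se
    stats["n"] = g.n
    params = {
        "theta0": g.theta0, "theta": g.theta, "sigma0sq": g.sigma0sq,
        "sigmasq": g.sigmasq, "n_causal": int(include.sum()),
    }
    return stats, R, params


@dataclass
class SyntheticStudy:
    """Everything one pipeline run needs, with its ground truth."""

    cfg: SimConfig
    landscape: Landscape
    network: RETGNetwork
    scored_res: list
    cohort: CohortGenotypes
    variant_meta: pd.DataFrame
    scorer: LinearScorer
    coding_cohort: CohortGenotypes
    coding_annotations: pd.DataFrame
    go_sets: dict
    truth: GroundTruth


def generate_study(cfg: SimConfig) -> SyntheticStudy:
    """Generate a full synthetic study (landscape, network, cohort,
    openness model, coding scores, GO sets) with planted ground truth."""
    landscape, truth = gen_landscape(cfg)
    network = build_synthetic_network(cfg, landscape)
    planted_res_for(cfg, landscape, network, truth)
    # scored REs: loop-anchor tiles plus every gene's promoter
    anchor_res = [e for e in network.elements.values() if e.source == "loop_anchor"]
    prom_res = [e for e in network.elements.values() if e.source == "promoter"]
    scored = sorted(anchor_res, key=lambda e: e.re_id) + sorted(
        prom_res, key=lambda e: e.re_id
    )
    cohort, meta = gen_cohort(cfg, scored, truth)
    scorer = gen_openness_model(cfg, scored, cohort, meta, truth)
    coding, annotations = gen_coding_scores(cfg, cohort, landscape.genes, truth)
    go_sets = gen_go_sets(cfg, landscape.genes["gene"], truth)
    return SyntheticStudy(
        cfg=cfg, landscape=landscape, network=network, scored_res=scored,
        cohort=cohort, variant_meta=meta, scorer=scorer, coding_cohort=coding,
        coding_annotations=annotations, go_sets=go_sets, truth=truth,
    )


def gen_external_pool(cfg: SimConfig, cohort: CohortGenotypes,
                      n_pool: int = 600) -> CohortGenotypes:
    """External healthy-control pool sharing the cohort's variant sites
    (plus a few pool-private variants, to exercise their removal)."""
    rng = cfg.rng("external")
    af = cohort.allele_frequency()
    n_v = cohort.n_variants
    dosage = rng.binomial(2, np.clip(af, 1e-4, 1 - 1e-4)[:, None],
                          (n_v, n_pool)).astype(np.int8)
    variants = cohort.variants.copy()
    # pool-private variants on a separate chromosome
    priv_rows, priv_dos = [], []
    for i in range(25):
        pos = 1000 + i * 10
        ref, alt = rng.choice(BASES, size=2, replace=False)
        priv_rows.append(("chrP", pos, str(ref), str(alt)))
        geno = np.zeros(n_pool, dtype=np.int8)
        geno[rng.choice(n_pool, size=3, replace=False)] = 1
        priv_dos.append(geno)
    variants = pd.concat(
        [variants, pd.DataFrame(priv_rows, columns=["chrom", "pos", "ref", "alt"])],
        ignore_index=True,
    )
    dosage = np.vstack([dosage, np.vstack(priv_dos)])
    return CohortGenotypes(
        samples=[f"ext{i:04d}" for i in range(n_pool)],
        labels=np.array(["control"] * n_pool),
        sex=np.where(rng.uniform(size=n_pool) < 0.5, "M", "F"),
        variants=variants,
        dosage=dosage,
    )
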