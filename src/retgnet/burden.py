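"""Per-gene mutation burden from rare nonsynonymous SNVs.

The burden of gene i in sample m is the sum of averaged deleteriousness
scores over the rare nonsynonymous SNVs of that gene the sample carries
(dosage >= 1). Case/control differences are tested per gene with a
one-tailed Welch t test (case mean > control mean).
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import CohortGenotypes
from .intervals import ValidationError

logger = logging.getLogger(__name__)

SCORE_COLUMNS = ["score1", "score2", "score3"]
ANNOTATION_COLUMNS = ["chrom", "pos", "ref", "alt", "gene", "consequence"]


def read_annotations(path) -> pd.DataFrame:
    """Read a variant annotation TSV: chrom, pos (0-based), ref, alt, gene,
    consequence, score1..score3 (empty cells = missing)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"annotation file missing columns {sorted(missing)}")
    return df


def average_scores(table: pd.DataFrame) -> pd.DataFrame:
    """Average the available predictor scores into a single column ``s``.

    SNVs with all three scores missing are dropped (count logged). Scores
    outside [0,1] raise.
    """
    present = [c for c in SCORE_COLUMNS if c in table.columns]
    if not present:
        raise ValidationError(f"no predictor score columns among {SCORE_COLUMNS}")
    scores = table[present].to_numpy(dtype=float)
    finite = np.isfinite(scores)
    bad = finite & ((scores < 0) | (scores > 1))
    if bad.any():
        raise ValidationError("predictor scores must lie in [0,1]")
    n_avail = finite.sum(axis=1)
    dropped = int((n_avail == 0).sum())
    if dropped:
        logger.info("average_scores: dropped %d SNVs with no scores", dropped)
    out = table[n_avail > 0].copy()
    with np.errstate(invalid="ignore"):
        out["s"] = np.nanmean(scores[n_avail > 0], axis=1)
    return out.reset_index(drop=True)


def filter_rare_nonsyn(
    cohort: CohortGenotypes,
    annotations: pd.DataFrame,
    af_threshold: float = 0.01,
) -> pd.DataFrame:
    """Keep nonsynonymous SNVs with cohort allele frequency < threshold.

    Returns the annotation rows joined with the cohort variant index and
    allele frequency (column ``af`` and row index ``variant_idx``).
    """
    af = cohort.allele_frequency()
    keys = cohort.variant_keys()
    idx_of = {k: i for i, k in enumerate(keys)}
    ann = annotations.copy()
    ann["variant_idx"] = [
        idx_of.get((c, p, r, a), -1)
        for c, p, r, a in zip(ann["chrom"], ann["pos"], ann["ref"], ann["alt"])
    ]
    ann = ann[ann["variant_idx"] >= 0].copy()
    ann["af"] = af[ann["variant_idx"].to_numpy()]
    keep = (ann["consequence"] == "nonsynonymous") & (ann["af"] < af_threshold)
    return ann[keep].reset_index(drop=True)


def burden(
    cohort: CohortGenotypes,
    variants: pd.DataFrame,
    gene_universe=None,
    dosage_weighted: bool = False,
) -> pd.DataFrame:
    """Genes x samples burden matrix g_im = sum of averaged scores over the
    sample's carried rare nonsynonymous SNVs in the gene.

    ``variants`` is the output of :func:`filter_rare_nonsyn` merged with a
    score column ``s``. A carrier (dosage >= 1) contributes the score once;
    with ``dosage_weighted`` the score is multiplied by the dosage.
    ``gene_universe`` adds zero rows for genes with no retained SNV.
    """
    if "s" not in variants.columns:
        raise ValidationError("variants need an averaged score column 's'")
    no_gene = variants["gene"].isna()
    if no_gene.any():
        logger.info("burden: dropped %d SNVs without a gene", int(no_gene.sum()))
        variants = variants[~no_gene]
    genes = sorted(variants["gene"].unique())
    if gene_universe is not None:
        genes = sorted(set(genes) | set(gene_universe))
    gene_idx = {g: i for i, g in enumerate(genes)}
    g = np.zeros((len(genes), cohort.n_samples))
    d = cohort.dosage
    for row in variants.itertuples(index=False):
        dv = d[row.variant_idx]
        carried = np.where(dv >= 1, dv if dosage_weighted else 1, 0)
        g[gene_idx[row.gene]] += row.s * carried
    return pd.DataFrame(g, index=pd.Index(genes, name="gene"), columns=cohort.samples)


def burden_test(matrix: pd.DataFrame, labels) -> pd.DataFrame:
    """Per-gene one-tailed Welch t test, alternative: case mean > control.

    Genes with zero variance in both groups get p = 1 (no evidence).
    """
    labels = np.asarray(labels)
    case = labels == "case"
    ctrl = labels == "control"
    if case.sum() < 2 or ctrl.sum() < 2:
        raise ValidationError("both groups need >= 2 samples")
    x = matrix.to_numpy()[:, case]
    y = matrix.to_numpy()[:, ctrl]
    with np.errstate(divide="ignore", invalid="ignore"):
        res = sps.ttest_ind(
            x, y, axis=1, equal_var=False, alternative="greater"
        )
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = (x.var(axis=1) == 0) & (y.var(axis=1) == 0)
    p[degenerate] = 1.0
    return pd.DataFrame(
        {
            "gene": matrix.index,
            "t": np.where(degenerate, 0.0, np.asarray(res.statistic, dtype=float)),
            "p": p,
            "case_mean": x.mean(axis=1),
            "control_mean": y.mean(axis=1),
        }
    ).reset_index(drop=True)
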