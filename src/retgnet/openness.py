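"""Differential chromatin openness between cases and controls.

Each individual's predicted accessibility of every RE is compared with a
baseline genome (major-allele or reference). Per RE, enrichment of
nonbaseline individuals among cases (one-sided Fisher exact) and a shift in
scores between nonbaseline cases and nonbaseline controls (two-sided
Wilcoxon rank-sum) are combined with Fisher's method; per gene, the
strongest REs (smallest combined p, up to five) are combined again and
genes are ranked with Benjamini-Hochberg FDR control.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Protocol

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import CohortGenotypes
from .intervals import RegulatoryElement, ValidationError
from .network import RETGNetwork
from .stats import bh_fdr, fisher_method, wilcoxon_rank_sum

logger = logging.getLogger(__name__)

VariantKey = tuple  # (chrom, pos0, ref, alt)


class OpennessScorer(Protocol):
    """Deterministic map (RE, set of alt alleles carried inside it) -> score.

    The score must depend only on the variants inside the RE; the same
    input always yields the same output.
    """

    def score(self, re: RegulatoryElement, carried: frozenset) -> float:
        ...


class LinearScorer:
    """Additive scorer: base(RE) + sum of per-variant weights carried.

    Stands in for a sequence-based accessibility predictor; weights are a
    sparse mapping from variant key to effect on openness, so individuals
    carrying no weighted variant score exactly at base.
    """

    def __init__(self, base: dict, weights: dict):
        self.base = dict(base)
        self.weights = dict(weights)

    def score(self, re: RegulatoryElement, carried: frozenset) -> float:
        total = self.base[re.re_id]
        for key in sorted(carried):
            w = self.weights.get(key)
            if w is not None:
                total += w
        return total


def build_baseline(cohort: CohortGenotypes, mode: str = "major_allele") -> frozenset:
    """Variant keys carried (homozygously) by the baseline genome.

    major_allele: alt included when its frequency > 0.5; tie at exactly 0.5
    keeps the reference. reference: empty set (the reference genome).
    """
    if mode == "reference":
        return frozenset()
    if mode != "major_allele":
        raise ValidationError(f"unknown baseline mode {mode!r}")
    af = cohort.allele_frequency()
    keys = cohort.variant_keys()
    return frozenset(keys[i] for i in np.flatnonzero(af > 0.5))


@dataclass
class OpennessMatrix:
    """Per-sample, per-RE openness scores plus the baseline genome's."""

    score: np.ndarray  # (n_samples, n_res)
    baseline: np.ndarray  # (n_res,)
    nonbaseline: np.ndarray  # bool (n_samples, n_res)
    re_ids: list
    samples: list
    n_missing_imputed: int = 0


def score_cohort(
    cohort: CohortGenotypes,
    res,
    scorer: OpennessScorer,
    baseline: frozenset,
    tolerance: float = 1e-9,
) -> OpennessMatrix:
    """Score every sample and the baseline genome on every RE.

    A sample carries a variant when dosage >= 1 (no phasing; the predictor
    consumes one personal sequence per individual). Missing genotypes are
    imputed to the baseline allele and counted.
    """
    res = list(res)
    keys = cohort.variant_keys()
    v = cohort.variants
    chroms = v["chrom"].to_numpy()
    pos = v["pos"].to_numpy()

    n_samples = cohort.n_samples
    score = np.empty((n_samples, len(res)))
    base_scores = np.empty(len(res))
    nonbase = np.zeros((n_samples, len(res)), dtype=bool)
    n_missing = 0

    if isinstance(scorer, LinearScorer):
        weight_arr = np.array([scorer.weights.get(k, 0.0) for k in keys])
    else:
        weight_arr = None

    for j, re in enumerate(res):
        iv = re.interval
        in_re = np.flatnonzero(
            (chroms == iv.chrom) & (pos >= iv.start) & (pos < iv.end)
        )
        base_carried = frozenset(k for k in (keys[i] for i in in_re) if k in baseline)
        base_scores[j] = scorer.score(re, base_carried)
        if len(in_re) == 0:
            score[:, j] = base_scores[j]
            continue
        d = cohort.dosage[in_re]  # (n_in_re, n_samples)
        missing = d < 0
        if missing.any():
            n_missing += int(missing.sum())
            base_dosage = np.array(
                [2 if keys[i] in baseline else 0 for i in in_re], dtype=np.int8
            )
            d = np.where(missing, base_dosage[:, None], d)
        carried = d >= 1  # (n_in_re, n_samples)
        if weight_arr is not None:
            # additive scorer: vectorized over samples
            score[:, j] = scorer.base[re.re_id] + carried.T @ weight_arr[in_re]
        else:
            for s in range(n_samples):
                carried_keys = frozenset(
                    keys[i] for i, c in zip(in_re, carried[:, s]) if c
                )
                score[s, j] = scorer.score(re, carried_keys)
        nonbase[:, j] = np.abs(score[:, j] - base_scores[j]) > tolerance

    if n_missing:
        logger.info("score_cohort: imputed %d missing genotypes to baseline", n_missing)
    return OpennessMatrix(
        score=score,
        baseline=base_scores,
        nonbaseline=nonbase,
        re_ids=[re.re_id for re in res],
        samples=list(cohort.samples),
        n_missing_imputed=n_missing,
    )


def re_test(matrix: OpennessMatrix, labels) -> pd.DataFrame:
    """Per-RE case/control comparison.

    p_fisher: one-sided Fisher exact (nonbaseline enriched in cases) on the
    2x2 of nonbaseline counts. p_wilcoxon: two-sided rank-sum comparing the
    openness scores of nonbaseline cases vs nonbaseline controls.
    p_combined: Fisher's method (chi2, 4 df). REs with no nonbaseline
    individual are skipped (p_combined = 1, flag 'skipped'); when only one
    group has nonbaseline individuals the Wilcoxon is undefined and
    p_combined falls back to p_fisher alone (flag 'fisher_only').
    """
    labels = np.asarray(labels)
    case = labels == "case"
    ctrl = labels == "control"
    n_case, n_ctrl = int(case.sum()), int(ctrl.sum())
    if n_case == 0 or n_ctrl == 0:
        raise ValidationError("both groups must be nonempty")

    nb = matrix.nonbaseline
    a = nb[case].sum(axis=0)  # nonbaseline cases per RE
    b = nb[ctrl].sum(axis=0)
    k = a + b
    # vectorized one-sided Fisher exact = hypergeometric upper tail
    p_fisher = sps.hypergeom.sf(a - 1, n_case + n_ctrl, k, n_case)

    rows = []
    for j, re_id in enumerate(matrix.re_ids):
        if k[j] == 0:
            rows.append((re_id, 1.0, np.nan, 1.0, 0, 0, n_case, n_ctrl, "skipped"))
            continue
        pf = min(float(p_fisher[j]), 1.0)
        sc_case = matrix.score[case, j][nb[case, j]]
        sc_ctrl = matrix.score[ctrl, j][nb[ctrl, j]]
        if len(sc_case) == 0 or len(sc_ctrl) == 0:
            rows.append(
                (re_id, pf, np.nan, pf, int(a[j]), int(b[j]), n_case, n_ctrl,
                 "fisher_only")
            )
            continue
        pw = wilcoxon_rank_sum(sc_case, sc_ctrl)
        _, pc = fisher_method([pf, pw])
        rows.append(
            (re_id, pf, pw, pc, int(a[j]), int(b[j]), n_case, n_ctrl, "ok")
        )
    return pd.DataFrame(
        rows,
        columns=[
            "re_id", "p_fisher", "p_wilcoxon", "p_combined",
            "cases_nonbaseline", "controls_nonbaseline", "n_cases",
            "n_controls", "flag",
        ],
    )


def gene_combine(
    network: RETGNetwork,
    re_results: pd.DataFrame,
    k: int = 5,
    fdr: float = 0.01,
) -> pd.DataFrame:
    """Aggregate RE-level evidence to genes.

    Per gene, the k linked REs with smallest p_combined ("highest
    differential open scores", score = -log p) are combined with Fisher's
    method on 2m degrees of freedom; BH q-values are computed across genes
    and the significant set is q < ``fdr``. Genes with no tested RE are
    omitted. Promoter REs participate.
    """
    p_by_re = dict(zip(re_results["re_id"], re_results["p_combined"]))
    gene_res: dict[str, list] = {}
    for re_id, gene in network.edges:
        if re_id in p_by_re:
            gene_res.setdefault(gene, []).append(re_id)
    rows = []
    for gene, re_ids in gene_res.items():
        ranked = sorted(re_ids, key=lambda r: (p_by_re[r], r))
        top = ranked[: k if k is not None else len(ranked)]
        _, pc = fisher_method([p_by_re[r] for r in top])
        rows.append((gene, ",".join(top), len(top), pc))
    out = pd.DataFrame(rows, columns=["gene", "contributing_res", "m", "p_combined"])
    out = out.sort_values(["p_combined", "gene"], kind="stable").reset_index(drop=True)
    out["q_value"] = bh_fdr(out["p_combined"].to_numpy())
    out["significant"] = out["q_value"] < fdr
    return out
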