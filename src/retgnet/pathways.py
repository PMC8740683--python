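"""Gene-set (GO term) level inference.

Noncoding evidence: hypergeometric enrichment of differential-openness
target genes in each term. Coding evidence: Poisson test on the count of
genes with nominally significant burden in the term. The two p-values are
combined per term with Fisher's method and the terms ranked with BH FDR.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .intervals import ValidationError
from .stats import bh_fdr, fisher_method

logger = logging.getLogger(__name__)


def read_gmt(path) -> dict:
    """Read a GMT file: term <tab> description <tab> gene1 <tab> gene2 ..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(parts[2:])
    return sets


def write_gmt(sets: dict, path, descriptions: dict | None = None) -> None:
    with open(path, "w") as fh:
        for term in sorted(sets):
            desc = (descriptions or {}).get(term, "na")
            fh.write("\t".join([term, desc] + sorted(sets[term])) + "\n")


@dataclass
class GeneSetCollection:
    """Named gene sets intersected with a declared universe."""

    sets: dict = field(default_factory=dict)
    universe: set = field(default_factory=set)

    def __post_init__(self) -> None:
        trimmed = {}
        for term, members in self.sets.items():
            inter = set(members) & self.universe
            if inter:
                trimmed[term] = inter
            else:
                logger.info("dropping empty gene set %s", term)
        self.sets = trimmed


def poisson_term_test(k: int, term_size: int, global_rate: float) -> float:
    """Upper Poisson tail for observing >= k significant genes in a term.

    lambda = term_size * global_rate; p = P(X >= k); k = 0 gives 1.
    """
    if not 0 <= k <= term_size:
        raise ValidationError("k must satisfy 0 <= k <= term_size")
    if not 0 < global_rate < 1:
        raise ValidationError("global_rate must be in (0,1)")
    if k == 0:
        return 1.0
    lam = term_size * global_rate
    return float(sps.poisson.sf(k - 1, lam))


def hypergeom_term_test(targets: set, term: set, universe: set) -> tuple[float, float]:
    """Upper hypergeometric tail P(overlap >= observed) and fold enrichment
    (overlap/|targets|) / (|term|/|universe|)."""
    if not targets:
        raise ValidationError("empty target gene set")
    targets = set(targets) & set(universe)
    term = set(term) & set(universe)
    if not targets:
        raise ValidationError("target genes fall outside the universe")
    overlap = len(targets & term)
    n_u, n_t, n_s = len(universe), len(term), len(targets)
    p = float(sps.hypergeom.sf(overlap - 1, n_u, n_t, n_s))
    expected = n_t / n_u
    fold = (overlap / n_s) / expected if expected > 0 else float("nan")
    return min(p, 1.0), fold


def coding_term_pvalues(
    burden_p: pd.DataFrame,
    collection: GeneSetCollection,
    alpha: float = 0.05,
) -> dict:
    """Poisson term p-values from per-gene burden test results.

    The global rate is the fraction of scored genes with burden p <= alpha
    (the expectation per gene under no term structure).
    """
    scored = burden_p[burden_p["gene"].isin(collection.universe)]
    sig = set(scored.loc[scored["p"] <= alpha, "gene"])
    rate = len(sig) / len(scored) if len(scored) else 0.0
    rate = min(max(rate, 1e-12), 1 - 1e-12)
    out = {}
    for term, members in collection.sets.items():
        k = len(sig & members)
        out[term] = poisson_term_test(k, len(members), rate)
    return out


def noncoding_term_pvalues(
    target_genes: set, collection: GeneSetCollection
) -> tuple[dict, dict]:
    """Hypergeometric term p-values (and folds) for noncoding target genes."""
    ps, folds = {}, {}
    for term, members in collection.sets.items():
        ps[term], folds[term] = hypergeom_term_test(
            target_genes, members, collection.universe
        )
    return ps, folds


def combine_and_rank(
    noncoding: dict, coding: dict, folds: dict | None = None
) -> pd.DataFrame:
    """Fisher's-method combination (chi2, 4 df) per shared term, ranked
    ascending, with BH q-values. Terms missing one side are excluded."""
    shared = sorted(set(noncoding) & set(coding))
    skipped = (set(noncoding) | set(coding)) - set(shared)
    if skipped:
        logger.info("combine_and_rank: %d terms missing one side", len(skipped))
    if not shared:
        raise ValidationError("no terms shared between the two sides")
    rows = []
    for term in shared:
        _, pc = fisher_method([noncoding[term], coding[term]])
        rows.append(
            (term, noncoding[term], coding[term], pc,
             (folds or {}).get(term, np.nan))
        )
    out = pd.DataFrame(
        rows, columns=["term", "p_noncoding", "p_coding", "p_combined", "fold"]
    )
    out = out.sort_values(["p_combined", "term"], kind="stable").reset_index(drop=True)
    out["q_value"] = bh_fdr(out["p_combined"].to_numpy())
    return out
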