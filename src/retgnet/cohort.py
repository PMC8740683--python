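"""Case/control cohort genotypes.

Holds biallelic variant calls for labeled samples as a dosage matrix
(variants x samples, values 0/1/2, -1 for missing) plus sample labels and
sex. Positions are stored 0-based; VCF input/output converts.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import ValidationError

logger = logging.getLogger(__name__)

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt"]


@dataclass
class CohortGenotypes:
    """Biallelic genotypes for a labeled cohort.

    variants: DataFrame with columns chrom, pos (0-based), ref, alt.
    dosage:   int8 array (n_variants, n_samples); -1 encodes missing.
    labels:   'case'/'control' per sample; sex: 'M'/'F' per sample.
    """

    samples: list
    labels: np.ndarray
    sex: np.ndarray
    variants: pd.DataFrame
    dosage: np.ndarray
    _af: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.sex = np.asarray(self.sex)
        if self.dosage.shape != (len(self.variants), len(self.samples)):
            raise ValidationError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.variants)} variants x {len(self.samples)} samples"
            )
        dup = self.variants.duplicated(subset=VARIANT_COLUMNS)
        if dup.any():
            raise ValidationError(
                f"duplicate variant records, e.g. "
                f"{self.variants[dup].iloc[0][VARIANT_COLUMNS].tolist()}"
            )
        bad = ~np.isin(self.labels, ["case", "control"])
        if bad.any():
            raise ValidationError(f"unknown labels: {set(self.labels[bad])}")

    # -- basic views -------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def case_mask(self) -> np.ndarray:
        return self.labels == "case"

    def allele_frequency(self) -> np.ndarray:
        """Alt-allele frequency per variant from non-missing dosages."""
        if self._af is None:
            d = self.dosage
            observed = d >= 0
            alt = np.where(observed, d, 0).sum(axis=1)
            n_alleles = 2 * observed.sum(axis=1)
            with np.errstate(invalid="ignore"):
                self._af = np.where(n_alleles > 0, alt / n_alleles, 0.0)
        return self._af

    def variant_keys(self) -> pd.Index:
        v = self.variants
        return pd.Index(zip(v["chrom"], v["pos"], v["ref"], v["alt"]))

    # -- VCF round trip ----------------------------------------------------
    def to_vcf(self, vcf_path, samples_path=None) -> None:
        """Write a minimal VCF v4.2 with GT fields only (1-based POS)."""
        order = np.lexsort(
            (self.variants["pos"].values, self.variants["chrom"].values)
        )
        with open(vcf_path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(self.samples) + "\n"
            )
            gt_map = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
            v = self.variants
            for i in order:
                gts = "\t".join(gt_map[int(d)] for d in self.dosage[i])
                fh.write(
                    f"{v.iloc[i]['chrom']}\t{v.iloc[i]['pos'] + 1}\t.\t"
                    f"{v.iloc[i]['ref']}\t{v.iloc[i]['alt']}\t.\tPASS\t.\tGT\t{gts}\n"
                )
        if samples_path is not None:
            pd.DataFrame(
                {"sample": self.samples, "label": self.labels, "sex": self.sex}
            ).to_csv(samples_path, sep="\t", index=False)

    @classmethod
    def from_vcf(cls, vcf_path, samples_path) -> "CohortGenotypes":
        """Read genotypes with cyvcf2 plus a samples TSV (sample, label, sex).

        Multi-allelic records are rejected; decompose them upstream
        (e.g. ``bcftools norm -m-``).
        """
        from cyvcf2 import VCF

        meta = pd.read_csv(samples_path, sep="\t")
        vcf = VCF(str(vcf_path), gts012=True)
        samples = list(vcf.samples)
        meta = meta.set_index("sample").loc[samples]
        rows, dosages = [], []
        for rec in vcf:
            if len(rec.ALT) != 1:
                raise ValidationError(
                    f"multi-allelic record at {rec.CHROM}:{rec.POS}; "
                    "decompose to biallelic records first"
                )
            rows.append((rec.CHROM, rec.POS - 1, rec.REF, rec.ALT[0]))
            gt = rec.gt_types.astype(np.int8)  # 0,1,2; 3 = unknown
            gt[gt == 3] = -1
            dosages.append(gt)
        variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
        dosage = (
            np.vstack(dosages)
            if dosages
            else np.zeros((0, len(samples)), dtype=np.int8)
        )
        return cls(
            samples=samples,
            labels=meta["label"].to_numpy(),
            sex=meta["sex"].to_numpy(),
            variants=variants,
            dosage=dosage,
        )

    def subset_samples(self, mask: np.ndarray) -> "CohortGenotypes":
        idx = np.flatnonzero(mask)
        return CohortGenotypes(
            samples=[self.samples[i] for i in idx],
            labels=self.labels[idx],
            sex=self.sex[idx],
            variants=self.variants.copy(),
            dosage=self.dosage[:, idx],
        )


def _largest_remainder(total: int, weights: np.ndarray) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``weights``."""
    quota = total * weights / weights.sum()
    alloc = np.floor(quota).astype(int)
    remainder = quota - alloc
    short = total - alloc.sum()
    for i in np.argsort(-remainder)[:short]:
        alloc[i] += 1
    return alloc


def augment_controls(
    cohort: CohortGenotypes,
    external_pool: CohortGenotypes,
    n: int = 500,
    seed: int = 0,
) -> CohortGenotypes:
    """Replace the cohort's controls with ``n`` external samples drawn with
    the case cohort's sex ratio (stratified, largest-remainder rounding).

    Variants carried only by the external samples and absent from the case
    samples are removed. Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    cases = cohort.subset_samples(cohort.case_mask)
    sexes = np.array(["M", "F"])
    case_counts = np.array([(cases.sex == s).sum() for s in sexes], dtype=float)
    want = _largest_remainder(n, case_counts)
    chosen: list[int] = []
    for s, k in zip(sexes, want):
        pool_idx = np.flatnonzero(external_pool.sex == s)
        if len(pool_idx) < k:
            raise ValidationError(
                f"external pool has {len(pool_idx)} samples of sex {s}, need {k}"
            )
        chosen.extend(rng.choice(pool_idx, size=k, replace=False))
    chosen = sorted(chosen)

    ext = external_pool.subset_samples(np.isin(np.arange(external_pool.n_samples), chosen))
    ext.labels = np.array(["control"] * ext.n_samples)

    # align variant tables (outer union, missing rows filled with dosage 0)
    case_keys = cases.variant_keys()
    ext_keys = ext.variant_keys()
    union = case_keys.union(ext_keys)
    d_case = np.zeros((len(union), cases.n_samples), dtype=np.int8)
    d_ext = np.zeros((len(union), ext.n_samples), dtype=np.int8)
    d_case[union.get_indexer(case_keys)] = cases.dosage
    d_ext[union.get_indexer(ext_keys)] = ext.dosage

    carried_case = (d_case > 0).any(axis=1)
    carried_ext = (d_ext > 0).any(axis=1)
    in_case_table = union.isin(case_keys)
    drop = (carried_ext & ~carried_case) | ~np.asarray(in_case_table)
    if drop.any():
        logger.info("augment_controls: dropped %d external-only variants", drop.sum())
    keep = ~drop
    variants = pd.DataFrame(
        [k for k, m in zip(union, keep) if m], columns=VARIANT_COLUMNS
    )
    return CohortGenotypes(
        samples=list(cases.samples) + list(ext.samples),
        labels=np.concatenate([cases.labels, ext.labels]),
        sex=np.concatenate([cases.sex, ext.sex]),
        variants=variants,
        dosage=np.hstack([d_case[keep], d_ext[keep]]),
    )
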