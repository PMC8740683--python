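"""Regulatory-element -> target-gene network construction.

Builds cell-type-specific networks from chromatin-loop calls (BEDPE),
open-chromatin peaks (BED) and gene models: loop anchors are split into
1-kb tiles, tiles are labeled open when they overlap >=1 ATAC peak, and a
gene inherits the tiles of the anchor opposite the one overlapping its
promoter. Genes are categorized as OpenLoop (>=1 open loop-anchor RE),
NonOpenLoop (loop-linked, all anchor REs nonopen) or NoLoop.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .intervals import (
    GenomicInterval,
    IntervalIndex,
    Loop,
    RegulatoryElement,
    ValidationError,
)

logger = logging.getLogger(__name__)

CATEGORIES = ("OpenLoop", "NonOpenLoop", "NoLoop")


class ParseError(ValueError):
    """Malformed input line; message names the file and line number."""


def read_loops(path, q_threshold: float = 0.01) -> list[Loop]:
    """Read BEDPE loop calls, keeping loops with q-value < ``q_threshold``.

    Expected columns: chrom1 start1 end1 chrom2 start2 end2 q (tab- or
    whitespace-separated; extra columns ignored). Coordinates are taken as
    0-based half-open.
    """
    loops: list[Loop] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 7:
                raise ParseError(
                    f"{path}: line {lineno}: expected >=7 columns, got {len(parts)}"
                )
            try:
                c1, s1, e1 = parts[0], int(parts[1]), int(parts[2])
                c2, s2, e2 = parts[3], int(parts[4]), int(parts[5])
                q = float(parts[6])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            if s1 >= e1 or s2 >= e2:
                raise ValidationError(
                    f"{path}: line {lineno}: anchor start >= end"
                )
            if q < q_threshold:
                loops.append(
                    Loop(GenomicInterval(c1, s1, e1), GenomicInterval(c2, s2, e2), q)
                )
    return loops


def write_loops(loops, path) -> None:
    """Write loops as 7-column BEDPE (chrom1..end2, q)."""
    with open(path, "w") as fh:
        for lp in loops:
            a, b = lp.anchor1, lp.anchor2
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}"
                f"\t{lp.q_value!r}\n"
            )


def read_bed(path) -> list[GenomicInterval]:
    """Read a BED3+ file into intervals (extra columns ignored)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >=3 columns")
            try:
                out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2])))
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
    return out


def write_bed(intervals, path, names=None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"iv{i}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")


def read_genes_bed(path) -> pd.DataFrame:
    """Read gene models from BED6 (chrom start end name score strand).

    The TSS is the interval start on '+' and the interval end on '-'.
    Returns a frame with columns gene, chrom, start, end, strand, tss.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 6:
                raise ParseError(
                    f"{path}: line {lineno}: gene models need 6 BED columns"
                )
            chrom, start, end, name, _score, strand = parts[:6]
            start, end = int(start), int(end)
            if strand not in ("+", "-"):
                raise ValidationError(
                    f"{path}: line {lineno}: missing/invalid strand {strand!r}"
                )
            tss = start if strand == "+" else end
            rows.append((name, chrom, start, end, strand, tss))
    return pd.DataFrame(
        rows, columns=["gene", "chrom", "start", "end", "strand", "tss"]
    )


def tile_and_classify(
    loops, peaks, tile_size: int = 1000
) -> list[RegulatoryElement]:
    """Split every distinct loop anchor into consecutive ``tile_size``-bp
    tiles (final tile truncated at the anchor end) and label each tile
    open iff it overlaps >=1 peak by >=1 bp.

    Tiles are deduplicated by coordinates across anchors.
    """
    peak_index = IntervalIndex(peaks)
    seen: dict[tuple[str, int, int], RegulatoryElement] = {}
    for lp in loops:
        for anchor in (lp.anchor1, lp.anchor2):
            for start in range(anchor.start, anchor.end, tile_size):
                end = min(start + tile_size, anchor.end)
                key = (anchor.chrom, start, end)
                if key in seen:
                    continue
                iv = GenomicInterval(anchor.chrom, start, end)
                cls = "open" if peak_index.any_overlap(iv) else "nonopen"
                seen[key] = RegulatoryElement(iv, "loop_anchor", cls)
    return list(seen.values())


def make_promoters(genes: pd.DataFrame, upstream: int = 2000) -> dict:
    """Promoter interval per gene: ``upstream`` bp upstream of the TSS.

    '+' strand: [TSS - upstream, TSS); '-' strand: [TSS, TSS + upstream);
    clipped at position 0.
    """
    required = {"gene", "chrom", "tss", "strand"}
    missing = required - set(genes.columns)
    if missing:
        raise ValidationError(f"gene models missing columns: {sorted(missing)}")
    promoters = {}
    for row in genes.itertuples(index=False):
        if row.strand == "+":
            start, end = max(0, row.tss - upstream), row.tss
        elif row.strand == "-":
            start, end = row.tss, row.tss + upstream
        else:
            raise ValidationError(f"gene {row.gene}: invalid strand {row.strand!r}")
        if start >= end:  # TSS at the chromosome start on '+'
            continue
        promoters[row.gene] = GenomicInterval(row.chrom, start, end)
    return promoters


@dataclass
class RETGNetwork:
    """RE <-> target-gene network with per-gene loop-linkage categories.

    ``elements`` maps re_id -> RegulatoryElement; ``edges`` is a set of
    (re_id, gene); ``gene_category`` partitions the declared gene universe
    into OpenLoop / NonOpenLoop / NoLoop. ``loops`` retains the loops the
    network was built from (used for silencer linkage statistics).
    """

    elements: dict = field(default_factory=dict)
    genes: set = field(default_factory=set)
    edges: set = field(default_factory=set)
    gene_category: dict = field(default_factory=dict)
    promoters: dict = field(default_factory=dict)
    loops: list = field(default_factory=list)

    def res_of_gene(self, gene: str) -> list[str]:
        return sorted(r for r, g in self.edges if g == gene)

    def genes_of_re(self, re_id: str) -> list[str]:
        return sorted(g for r, g in self.edges if r == re_id)

    def validate(self) -> None:
        for re_id, gene in self.edges:
            if re_id not in self.elements:
                raise ValidationError(f"edge references unknown RE {re_id}")
            if gene not in self.genes:
                raise ValidationError(f"edge references unknown gene {gene}")
        if set(self.gene_category) != self.genes:
            raise ValidationError("categories do not cover the gene universe")

    # -- serialization -----------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "elements": [
                {
                    "re_id": e.re_id,
                    "chrom": e.interval.chrom,
                    "start": e.interval.start,
                    "end": e.interval.end,
                    "source": e.source,
                    "openness_class": e.openness_class,
                }
                for e in self.elements.values()
            ],
            "edges": sorted(self.edges),
            "gene_category": self.gene_category,
            "promoters": {
                g: [iv.chrom, iv.start, iv.end] for g, iv in self.promoters.items()
            },
            "loops": [
                [
                    lp.anchor1.chrom, lp.anchor1.start, lp.anchor1.end,
                    lp.anchor2.chrom, lp.anchor2.start, lp.anchor2.end,
                    lp.q_value,
                ]
                for lp in self.loops
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "RETGNetwork":
        with open(path) as fh:
            payload = json.load(fh)
        net = cls()
        for rec in payload["elements"]:
            e = RegulatoryElement(
                GenomicInterval(rec["chrom"], rec["start"], rec["end"]),
                rec["source"],
                rec["openness_class"],
                rec["re_id"],
            )
            net.elements[e.re_id] = e
        net.edges = {tuple(e) for e in payload["edges"]}
        net.gene_category = dict(payload["gene_category"])
        net.genes = set(net.gene_category)
        net.promoters = {
            g: GenomicInterval(c, s, e)
            for g, (c, s, e) in payload["promoters"].items()
        }
        net.loops = [
            Loop(GenomicInterval(c1, s1, e1), GenomicInterval(c2, s2, e2), q)
            for c1, s1, e1, c2, s2, e2, q in payload["loops"]
        ]
        return net

    def to_tables(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(elements table, edges table) as DataFrames for TSV export."""
        els = pd.DataFrame(
            [
                (e.re_id, e.interval.chrom, e.interval.start, e.interval.end,
                 e.source, e.openness_class)
                for e in self.elements.values()
            ],
            columns=["re_id", "chrom", "start", "end", "source", "openness_class"],
        )
        edges = pd.DataFrame(sorted(self.edges), columns=["re_id", "gene"])
        return els, edges


def build_network(
    loops, promoters: dict, res, peaks=None, gene_universe=None
) -> RETGNetwork:
    """Link anchor tiles to target genes through loops.

    For each loop with one anchor overlapping a gene's promoter, the tiles
    of the *other* anchor become REs of that gene. Each gene's own promoter
    is added as an RE (source=promoter; labeled against ``peaks`` when
    given). Categories: OpenLoop if any linked loop-anchor RE is open,
    NonOpenLoop if loop-linked but all anchor REs nonopen, else NoLoop.
    """
    if gene_universe is None:
        gene_universe = set(promoters)
    else:
        gene_universe = set(gene_universe)
        unknown = set(promoters) - gene_universe
        if unknown:
            raise ValidationError(
                f"promoters reference genes outside the universe: {sorted(unknown)[:5]}"
            )

    net = RETGNetwork(genes=gene_universe, promoters=dict(promoters), loops=list(loops))
    tiles_by_coord: dict[tuple, RegulatoryElement] = {}
    tile_index = IntervalIndex()
    for e in res:
        tiles_by_coord[(e.interval.chrom, e.interval.start, e.interval.end)] = e
        tile_index.add(e.interval)
        net.elements[e.re_id] = e

    prom_index = IntervalIndex()
    prom_genes: dict[tuple, list[str]] = {}
    for gene, iv in promoters.items():
        if gene not in gene_universe:
            raise ValidationError(f"promoter gene {gene} absent from gene universe")
        prom_index.add(iv)
        prom_genes.setdefault((iv.chrom, iv.start, iv.end), []).append(gene)

    peak_index = IntervalIndex(peaks) if peaks is not None else None

    def anchor_tiles(anchor: GenomicInterval) -> list[RegulatoryElement]:
        hits = []
        for iv in tile_index.overlapping(anchor):
            # only tiles that lie inside this anchor, not merely overlapping
            if iv.start >= anchor.start and iv.end <= anchor.end:
                hits.append(tiles_by_coord[(iv.chrom, iv.start, iv.end)])
        return hits

    linked_open: dict[str, bool] = {}
    for lp in net.loops:
        for prom_anchor, other in ((lp.anchor1, lp.anchor2), (lp.anchor2, lp.anchor1)):
            for prom_iv in prom_index.overlapping(prom_anchor):
                for gene in prom_genes[(prom_iv.chrom, prom_iv.start, prom_iv.end)]:
                    for tile in anchor_tiles(other):
                        net.edges.add((tile.re_id, gene))
                        if tile.openness_class == "open":
                            linked_open[gene] = True
                        else:
                            linked_open.setdefault(gene, False)

    for gene, iv in promoters.items():
        cls = "nonopen"
        if peak_index is not None and peak_index.any_overlap(iv):
            cls = "open"
        prom_re = RegulatoryElement(iv, "promoter", cls)
        net.elements[prom_re.re_id] = prom_re
        net.edges.add((prom_re.re_id, gene))

    for gene in gene_universe:
        if gene not in linked_open:
            net.gene_category[gene] = "NoLoop"
        elif linked_open[gene]:
            net.gene_category[gene] = "OpenLoop"
        else:
            net.gene_category[gene] = "NonOpenLoop"
    net.validate()
    return net


def read_expression(path) -> dict:
    """Read a two-column TSV gene -> FPKM into a dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "fpkm"],
                     comment="#")
    if (df["fpkm"] < 0).any():
        raise ValidationError("FPKM values must be >= 0")
    return dict(zip(df["gene"], df["fpkm"].astype(float)))


def expression_quantiles(
    network: RETGNetwork, expr: dict, probs
) -> pd.DataFrame:
    """Per-category empirical FPKM quantiles.

    Genes absent from ``expr`` count as 0 (not expressed or not detected).
    Empty categories yield NaN rows (flagged, never silent zeros).
    """
    probs = list(probs)
    if any(not 0 < p < 1 for p in probs):
        raise ValidationError("quantile probabilities must be in (0,1)")
    neg = [g for g, v in expr.items() if v < 0]
    if neg:
        raise ValidationError(f"negative FPKM for genes {neg[:5]}")
    rows = {}
    for cat in CATEGORIES:
        members = [g for g in network.genes if network.gene_category[g] == cat]
        if not members:
            logger.warning("expression_quantiles: category %s is empty", cat)
            rows[cat] = [np.nan] * len(probs)
            continue
        values = np.array([expr.get(g, 0.0) for g in members])
        rows[cat] = list(np.quantile(values, probs))
    out = pd.DataFrame.from_dict(rows, orient="index", columns=probs)
    out.index.name = "category"
    return out


def _silencer_linked_genes(network: RETGNetwork, silencer_index: IntervalIndex) -> set:
    """Genes with >=1 RE overlapping a silencer (direct) or linked through a
    loop whose other anchor overlaps a silencer (indirect)."""
    linked = set()
    re_gene: dict[str, list[str]] = {}
    for re_id, gene in network.edges:
        re_gene.setdefault(re_id, []).append(gene)
    for re_id, e in network.elements.items():
        if re_id in re_gene and silencer_index.any_overlap(e.interval):
            linked.update(re_gene[re_id])
    prom_index = IntervalIndex()
    prom_genes: dict[tuple, list[str]] = {}
    for gene, iv in network.promoters.items():
        prom_index.add(iv)
        prom_genes.setdefault((iv.chrom, iv.start, iv.end), []).append(gene)
    for lp in network.loops:
        for prom_anchor, other in ((lp.anchor1, lp.anchor2), (lp.anchor2, lp.anchor1)):
            if silencer_index.any_overlap(other):
                for prom_iv in prom_index.overlapping(prom_anchor):
                    linked.update(prom_genes[(prom_iv.chrom, prom_iv.start, prom_iv.end)])
    return linked


def silencer_stats(
    network_a: RETGNetwork,
    network_b: RETGNetwork,
    silencers,
    category: str = "NonOpenLoop",
) -> dict:
    """Fraction of genes linked to silencers per network and category, plus a
    two-sided Fisher exact p comparing the two networks in ``category``.

    Two-sidedness follows the point-probability summation rule (all tables
    with probability <= the observed table's).
    """
    idx = IntervalIndex(silencers)
    fractions = {}
    counts = {}
    for label, net in (("A", network_a), ("B", network_b)):
        linked = _silencer_linked_genes(net, idx)
        fractions[label] = {}
        counts[label] = {}
        for cat in CATEGORIES:
            members = [g for g in net.genes if net.gene_category[g] == cat]
            hit = sum(1 for g in members if g in linked)
            counts[label][cat] = (hit, len(members))
            fractions[label][cat] = hit / len(members) if members else float("nan")
    a_hit, a_n = counts["A"][category]
    b_hit, b_n = counts["B"][category]
    if a_n == 0 or b_n == 0:
        raise ValidationError(f"category {category} empty in one network")
    if len(idx) == 0:
        p = 1.0
    else:
        table = [[a_hit, a_n - a_hit], [b_hit, b_n - b_hit]]
        p = float(sps.fisher_exact(table, alternative="two-sided")[1])
    return {"fractions": fractions, "counts": counts, "category": category,
            "p_value": p}
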