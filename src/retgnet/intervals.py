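"""Genomic interval primitives.

All coordinates are 0-based half-open (BED convention). VCF positions are
converted to 0-based on read everywhere in this package.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from intervaltree import IntervalTree


class ValidationError(ValueError):
    """Input violates a structural precondition."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom must be nonempty")
        if not self.start < self.end:
            raise ValidationError(
                f"start must be < end, got [{self.start}, {self.end})"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class Loop:
    """A chromatin loop between two anchors with an FDR-adjusted q-value."""

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    q_value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.q_value <= 1.0:
            raise ValidationError(f"q_value must be in [0,1], got {self.q_value}")


@dataclass(frozen=True)
class RegulatoryElement:
    """A regulatory element: a <=1-kb anchor tile or a 2-kb promoter."""

    interval: GenomicInterval
    source: str  # {"loop_anchor", "promoter"}
    openness_class: str  # {"open", "nonopen"}
    re_id: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.source not in ("loop_anchor", "promoter"):
            raise ValidationError(f"unknown RE source {self.source!r}")
        if self.openness_class not in ("open", "nonopen"):
            raise ValidationError(f"unknown openness class {self.openness_class!r}")
        if self.source == "loop_anchor" and self.interval.width > 1000:
            raise ValidationError("loop-anchor tiles must be <= 1000 bp")
        if self.source == "promoter" and self.interval.width != 2000:
            raise ValidationError("promoter REs must be exactly 2000 bp")
        if not self.re_id:
            object.__setattr__(
                self, "re_id", f"{self.source}:{self.interval}"
            )


class IntervalIndex:
    """Per-chromosome interval tree for >=1-bp overlap queries."""

    def __init__(self, intervals: Iterable[GenomicInterval] = ()):
        self._trees: dict[str, IntervalTree] = {}
        self._n = 0
        for iv in intervals:
            self.add(iv)

    def add(self, iv: GenomicInterval) -> None:
        self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
        self._n += 1

    def overlapping(self, iv: GenomicInterval) -> list[GenomicInterval]:
        tree = self._trees.get(iv.chrom)
        if tree is None:
            return []
        return [hit.data for hit in tree.overlap(iv.start, iv.end)]

    def any_overlap(self, iv: GenomicInterval) -> bool:
        tree = self._trees.get(iv.chrom)
        return tree is not None and bool(tree.overlap(iv.start, iv.end))

    def any_within(self, chrom: str, pos: int, window: int) -> bool:
        """True iff any indexed interval lies within the closed +-window of
        the single base at ``pos`` (distance 0 inside the interval)."""
        tree = self._trees.get(chrom)
        if tree is None:
            return False
        # closed window: a base at pos is within `window` of [s, e) iff
        # s - window <= pos <= e - 1 + window
        return bool(tree.overlap(pos - window, pos + window + 1))

    def __len__(self) -> int:
        return self._n

    def __iter__(self) -> Iterator[GenomicInterval]:
        for tree in self._trees.values():
            for hit in tree:
                yield hit.data
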