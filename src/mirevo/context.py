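"""Genomic-context classification of miRNA loci.

Each locus receives exactly one label from {repeat, exon, intron,
intergenic}: the highest-priority feature class overlapping the precursor
interval by at least one base pair, or "intergenic" when nothing overlaps.
The default priority (repeat > exon > intron) follows the convention that a
repeat-embedded miRNA is reported as repeat-derived even when the repeat
sits inside a gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from intervaltree import IntervalTree

from .io import AnnotationSet, MirnaLocus

CONTEXT_CLASSES = ("repeat", "exon", "intron", "intergenic")
DEFAULT_PRIORITY = ("repeat", "exon", "intron")


def _annotation_trees(annotation: AnnotationSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end, feat in annotation.intervals:
        trees.setdefault(chrom, IntervalTree()).addi(start, end, feat)
    return trees


class ContextClassifier:
    """Reusable classifier holding per-chromosome interval trees."""

    def __init__(self, annotation: AnnotationSet,
                 priority: Sequence[str] = DEFAULT_PRIORITY,
                 min_overlap: int = 1):
        unknown = set(priority) - set(CONTEXT_CLASSES)
        if unknown:
            raise ValueError(f"unknown classes in priority: {sorted(unknown)}")
        self.priority = tuple(priority)
        self.min_overlap = min_overlap
        self._trees = _annotation_trees(annotation)

    def classify(self, locus: MirnaLocus) -> str:
        tree = self._trees.get(locus.chrom)
        if tree is None:
            return "intergenic"
        hits: dict[str, int] = {}
        for iv in tree.overlap(locus.start, locus.end):
            ov = min(iv.end, locus.end) - max(iv.begin, locus.start)
            if ov >= self.min_overlap:
                hits[iv.data] = max(hits.get(iv.data, 0), ov)
        for cls in self.priority:
            if cls in hits:
                return cls
        return "intergenic"


def classify_locus(locus: MirnaLocus, annotation: AnnotationSet,
                   priority: Sequence[str] = DEFAULT_PRIORITY) -> str:
    return ContextClassifier(annotation, priority).classify(locus)


def classify_loci(loci: Sequence[MirnaLocus], annotation: AnnotationSet,
                  priority: Sequence[str] = DEFAULT_PRIORITY) -> dict[str, str]:
    clf = ContextClassifier(annotation, priority)
    return {locus.id: clf.classify(locus) for locus in loci}


@dataclass
class ContextSummary:
    counts: dict[str, int]          # class -> locus count
    percents: dict[str, float]      # class -> % of total, 2 decimals
    intergenic_intron_ratio: float | None  # None when intron count is 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def context_summary(loci: Sequence[MirnaLocus],
                    annotation: AnnotationSet,
                    priority: Sequence[str] = DEFAULT_PRIORITY) -> ContextSummary:
    """Tally context classes and the intergenic/intron abundance ratio."""
    if not loci:
        raise ValueError("context_summary requires at least one locus")
    labels = classify_loci(loci, annotation, priority)
    return summarize_context_labels(labels)


def summarize_context_labels(labels: dict[str, str]) -> ContextSummary:
    counts = {cls: 0 for cls in CONTEXT_CLASSES}
    for lab in labels.values():
        counts[lab] += 1
    total = len(labels)
    percents = {cls: round(100.0 * n / total, 2) for cls, n in counts.items()}
    ratio = (
        round(counts["intergenic"] / counts["intron"], 2)
        if counts["intron"] > 0 else None
    )
    return ContextSummary(counts=counts, percents=percents,
                          intergenic_intron_ratio=ratio)
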