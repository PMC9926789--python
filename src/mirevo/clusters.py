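"""miRNA cluster detection and cluster-level summaries.

A cluster is a maximal run of >= 2 loci on one chromosome in which every
pair of consecutive loci (sorted by start) is separated by at most the
maximum inter-miRNA distance (MID, default 10 kb).  The gap between
consecutive loci is end-to-start, floored at zero for overlapping loci.

The enrichment test asks whether conserved ("common") miRNAs sit in
clusters more often than chance expects, either by re-drawing locus
positions uniformly on their own chromosomes ("reposition") or by shuffling
conservation labels over the fixed locus map ("label_shuffle").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import MirnaLocus, ValidationError

DEFAULT_MID = 10_000


@dataclass(frozen=True)
class MirnaCluster:
    cluster_id: str
    chrom: str
    members: tuple[str, ...]          # locus ids ordered by start
    span: tuple[int, int]             # (start of first, end of last)

    def __post_init__(self):
        if len(self.members) < 2:
            raise ValidationError("a cluster needs at least 2 members")

    @property
    def size(self) -> int:
        return len(self.members)


def gap_between(a: MirnaLocus, b: MirnaLocus) -> int:
    """End-to-start separation of two loci sorted by start; 0 if overlapping."""
    first, second = (a, b) if a.start <= b.start else (b, a)
    return max(0, second.start - first.end)


def detect_clusters(loci: Sequence[MirnaLocus], mid: int = DEFAULT_MID) -> list[MirnaCluster]:
    """Single-linkage chaining of loci within ``mid`` bp on each chromosome.

    Output is independent of input order; cluster ids are assigned by
    (chrom, start) of the first member.
    """
    if mid <= 0:
        raise ValueError("mid must be positive")
    by_chrom: dict[str, list[MirnaLocus]] = {}
    for locus in loci:
        by_chrom.setdefault(locus.chrom, []).append(locus)

    clusters: list[MirnaCluster] = []
    for chrom in sorted(by_chrom):
        chain: list[MirnaLocus] = []
        chain_end = -1  # max end seen in the chain, for contained loci
        for locus in sorted(by_chrom[chrom], key=lambda l: (l.start, l.end, l.id)):
            if chain and max(0, locus.start - chain_end) <= mid:
                chain.append(locus)
                chain_end = max(chain_end, locus.end)
            else:
                if len(chain) >= 2:
                    clusters.append(_make_cluster(chrom, chain))
                chain = [locus]
                chain_end = locus.end
        if len(chain) >= 2:
            clusters.append(_make_cluster(chrom, chain))
    return [
        MirnaCluster(f"cluster_{i + 1}", c.chrom, c.members, c.span)
        for i, c in enumerate(sorted(clusters, key=lambda c: (c.chrom, c.span)))
    ]


def _make_cluster(chrom: str, chain: list[MirnaLocus]) -> MirnaCluster:
    return MirnaCluster(
        cluster_id="tmp",
        chrom=chrom,
        members=tuple(l.id for l in chain),
        span=(chain[0].start, max(l.end for l in chain)),
    )


def clustered_ids(clusters: Sequence[MirnaCluster]) -> set[str]:
    out: set[str] = set()
    for c in clusters:
        out.update(c.members)
    return out


def percent(part: int, whole: int, ndigits: int = 2) -> float | None:
    """Percentage rounded to ``ndigits``; None for a zero denominator."""
    if whole == 0:
        return None
    return round(100.0 * part / whole, ndigits)


@dataclass
class ClusterSummary:
    n_clusters: int
    n_clustered: int
    n_total: int
    pct_clustered: float | None                 # overall, 1 decimal
    per_class_clustered: dict[str, int]         # conservation class -> clustered count
    per_class_total: dict[str, int]
    per_class_pct: dict[str, float | None]      # 2 decimals
    size_histogram: dict[int, int]
    context_counts: dict[str, int] = field(default_factory=dict)
    context_pct: dict[str, float | None] = field(default_factory=dict)


def cluster_summary(
    clusters: Sequence[MirnaCluster],
    loci: Sequence[MirnaLocus],
    context_labels: dict[str, str] | None = None,
) -> ClusterSummary:
    """Fractions of clustered miRNAs overall and per conservation class,
    the cluster-size histogram, and (optionally) the genomic-context
    composition of the clustered loci."""
    in_cluster = clustered_ids(clusters)
    per_class_total: dict[str, int] = {}
    per_class_clustered: dict[str, int] = {}
    for locus in loci:
        per_class_total[locus.conservation] = per_class_total.get(locus.conservation, 0) + 1
        if locus.id in in_cluster:
            per_class_clustered[locus.conservation] = (
                per_class_clustered.get(locus.conservation, 0) + 1
            )
    size_hist: dict[int, int] = {}
    for c in clusters:
        size_hist[c.size] = size_hist.get(c.size, 0) + 1

    context_counts: dict[str, int] = {}
    context_pct: dict[str, float | None] = {}
    if context_labels is not None:
        for lid in in_cluster:
            cls = context_labels[lid]
            context_counts[cls] = context_counts.get(cls, 0) + 1
        context_pct = {
            cls: percent(n, len(in_cluster)) for cls, n in context_counts.items()
        }

    return ClusterSummary(
        n_clusters=len(clusters),
        n_clustered=len(in_cluster),
        n_total=len(loci),
        pct_clustered=percent(len(in_cluster), len(loci), ndigits=1),
        per_class_clustered=per_class_clustered,
        per_class_total=per_class_total,
        per_class_pct={
            cls: percent(per_class_clustered.get(cls, 0), tot)
            for cls, tot in per_class_total.items()
        },
        size_histogram=size_hist,
        context_counts=context_counts,
        context_pct=context_pct,
    )


def fraction_clustered(ids: Sequence[str], clusters: Sequence[MirnaCluster],
                       ndigits: int = 1) -> float | None:
    """Percentage of the given miRNA ids that fall inside clusters."""
    in_cluster = clustered_ids(clusters)
    return percent(sum(1 for i in ids if i in in_cluster), len(ids), ndigits)


# ---------------------------------------------------------------------------
# enrichment permutation test


@dataclass
class EnrichmentResult:
    observed: int
    null: list[int]
    p_value: float
    n_perm: int
    seed: int
    mode: str

    def __post_init__(self):
        if not (0.0 < self.p_value <= 1.0):
            raise ValidationError("empirical p-value must lie in (0, 1]")


def _count_label_in_clusters(loci: Sequence[MirnaLocus], mid: int, label: str) -> int:
    members = clustered_ids(detect_clusters(loci, mid))
    return sum(1 for l in loci if l.id in members and l.conservation == label)


def enrichment_permutation_test(
    loci: Sequence[MirnaLocus],
    mid: int = DEFAULT_MID,
    label: str = "common",
    n_perm: int = 999,
    seed: int = 0,
    mode: str = "reposition",
    chrom_lengths: dict[str, int] | None = None,
) -> EnrichmentResult:
    """Permutation test of conservation-class enrichment in clusters.

    ``reposition`` re-draws each locus start uniformly on its own chromosome
    (length preserved, overlaps allowed) and re-runs cluster detection;
    ``label_shuffle`` permutes conservation labels over fixed loci.  The
    statistic is the number of ``label`` miRNAs inside clusters and the
    p-value is the add-one upper tail (1 + #{null >= obs}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if mode not in ("reposition", "label_shuffle"):
        raise ValueError(f"unknown mode {mode!r}")
    loci = list(loci)
    rng = np.random.default_rng(seed)
    observed = _count_label_in_clusters(loci, mid, label)

    null: list[int] = []
    if mode == "reposition":
        if not chrom_lengths:
            raise ValueError("reposition mode requires chrom_lengths")
        for locus in loci:
            if locus.length > chrom_lengths.get(locus.chrom, 0):
                raise ValidationError(
                    f"chromosome {locus.chrom} shorter than locus {locus.id}"
                )
        for _ in range(n_perm):
            shuffled = [
                MirnaLocus(
                    id=l.id, chrom=l.chrom,
                    start=(s := int(rng.integers(0, chrom_lengths[l.chrom] - l.length + 1))),
                    end=s + l.length,
                    strand=l.strand, conservation=l.conservation,
                )
                for l in loci
            ]
            null.append(_count_label_in_clusters(shuffled, mid, label))
    else:
        # cluster structure fixed; only labels move
        members = clustered_ids(detect_clusters(loci, mid))
        in_cluster = np.array([l.id in members for l in loci])
        labels = np.array([l.conservation == label for l in loci])
        for _ in range(n_perm):
            null.append(int(labels[rng.permutation(len(labels))][in_cluster].sum()))

    p = (1 + sum(1 for x in null if x >= observed)) / (n_perm + 1)
    return EnrichmentResult(observed=observed, null=null, p_value=p,
                            n_perm=n_perm, seed=seed, mode=mode)
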