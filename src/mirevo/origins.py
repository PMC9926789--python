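"""Origin classification of clustered miRNAs.

For each cluster member, in genomic order:

* the 5'-most member is excluded ("excluded_first") — on its own it could
  not seed a cluster, and its own origin cannot be dated from within;
* conserved ("common") members are "inherited" and not searched further;
* otherwise the mature sequence is compared against every other focal
  mature miRNA; a qualifying similarity to a partner on the same
  chromosome is a cis-duplication, on a different chromosome a
  trans-duplication;
* equally good partners on both same and different chromosomes leave the
  member "undetermined";
* no qualifying partner at all means de novo formation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .clusters import MirnaCluster
from .families import DEFAULT_CRITERIA, SimilarityCriteria, similarity_match
from .io import MirnaLocus

ORIGIN_LABELS = (
    "inherited", "cis_duplication", "trans_duplication",
    "de_novo", "excluded_first", "undetermined",
)


@dataclass(frozen=True)
class OriginLabel:
    value: str
    partner_id: str | None = None
    aligned_len: int = 0
    mismatches: int = 0

    def __post_init__(self):
        if self.value not in ORIGIN_LABELS:
            raise ValueError(f"unknown origin label {self.value!r}")


def _midpoint(locus: MirnaLocus) -> float:
    return (locus.start + locus.end) / 2.0


def classify_origin(
    clusters: Sequence[MirnaCluster],
    loci: Sequence[MirnaLocus],
    criteria: SimilarityCriteria = DEFAULT_CRITERIA,
    cis_within_cluster_only: bool = False,
) -> dict[str, OriginLabel]:
    """Label every clustered miRNA with its inferred origin.

    The partner search runs over all focal miRNAs with a mature sequence
    (clustered or single, regardless of conservation).  The best partner
    maximizes aligned length, then minimizes mismatches; remaining ties are
    broken by genomic proximity on the same chromosome, then by id.  With
    ``cis_within_cluster_only`` a cis call additionally requires the
    partner to be a member of the same cluster.
    """
    by_id = {l.id: l for l in loci}
    for c in clusters:
        missing = [m for m in c.members if m not in by_id]
        if missing:
            raise KeyError(f"cluster {c.cluster_id} member(s) missing from loci: {missing}")

    searchable = [l for l in loci if l.mature_seq]
    labels: dict[str, OriginLabel] = {}
    for cluster in clusters:
        for rank, member_id in enumerate(cluster.members):
            member = by_id[member_id]
            if rank == 0:
                labels[member_id] = OriginLabel("excluded_first")
                continue
            if member.conservation == "common":
                labels[member_id] = OriginLabel("inherited")
                continue
            labels[member_id] = _classify_one(
                member, cluster, searchable, criteria, cis_within_cluster_only
            )
    return labels


def _classify_one(member, cluster, searchable, criteria,
                  cis_within_cluster_only) -> OriginLabel:
    if not member.mature_seq:
        return OriginLabel("undetermined")
    hits = []  # (aligned_len, mismatches, partner locus)
    for other in searchable:
        if other.id == member.id:
            continue
        res = similarity_match(member.mature_seq, other.mature_seq, criteria)
        if res.passes:
            hits.append((res.aligned_len, res.mismatches, other))
    if not hits:
        return OriginLabel("de_novo")

    best_quality = max((ln, -mm) for ln, mm, _ in hits)
    top = [h for h in hits if (h[0], -h[1]) == best_quality]
    same = [h for h in top if h[2].chrom == member.chrom]
    diff = [h for h in top if h[2].chrom != member.chrom]
    if same and diff:
        return OriginLabel("undetermined")

    if same:
        same.sort(key=lambda h: (abs(_midpoint(h[2]) - _midpoint(member)), h[2].id))
        ln, mm, partner = same[0]
        if cis_within_cluster_only and partner.id not in cluster.members:
            return OriginLabel("undetermined", partner_id=partner.id,
                               aligned_len=ln, mismatches=mm)
        return OriginLabel("cis_duplication", partner_id=partner.id,
                           aligned_len=ln, mismatches=mm)
    diff.sort(key=lambda h: h[2].id)
    ln, mm, partner = diff[0]
    return OriginLabel("trans_duplication", partner_id=partner.id,
                       aligned_len=ln, mismatches=mm)


@dataclass
class OriginSummary:
    counts: dict[str, int]
    duplication_total: int
    n_classified: int

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def origin_summary(origins: Mapping[str, OriginLabel]) -> OriginSummary:
    """Tally origin labels; the duplication total is cis + trans."""
    if not origins:
        raise ValueError("origin_summary requires a nonempty label map")
    counts = {label: 0 for label in ORIGIN_LABELS}
    for lab in origins.values():
        counts[lab.value] += 1
    dup = counts["cis_duplication"] + counts["trans_duplication"]
    classified = sum(
        counts[l] for l in ("inherited", "cis_duplication",
                            "trans_duplication", "de_novo", "undetermined")
    )
    return OriginSummary(counts=counts, duplication_total=dup, n_classified=classified)
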