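"""Mature-miRNA sequence similarity, family assignment and conservation labels.

Two mature miRNAs are similar when they share a gapless aligned block of at
least ``min_align_len`` nt (default 15) with at most ``max_mismatch``
mismatches (default 2) that covers the seed region, positions 2-8 of the
mature sequence.  Mature miRNAs are 18-30 nt, so an exhaustive scan over
all relative offsets of the two sense strands is exact and replaces a
heuristic aligner.

Families are the single-linkage transitive closure of pairwise similarity;
conservation labelling marks a miRNA "common" when it is similar to any
mature miRNA of a reference species set, else "specific".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .io import MATURE_MAX_LEN, MATURE_MIN_LEN, ValidationError, normalize_seq

_VALID = set("ACGT")


@dataclass(frozen=True)
class SimilarityCriteria:
    min_align_len: int = 15
    max_mismatch: int = 2
    seed_region: tuple[int, int] = (2, 8)   # 1-based inclusive positions
    require_seed_both: bool = False         # strict mode: seed of both sequences

    def __post_init__(self):
        if self.min_align_len < 7:
            raise ValueError("min_align_len must be >= 7")
        lo, hi = self.seed_region
        if not (1 <= lo <= hi):
            raise ValueError("bad seed region")


DEFAULT_CRITERIA = SimilarityCriteria()


@dataclass(frozen=True)
class MatchResult:
    aligned_len: int
    mismatches: int
    covers_seed: bool
    passes: bool


def _validate(seq: str, which: str) -> str:
    seq = normalize_seq(seq)
    if not set(seq) <= _VALID:
        raise ValidationError(f"{which} sequence contains non-ACGT(U) characters")
    if not (MATURE_MIN_LEN <= len(seq) <= MATURE_MAX_LEN):
        raise ValidationError(
            f"{which} sequence length {len(seq)} outside "
            f"[{MATURE_MIN_LEN}, {MATURE_MAX_LEN}]"
        )
    return seq


def similarity_match(a: str, b: str,
                     criteria: SimilarityCriteria = DEFAULT_CRITERIA) -> MatchResult:
    """Best gapless block shared by two mature sequences over all offsets.

    A candidate block at a given relative offset is a contiguous run of
    aligned positions.  ``passes`` requires a block of length >=
    ``min_align_len`` with <= ``max_mismatch`` mismatches that covers the
    seed region of ``a`` (of both sequences with ``require_seed_both``).
    The reported block maximizes aligned length, then minimizes mismatches;
    when no block passes, the longest full-overlap block is reported.
    """
    a = _validate(a, "first")
    b = _validate(b, "second")
    seed_lo = criteria.seed_region[0] - 1          # 0-based inclusive
    seed_hi = criteria.seed_region[1] - 1
    la, lb = len(a), len(b)

    best_pass: tuple[int, int] | None = None       # (len, mm) of best passing block
    best_any: tuple[int, int] | None = None        # best full-overlap block

    # offset o: position i of `a` aligns to position i - o of `b`
    for o in range(-(lb - 1), la):
        lo = max(0, o)
        hi = min(la, o + lb)
        if hi - lo < 1:
            continue
        mism = [a[i] != b[i - o] for i in range(lo, hi)]
        prefix = [0]
        for m in mism:
            prefix.append(prefix[-1] + m)
        full = (hi - lo, prefix[-1])
        if best_any is None or (full[0], -full[1]) > (best_any[0], -best_any[1]):
            best_any = full

        # passing blocks must contain [seed_lo, seed_hi] of `a`
        if lo > seed_lo or hi <= seed_hi:
            continue
        if criteria.require_seed_both:
            # the aligned b positions of the block must contain b's seed too
            if lo - o > seed_lo or hi - o <= seed_hi:
                continue
        for s in range(lo, seed_lo + 1):
            # longest e >= seed_hi with mismatches(s..e) <= max_mismatch
            e_best = -1
            for e in range(seed_hi, hi):
                if prefix[e + 1 - lo] - prefix[s - lo] <= criteria.max_mismatch:
                    e_best = e
            if e_best < 0:
                continue
            blk_len = e_best - s + 1
            blk_mm = prefix[e_best + 1 - lo] - prefix[s - lo]
            if blk_len >= criteria.min_align_len:
                cand = (blk_len, blk_mm)
                if best_pass is None or (cand[0], -cand[1]) > (best_pass[0], -best_pass[1]):
                    best_pass = cand

    if best_pass is not None:
        return MatchResult(aligned_len=best_pass[0], mismatches=best_pass[1],
                           covers_seed=True, passes=True)
    ln, mm = best_any if best_any is not None else (0, 0)
    return MatchResult(aligned_len=ln, mismatches=mm, covers_seed=False, passes=False)


def pair_passes(a: str, b: str,
                criteria: SimilarityCriteria = DEFAULT_CRITERIA) -> bool:
    """Symmetrized pass used for clustering: either direction suffices."""
    if similarity_match(a, b, criteria).passes:
        return True
    return similarity_match(b, a, criteria).passes


# ---------------------------------------------------------------------------
# families


@dataclass
class FamilyTable:
    families: dict[str, list[str]]   # family id -> sorted member ids

    @property
    def n_families(self) -> int:
        return len(self.families)

    def family_of(self) -> dict[str, str]:
        return {m: fid for fid, members in self.families.items() for m in members}

    def genes_per_family(self) -> dict[str, int]:
        return {fid: len(members) for fid, members in self.families.items()}

    @property
    def mean_genes_per_family(self) -> float:
        if not self.families:
            return 0.0
        return sum(len(m) for m in self.families.values()) / len(self.families)


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def assign_families(matures: Mapping[str, str],
                    criteria: SimilarityCriteria = DEFAULT_CRITERIA) -> FamilyTable:
    """Single-linkage families over pairwise similarity; the family id is
    the lexicographically smallest member id."""
    ids = sorted(matures)
    if len(ids) != len(set(ids)):
        raise ValidationError("duplicate miRNA ids")
    uf = _UnionFind(ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if pair_passes(matures[a], matures[b], criteria):
                uf.union(a, b)
    families: dict[str, list[str]] = {}
    for x in ids:
        families.setdefault(uf.find(x), []).append(x)
    return FamilyTable(families={fid: sorted(ms) for fid, ms in sorted(families.items())})


def label_conservation(
    matures: Mapping[str, str],
    reference_sets: Mapping[str, Mapping[str, str]],
    criteria: SimilarityCriteria = DEFAULT_CRITERIA,
) -> dict[str, str]:
    """Label each focal mature "common" iff it is similar to any reference
    species' mature miRNA, else "specific"."""
    if not reference_sets or all(len(v) == 0 for v in reference_sets.values()):
        raise ValidationError("at least one non-empty reference set is required")
    labels: dict[str, str] = {}
    ref_seqs = [seq for refs in reference_sets.values() for seq in refs.values()]
    for mid, seq in matures.items():
        labels[mid] = (
            "common"
            if any(similarity_match(seq, r, criteria).passes for r in ref_seqs)
            else "specific"
        )
    return labels


def apply_conservation(loci, labels: Mapping[str, str]):
    """Return loci with conservation labels applied (ids absent from
    ``labels`` keep their current label)."""
    return [
        l.with_conservation(labels[l.id]) if l.id in labels else l
        for l in loci
    ]
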