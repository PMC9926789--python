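"""Flanking-normalized miRNA evolution rates.

For an orthologous precursor pair the divergence of the precursor (Kp) is
normalized by the divergence of equal-length flanking sequence (Kf),
giving K = Kp / Kf.  Flanks act as a local neutral proxy, so K < 1
indicates the precursor changes more slowly than its genomic
neighbourhood (purifying selection), K ~ 1 neutrality.

Distances are per-site nucleotide divergences under p-distance, JC69 or
K2P; K is a ratio, so any consistent nucleotide model serves — K2P is the
default.  Unequal-length inputs are globally aligned first (match +1,
mismatch -1, gap -2) and gap columns excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Seq import Seq
from scipy import stats

from .io import MirnaLocus, normalize_seq

MODELS = ("p-distance", "JC69", "K2P")

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


class DistanceUndefinedError(ArithmeticError):
    """Divergence too high for the correction formula (saturation)."""


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 1
    al.mismatch_score = -1
    al.open_gap_score = -2
    al.extend_gap_score = -2
    return al


def _aligned_columns(seq_a: str, seq_b: str) -> list[tuple[str, str]]:
    """Ungapped aligned columns; same-length input is taken as aligned."""
    seq_a, seq_b = normalize_seq(seq_a), normalize_seq(seq_b)
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    if len(seq_a) == len(seq_b):
        return list(zip(seq_a, seq_b))
    aln = _aligner().align(seq_a, seq_b)[0]
    cols = []
    for x, y in zip(str(aln[0]), str(aln[1])):
        if x != "-" and y != "-":
            cols.append((x, y))
    return cols


def pairwise_distance(seq_a: str, seq_b: str, model: str = "K2P") -> float:
    """Per-site substitution distance between two sequences.

    Raises :class:`DistanceUndefinedError` when the correction formula is
    undefined (JC69 at p >= 3/4; K2P log arguments <= 0) and ValueError
    when no ungapped columns remain.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    cols = _aligned_columns(seq_a, seq_b)
    n = len(cols)
    if n == 0:
        raise ValueError("no ungapped aligned columns")
    mism = sum(1 for x, y in cols if x != y)
    p = mism / n
    if model == "p-distance":
        return p
    if model == "JC69":
        if p >= 0.75:
            raise DistanceUndefinedError(f"JC69 undefined at p = {p:.3f} >= 0.75")
        return -0.75 * math.log(1 - (4.0 / 3.0) * p)
    # K2P
    ts = sum(
        1 for x, y in cols
        if x != y and ({x, y} <= _PURINES or {x, y} <= _PYRIMIDINES)
    )
    P = ts / n
    Q = (mism - ts) / n
    arg1 = 1 - 2 * P - Q
    arg2 = 1 - 2 * Q
    if arg1 <= 0 or arg2 <= 0:
        raise DistanceUndefinedError(f"K2P undefined at P = {P:.3f}, Q = {Q:.3f}")
    return -0.5 * math.log(arg1) - 0.25 * math.log(arg2)


# ---------------------------------------------------------------------------
# flank extraction


@dataclass(frozen=True)
class FlankResult:
    upstream: str | None
    downstream: str | None
    truncated: bool


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def extract_flanks(locus: MirnaLocus, genome: Mapping[str, str],
                   side: str = "both") -> FlankResult:
    """Flanking sequence of precursor length on each requested side.

    Strand-aware: for minus-strand loci the flanks are reverse-complemented
    and up/downstream swap (upstream = 5' of the transcribed precursor).
    Flanks running off the chromosome are truncated and flagged; a side
    with zero available sequence raises.
    """
    if side not in ("up", "down", "both"):
        raise ValueError(f"bad side {side!r}")
    if locus.chrom not in genome:
        raise KeyError(f"chromosome {locus.chrom} not in genome")
    chrom_seq = genome[locus.chrom]
    flank_len = locus.length
    left = chrom_seq[max(0, locus.start - flank_len):locus.start]
    right = chrom_seq[locus.end:locus.end + flank_len]
    truncated = len(left) < flank_len or len(right) < flank_len
    if locus.strand == "+":
        up, down = left, right
    else:
        up, down = _revcomp(right), _revcomp(left)

    want_up = side in ("up", "both")
    want_down = side in ("down", "both")
    if want_up and not up:
        raise ValueError(f"locus {locus.id}: no upstream flank available")
    if want_down and not down:
        raise ValueError(f"locus {locus.id}: no downstream flank available")
    return FlankResult(upstream=up if want_up else None,
                       downstream=down if want_down else None,
                       truncated=truncated)


# ---------------------------------------------------------------------------
# K = Kp / Kf


@dataclass(frozen=True)
class OrthologPair:
    pair_id: str
    focal_precursor: str
    ortholog_precursor: str
    focal_flank_up: str | None = None
    focal_flank_down: str | None = None
    ortholog_flank_up: str | None = None
    ortholog_flank_down: str | None = None
    focal_species: str = "focal"
    ortholog_species: str = "ortholog"

    def __post_init__(self):
        if not self.focal_precursor or not self.ortholog_precursor:
            raise ValueError("precursor sequences must be non-empty")


@dataclass
class RateResult:
    pair_id: str
    K_p: float
    K_f: float | None
    K: float | None
    K_f_up: float | None
    K_f_down: float | None
    model: str
    status: str  # "ok" | "undefined"


def evolution_rate(pair: OrthologPair, model: str = "K2P") -> RateResult:
    """Kp from the precursor pair, Kf as the mean of the available flank
    divergences, K = Kp/Kf (undefined when Kf = 0 or any distance
    saturates)."""
    sides = []
    if pair.focal_flank_up and pair.ortholog_flank_up:
        sides.append(("up", pair.focal_flank_up, pair.ortholog_flank_up))
    if pair.focal_flank_down and pair.ortholog_flank_down:
        sides.append(("down", pair.focal_flank_down, pair.ortholog_flank_down))
    if not sides:
        raise ValueError(f"pair {pair.pair_id}: no flank pair available")
    try:
        kp = pairwise_distance(pair.focal_precursor, pair.ortholog_precursor, model)
        kf_by_side = {name: pairwise_distance(a, b, model) for name, a, b in sides}
    except DistanceUndefinedError:
        return RateResult(pair.pair_id, math.nan, None, None, None, None,
                          model, "undefined")
    kf = float(np.mean(list(kf_by_side.values())))
    if kf == 0.0:
        return RateResult(pair.pair_id, kp, kf, None,
                          kf_by_side.get("up"), kf_by_side.get("down"),
                          model, "undefined")
    return RateResult(pair.pair_id, kp, kf, kp / kf,
                      kf_by_side.get("up"), kf_by_side.get("down"),
                      model, "ok")


def rates_for_pairs(pairs: Sequence[OrthologPair], model: str = "K2P") -> list[RateResult]:
    return [evolution_rate(p, model) for p in pairs]


# ---------------------------------------------------------------------------
# group comparison: one-way ANOVA + LSD post-hoc


@dataclass
class GroupComparison:
    F: float
    p_value: float
    df_between: int
    df_within: int
    mse: float
    lsd: list[dict]   # per pair: group_a, group_b, diff, t, p


def group_rate_compare(groups: Mapping[str, Sequence[float]]) -> GroupComparison:
    """One-way ANOVA over the groups plus Fisher's LSD pairwise contrasts.

    LSD uses the pooled mean squared error and residual degrees of freedom
    from the ANOVA; p-values are two-sided.
    """
    names = [g for g in groups]
    if len(names) < 2:
        raise ValueError("need at least two groups")
    data = {g: np.asarray(list(groups[g]), dtype=float) for g in names}
    for g, x in data.items():
        if len(x) < 2:
            raise ValueError(f"group {g!r} needs n >= 2")
    k = len(names)
    n_total = sum(len(x) for x in data.values())
    grand = np.concatenate(list(data.values())).mean()
    ss_between = sum(len(x) * (x.mean() - grand) ** 2 for x in data.values())
    ss_within = sum(((x - x.mean()) ** 2).sum() for x in data.values())
    df_b, df_w = k - 1, n_total - k
    ms_between = ss_between / df_b
    mse = ss_within / df_w
    if mse == 0:
        F = math.inf if ms_between > 0 else 0.0
        p = 0.0 if ms_between > 0 else 1.0
    else:
        F = ms_between / mse
        p = float(stats.f.sf(F, df_b, df_w))

    lsd = []
    for i, ga in enumerate(names):
        for gb in names[i + 1:]:
            xa, xb = data[ga], data[gb]
            diff = xa.mean() - xb.mean()
            if mse == 0:
                t = math.inf if diff != 0 else 0.0
                pt = 0.0 if diff != 0 else 1.0
            else:
                se = math.sqrt(mse * (1 / len(xa) + 1 / len(xb)))
                t = diff / se
                pt = float(2 * stats.t.sf(abs(t), df_w))
            lsd.append({"group_a": ga, "group_b": gb, "diff": diff, "t": t, "p": pt})
    return GroupComparison(F=float(F), p_value=float(p), df_between=df_b,
                           df_within=df_w, mse=float(mse), lsd=lsd)
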