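"""Survey-scale synthetic dataset builders.

These construct a synthetic miRNA repertoire whose *marginal composition*
matches the genome-wide grass carp miRNA survey that motivates this
package: 1,513 miRNAs of which 397 sit in 171 clusters (sizes 2-3 here),
71 conserved ("common") miRNAs of which 52 are clustered, genomic-context
margins of 71 repeat / 79 exon / 493 intron / 870 intergenic overall and
7 / 16 / 104 / 270 among clustered loci, a 64-miRNA collinear-block set
with 40 members clustered, the printed origin partition of clustered
miRNAs, and 327 strictly tissue-specific miRNAs split 3 muscle / 11
intestine / 12 heart / 14 gill / 38 brain / 249 hatching.

Only the composition is real; coordinates and sequences are synthetic.
Running the analysis modules over these datasets checks that the summary
arithmetic (percentages, ratios, totals) reproduces the survey's headline
numbers from its raw counts.
"""

from __future__ import annotations

import numpy as np

from .io import AnnotationSet, ExpressionMatrix, MirnaLocus
from .origins import OriginLabel
from .simulate import ExpressionSimConfig, simulate_expression

N_TOTAL = 1513
CLUSTER_SIZES = [2] * 116 + [3] * 55          # 171 clusters, 397 members
CLUSTERED_CONTEXT = {"repeat": 7, "exon": 16, "intron": 104, "intergenic": 270}
SINGLE_CONTEXT = {"repeat": 64, "exon": 63, "intron": 389, "intergenic": 600}
CLUSTERED_COMMON, CLUSTERED_SPECIFIC = 52, 345
SINGLE_COMMON, SINGLE_SPECIFIC = 19, 1097
COLLINEAR_CLUSTERED, COLLINEAR_SINGLE = 40, 24
ORIGIN_COUNTS = {
    "inherited": 52,
    "cis_duplication": 104,
    "trans_duplication": 26,
    "de_novo": 159,
    "undetermined": 56,
}
TISSUE_SPECIFIC_COUNTS = {
    "muscle": 3, "intestine": 11, "heart": 12,
    "gill": 14, "brain": 38, "hatching": 249,
}

_N_CHROM = 24
_CHROM_LEN = 2_000_000
_PRE_LEN = 80


def _expand(counts: dict[str, int], rng: np.random.Generator) -> list[str]:
    out = [k for k, n in counts.items() for _ in range(n)]
    rng.shuffle(out)
    return out


def survey_scale_loci(seed: int = 0):
    """Build the survey-scale locus set.

    Returns (loci, annotation, collinear_ids).  Cluster members sit 2-8 kb
    apart; distinct groups are separated by > 10 kb so cluster detection
    at the standard threshold recovers exactly the planted clusters.
    Context is planted by laying a feature interval directly over each
    non-intergenic locus.
    """
    rng = np.random.default_rng([int(seed), 61])
    n_clustered = sum(CLUSTER_SIZES)
    clustered_ctx = _expand(CLUSTERED_CONTEXT, rng)
    single_ctx = _expand(SINGLE_CONTEXT, rng)
    clustered_cons = _expand(
        {"common": CLUSTERED_COMMON, "specific": CLUSTERED_SPECIFIC}, rng)
    single_cons = _expand({"common": SINGLE_COMMON, "specific": SINGLE_SPECIFIC}, rng)

    n_singles = N_TOTAL - n_clustered
    groups: list[dict] = [{"kind": "cluster", "size": s} for s in CLUSTER_SIZES]
    groups += [{"kind": "single"} for _ in range(n_singles)]
    order = rng.permutation(len(groups))
    groups = [groups[i] for i in order]

    chroms = [f"chr{i + 1}" for i in range(_N_CHROM)]
    cursors = {c: 10_000 for c in chroms}
    loci: list[MirnaLocus] = []
    intervals: list[tuple[str, int, int, str]] = []
    collinear: list[str] = []
    cl_i = si = 0
    counter = 0
    clustered_collinear_slots = set(
        rng.choice(n_clustered, size=COLLINEAR_CLUSTERED, replace=False))
    single_collinear_slots = set(
        rng.choice(n_singles, size=COLLINEAR_SINGLE, replace=False))

    def emit(chrom: str, start: int, ctx: str, cons: str) -> MirnaLocus:
        nonlocal counter
        counter += 1
        locus = MirnaLocus(id=f"cid-mir-{counter:04d}", chrom=chrom,
                           start=start, end=start + _PRE_LEN,
                           conservation=cons)
        if ctx != "intergenic":
            intervals.append((chrom, start - 5, start + _PRE_LEN + 5, ctx))
        loci.append(locus)
        return locus

    gi = 0
    for g in groups:
        chrom = chroms[gi % _N_CHROM]
        gi += 1
        pos = cursors[chrom]
        if g["kind"] == "single":
            locus = emit(chrom, pos, single_ctx[si], single_cons[si])
            if si in single_collinear_slots:
                collinear.append(locus.id)
            si += 1
            end = locus.end
        else:
            next_start = pos
            for _ in range(g["size"]):
                locus = emit(chrom, next_start, clustered_ctx[cl_i],
                             clustered_cons[cl_i])
                if cl_i in clustered_collinear_slots:
                    collinear.append(locus.id)
                cl_i += 1
                next_start = locus.end + int(rng.integers(2_000, 8_000))
            end = loci[-1].end
        cursors[chrom] = end + 10_001 + int(rng.integers(0, 2_000))
        if cursors[chrom] > _CHROM_LEN - 30_000:
            raise RuntimeError("survey layout exceeded chromosome length")

    annotation = AnnotationSet(
        intervals=intervals,
        chrom_lengths={c: _CHROM_LEN for c in chroms},
    )
    return loci, annotation, collinear


def survey_origin_labels() -> dict[str, OriginLabel]:
    """Origin-label map for the 397 clustered miRNAs at the survey's
    printed per-category counts."""
    labels: dict[str, OriginLabel] = {}
    i = 0
    for value, n in ORIGIN_COUNTS.items():
        for _ in range(n):
            i += 1
            labels[f"cl-mir-{i:03d}"] = OriginLabel(value)
    return labels


def survey_expression(seed: int = 0) -> ExpressionMatrix:
    """Count matrix (6 tissues x 3 libraries) over the survey-scale
    repertoire with the printed per-tissue tissue-specific counts planted."""
    loci, _, _ = survey_scale_loci(seed)
    cfg = ExpressionSimConfig(
        tissues=tuple(TISSUE_SPECIFIC_COUNTS),
        cluster_loading=0.0,
        n_tissue_specific=dict(TISSUE_SPECIFIC_COUNTS),
    )
    em, _ = simulate_expression(loci, clusters=[], config=cfg, seed=seed)
    return em
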