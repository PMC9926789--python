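"""Expression analysis of miRNA count matrices.

Covers TPM normalization, expressed/tissue-specific calls on raw counts,
the tissue-specificity score

    T_i = 1/(n-1) * sum_j (1 - a_ij / max_j a_ij)

(1 for strictly single-tissue expression, 0 for perfectly uniform
expression; a_ij is the mean TPM of miRNA i over tissue j's replicate
libraries), expression correlation of neighbouring / duplicated miRNA
pairs, and a light-weight co-expression module detector used to measure
cluster/module concordance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .clusters import MirnaCluster, clustered_ids, gap_between
from .io import ExpressionMatrix, MirnaLocus
from .origins import OriginLabel

logger = logging.getLogger(__name__)

EXPRESSED_THRESHOLD = 3


def tpm_normalize(em: ExpressionMatrix) -> pd.DataFrame:
    """Transcripts-per-million: each library column scaled to sum 1e6."""
    totals = em.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"libraries with zero total count: {list(zero.index)}")
    return em.counts / totals * 1e6


def tissue_mean(matrix: pd.DataFrame, em: ExpressionMatrix) -> pd.DataFrame:
    """Average a per-library matrix over each tissue's replicate libraries."""
    cols = {t: em.libraries_of(t) for t in em.tissues}
    return pd.DataFrame({t: matrix[libs].mean(axis=1) for t, libs in cols.items()})


@dataclass
class ExpressedCalls:
    expressed: pd.DataFrame          # miRNA x tissue booleans
    tissue_specific: dict[str, str]  # miRNA id -> its single tissue
    per_tissue_specific: dict[str, int]
    total_specific: int
    threshold: float
    aggregate: str


def expressed_calls(em: ExpressionMatrix, threshold: float = EXPRESSED_THRESHOLD,
                    aggregate: str = "mean") -> ExpressedCalls:
    """Call a miRNA expressed in a tissue when its aggregated raw count is
    strictly greater than ``threshold``; tissue-specific = expressed in
    exactly one tissue."""
    if aggregate not in ("mean", "sum", "max"):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    agg = getattr(em.counts.T.groupby(em.library_tissue), aggregate)().T
    agg = agg[em.tissues]
    expressed = agg > threshold
    n_tissues = expressed.sum(axis=1)
    specific = {}
    for mid in expressed.index[n_tissues == 1]:
        specific[mid] = expressed.columns[expressed.loc[mid]][0]
    per_tissue = {t: sum(1 for v in specific.values() if v == t) for t in em.tissues}
    return ExpressedCalls(expressed=expressed, tissue_specific=specific,
                          per_tissue_specific=per_tissue,
                          total_specific=len(specific),
                          threshold=threshold, aggregate=aggregate)


def tissue_specificity(tissue_tpm: pd.DataFrame) -> pd.Series:
    """Tissue-specificity score per miRNA from a miRNA x tissue mean-TPM
    matrix; all-zero miRNAs are excluded (logged)."""
    n = tissue_tpm.shape[1]
    if n < 2:
        raise ValueError("tissue specificity needs at least 2 tissues")
    if (tissue_tpm.values < 0).any():
        raise ValueError("negative expression values")
    maxima = tissue_tpm.max(axis=1)
    zero = maxima[maxima == 0]
    if len(zero):
        logger.info("excluding %d all-zero miRNAs from tissue specificity", len(zero))
    kept = tissue_tpm.loc[maxima > 0]
    scores = (1 - kept.div(kept.max(axis=1), axis=0)).sum(axis=1) / (n - 1)
    scores.name = "T"
    return scores


def tissue_specificity_score(values: Sequence[float]) -> float:
    """Score for a single miRNA's per-tissue mean expression vector."""
    a = np.asarray(list(values), dtype=float)
    if a.size < 2:
        raise ValueError("need at least 2 tissues")
    m = a.max()
    if m <= 0:
        raise ValueError("all-zero expression vector has no defined score")
    return float((1 - a / m).sum() / (a.size - 1))


# ---------------------------------------------------------------------------
# neighbour / duplicate pair correlation


@dataclass(frozen=True)
class NeighborPair:
    id_a: str
    id_b: str
    gap: int | None            # bp for same-chromosome pairs, None otherwise
    relationship: str          # same_cluster | cis_duplicate | trans_duplicate | unrelated
    r: float


def _log_tpm(em: ExpressionMatrix, transform: str) -> pd.DataFrame:
    tpm = tpm_normalize(em)
    if transform == "log2p1":
        return np.log2(tpm + 1)
    if transform == "none":
        return tpm
    raise ValueError(f"unknown transform {transform!r}")


def _corr(x: np.ndarray, y: np.ndarray, method: str) -> float | None:
    if np.std(x) == 0 or np.std(y) == 0:
        return None
    if method == "pearson":
        return float(np.corrcoef(x, y)[0, 1])
    from scipy import stats
    return float(stats.spearmanr(x, y).statistic)


def neighbor_correlation(
    loci: Sequence[MirnaLocus],
    clusters: Sequence[MirnaCluster],
    origins: Mapping[str, OriginLabel] | None,
    em: ExpressionMatrix,
    transform: str = "log2p1",
    method: str = "pearson",
) -> list[NeighborPair]:
    """Expression correlation of genomically adjacent pairs and of
    cis/trans duplicate pairs, on log2(TPM+1) per-library profiles.

    Adjacent same-chromosome pairs are classed same_cluster when both
    members share a cluster, else unrelated; duplicate pairs come from the
    origin labels' partner evidence.  Pairs with a constant profile are
    excluded (correlation undefined).
    """
    mat = _log_tpm(em, transform)
    by_id = {l.id: l for l in loci}
    member_cluster: dict[str, str] = {}
    for c in clusters:
        for m in c.members:
            member_cluster[m] = c.cluster_id

    pairs: list[NeighborPair] = []
    seen: set[tuple[str, str]] = set()

    def add(a: str, b: str, gap: int | None, rel: str) -> None:
        key = tuple(sorted((a, b)))
        if key in seen or a not in mat.index or b not in mat.index:
            return
        r = _corr(mat.loc[a].values, mat.loc[b].values, method)
        if r is None:
            logger.info("constant profile; dropping pair (%s, %s)", a, b)
            return
        seen.add(key)
        pairs.append(NeighborPair(a, b, gap, rel, r))

    by_chrom: dict[str, list[MirnaLocus]] = {}
    for l in loci:
        by_chrom.setdefault(l.chrom, []).append(l)
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda l: (l.start, l.end, l.id))
        for a, b in zip(ordered, ordered[1:]):
            rel = (
                "same_cluster"
                if member_cluster.get(a.id) is not None
                and member_cluster.get(a.id) == member_cluster.get(b.id)
                else "unrelated"
            )
            add(a.id, b.id, gap_between(a, b), rel)

    if origins:
        for mid, lab in origins.items():
            if lab.value in ("cis_duplication", "trans_duplication") and lab.partner_id:
                a, b = by_id.get(mid), by_id.get(lab.partner_id)
                gap = gap_between(a, b) if a and b and a.chrom == b.chrom else None
                rel = ("cis_duplicate" if lab.value == "cis_duplication"
                       else "trans_duplicate")
                add(mid, lab.partner_id, gap, rel)
    return pairs


def pair_group_summary(pairs: Sequence[NeighborPair],
                       distance_cut: int = 10_000) -> pd.DataFrame:
    """Mean correlation by relationship and by distance bin (< / >= cut)."""
    rows = []
    for p in pairs:
        bin_ = None
        if p.gap is not None:
            bin_ = f"<{distance_cut}" if p.gap < distance_cut else f">={distance_cut}"
        rows.append({"relationship": p.relationship, "distance_bin": bin_, "r": p.r})
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    return (
        df.groupby(["relationship", "distance_bin"], dropna=False)["r"]
        .agg(["mean", "count"]).reset_index()
    )


# ---------------------------------------------------------------------------
# co-expression modules (simplified detector)


def assign_coexpression_modules(
    mat: pd.DataFrame,
    cut_height: float = 0.25,
    min_size: int = 3,
) -> dict[str, int | None]:
    """Average-linkage hierarchical modules on dissimilarity 1 - |r|.

    ``mat`` is a per-library expression matrix (rows = miRNAs), typically
    log2(TPM+1).  The dendrogram is cut at ``cut_height``; modules smaller
    than ``min_size`` are unassigned (None).  This is a deliberately small
    stand-in for heavier co-expression network pipelines: only the
    cluster/module concordance statistic downstream depends on it.
    """
    if not (0 < cut_height < 1):
        raise ValueError("cut_height must lie in (0, 1)")
    if mat.shape[0] < 3:
        raise ValueError("need at least 3 miRNAs")
    keep = mat.index[mat.std(axis=1) > 0]
    dropped = [m for m in mat.index if m not in set(keep)]
    modules: dict[str, int | None] = {m: None for m in dropped}
    if len(keep) < 2:
        modules.update({m: None for m in keep})
        return modules
    sub = mat.loc[keep]
    corr = np.corrcoef(sub.values)
    dis = 1 - np.abs(corr)
    np.fill_diagonal(dis, 0.0)
    dis = np.clip((dis + dis.T) / 2, 0, None)
    link = hierarchy.linkage(squareform(dis, checks=False), method="average")
    labels = hierarchy.fcluster(link, t=cut_height, criterion="distance")
    sizes = pd.Series(labels).value_counts()
    for mid, lab in zip(keep, labels):
        modules[mid] = int(lab) if sizes[lab] >= min_size else None
    return modules


def cluster_module_concordance(
    clusters: Sequence[MirnaCluster],
    modules: Mapping[str, int | None],
) -> tuple[float | None, int, int]:
    """Fraction of clusters whose members are all assigned to one module.

    Only clusters with every member assigned count toward the denominator.
    Returns (fraction or None, n_concordant, n_eligible).
    """
    eligible = concordant = 0
    for c in clusters:
        labs = [modules.get(m) for m in c.members]
        if any(l is None for l in labs):
            continue
        eligible += 1
        if len(set(labs)) == 1:
            concordant += 1
    frac = concordant / eligible if eligible else None
    return frac, concordant, eligible
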