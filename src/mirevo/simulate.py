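"""Synthetic data generators with recorded ground truth.

Every generator is deterministic given (config, seed) and returns a
:class:`SyntheticTruth` describing each planted property, so that the
analysis modules can be tested as round trips: generate with known
structure, analyze, compare against the truth.

The generators emulate the statistical structure of a teleost miRNA
survey — clustered loci with short geometric inter-locus gaps, cis/trans
duplication by sequence copying with point mutations, conservation as
near-copies in reference species sets, family presence/absence evolved by
single-origin gain and per-branch Poisson loss, and overdispersed count
matrices with a shared latent factor inside clusters plus strictly
single-tissue miRNAs — not the base composition or hairpin structure of
any real genome.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .birthdeath import _node_label, label_internal_nodes
from .io import (
    AnnotationSet,
    ExpressionMatrix,
    FamilyPresenceMatrix,
    MirnaLocus,
    PhyloTree,
)
from .rates import OrthologPair

_NUCS = np.array(list("ACGT"))

# one fixed substream id per generator so runs are reproducible regardless
# of call order
_STREAMS = {
    "genome": 1,
    "plant_mirnas": 2,
    "ortholog_pairs": 3,
    "family_evolution": 4,
    "expression": 5,
    "survey_scale": 6,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_NUCS, size=length))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Per-site substitution with probability ``rate`` (uniform over the
    three alternative bases)."""
    chars = np.array(list(seq))
    hit = rng.random(len(chars)) < rate
    for i in np.nonzero(hit)[0]:
        alternatives = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alternatives[rng.integers(3)]
    return "".join(chars)


@dataclass
class SyntheticTruth:
    """Ground truth for planted structure; fields are filled by whichever
    generator produced the dataset."""

    clusters: list[list[str]] = field(default_factory=list)
    origins: dict[str, str] = field(default_factory=dict)
    conservation: dict[str, str] = field(default_factory=dict)
    context: dict[str, str] = field(default_factory=dict)
    ortholog_q: dict[str, tuple[float, float]] = field(default_factory=dict)
    family_gain_branch: dict[str, str] = field(default_factory=dict)
    family_loss_branches: dict[str, list[str]] = field(default_factory=dict)
    tissue_specific: dict[str, str] = field(default_factory=dict)
    cluster_loading: float | None = None
    seed: int | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=list)


# ---------------------------------------------------------------------------
# genome + annotation


def generate_genome(
    n_chrom: int = 3,
    chrom_length: int = 1_000_000,
    annotation_density: Mapping[str, float] | None = None,
    seed: int = 0,
    feature_len: int = 500,
) -> tuple[dict[str, str], AnnotationSet]:
    """I.i.d. uniform ACGT chromosomes with non-overlapping exon / intron /
    repeat intervals placed at the requested per-class densities."""
    if chrom_length < 10_000:
        raise ValueError("chrom_length must be >= 1e4")
    density = dict(annotation_density or {})
    if sum(density.values()) > 1:
        raise ValueError("annotation densities sum above 1")
    rng = _rng(seed, "genome")
    genome: dict[str, str] = {}
    intervals: list[tuple[str, int, int, str]] = []
    chrom_lengths: dict[str, int] = {}
    for ci in range(1, n_chrom + 1):
        chrom = f"chr{ci}"
        genome[chrom] = _random_seq(rng, chrom_length)
        chrom_lengths[chrom] = chrom_length
        # fixed-length blocks laid down left-to-right with random spacers;
        # block counts hit the requested densities exactly (+- one block)
        blocks: list[str] = []
        for feat, d in density.items():
            blocks += [feat] * int(round(d * chrom_length / feature_len))
        rng.shuffle(blocks)
        occupied = len(blocks) * feature_len
        free = chrom_length - occupied
        if free < 0:
            raise ValueError("feature blocks exceed chromosome length")
        cuts = np.sort(rng.integers(0, free + 1, size=len(blocks)))
        pos = 0
        prev_cut = 0
        for feat, cut in zip(blocks, cuts):
            pos += int(cut) - prev_cut
            prev_cut = int(cut)
            intervals.append((chrom, pos, pos + feature_len, feat))
            pos += feature_len
    return genome, AnnotationSet(intervals=intervals, chrom_lengths=chrom_lengths)


# ---------------------------------------------------------------------------
# miRNA planting


@dataclass(frozen=True)
class PlantConfig:
    """Composition of the planted miRNA repertoire.

    Defaults give a desk-scale repertoire with the qualitative structure of
    a teleost survey: ~40% of loci clustered, clusters of 2-4 members with
    gaps well inside the 10-kb cluster threshold, duplications split
    roughly 2:1 cis:trans, and a minority of conserved miRNAs placed
    preferentially in clusters.
    """

    n_total: int = 100
    n_clusters: int = 15
    n_clustered: int = 40
    gap_mean: float = 2_000.0       # geometric mean inter-member gap (bp)
    n_cis: int = 10
    n_trans: int = 5
    n_conserved: int = 12
    conserved_clustered_fraction: float = 0.75
    mutation_rate: float = 0.01
    reference_mutation_rate: float = 0.01
    mature_len: int = 22
    precursor_len: int = 80
    mid: int = 10_000
    isolation: int = 12_000         # min gap separating planted groups
    n_ref_species: int = 2

    def __post_init__(self):
        if self.n_clustered > self.n_total:
            raise ValueError("n_clustered > n_total")
        if self.n_clusters * 2 > self.n_clustered:
            raise ValueError("n_clusters too large for n_clustered (need >=2 members)")
        if self.n_cis + self.n_trans > self.n_clustered - self.n_clusters:
            raise ValueError("n_cis + n_trans exceeds non-founder clustered members")
        if not 0 <= self.conserved_clustered_fraction <= 1:
            raise ValueError("conserved_clustered_fraction outside [0,1]")


def plant_mirnas(
    genome: Mapping[str, str],
    config: PlantConfig = PlantConfig(),
    seed: int = 0,
) -> tuple[list[MirnaLocus], dict[str, dict[str, str]], SyntheticTruth]:
    """Plant miRNA loci into a genome with known clusters, origins and
    conservation.

    Returns (loci, reference mature sets per species, truth).  Cluster
    members are separated by geometric gaps (mean ``gap_mean``, clipped to
    the cluster threshold); cis copies derive from an earlier member of the
    same cluster, trans copies from a single locus on another chromosome;
    conserved miRNAs get a lightly mutated copy in each reference set.
    Precursor sequences are spliced into the genome so flank extraction is
    consistent.
    """
    cfg = config
    rng = _rng(seed, "plant_mirnas")
    chroms = sorted(genome)
    if len(chroms) < 2 and cfg.n_trans > 0:
        raise ValueError("trans duplications need >= 2 chromosomes")
    genome_in = genome
    genome = {c: list(genome[c]) for c in chroms}

    # cluster sizes: spread members evenly, minimum 2
    sizes = [2] * cfg.n_clusters
    extra = cfg.n_clustered - 2 * cfg.n_clusters
    for i in range(extra):
        sizes[i % cfg.n_clusters] += 1

    n_singles = cfg.n_total - cfg.n_clustered
    groups: list[dict] = [{"kind": "cluster", "size": s} for s in sizes]
    groups += [{"kind": "single"} for _ in range(n_singles)]
    order = rng.permutation(len(groups))
    groups = [groups[i] for i in order]

    truth = SyntheticTruth(seed=seed)
    loci_raw: list[dict] = []
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"mir-{counter:04d}"

    # lay groups across chromosomes with isolation gaps; founder and
    # de-novo sequences are drawn here, duplicates overwritten below
    cursors = {c: int(rng.integers(1_000, 5_000)) for c in chroms}
    singles_by_chrom: dict[str, list[dict]] = {c: [] for c in chroms}
    cluster_records: list[list[dict]] = []
    ci = 0
    for g in groups:
        chrom = None
        for _ in range(len(chroms)):
            cand = chroms[ci % len(chroms)]
            ci += 1
            span = cfg.precursor_len
            if g["kind"] == "cluster":
                span = g["size"] * (cfg.precursor_len + cfg.mid)
            if cursors[cand] + span + cfg.isolation < len(genome[cand]):
                chrom = cand
                break
        if chrom is None:
            raise ValueError("genome too small for requested loci")
        if g["kind"] == "single":
            rec = _new_locus_rec(new_id(), chrom, cursors[chrom], cfg, rng)
            loci_raw.append(rec)
            singles_by_chrom[chrom].append(rec)
            cursors[chrom] = rec["end"] + cfg.isolation + int(rng.integers(0, 3_000))
        else:
            members = []
            pos = cursors[chrom]
            for _ in range(g["size"]):
                rec = _new_locus_rec(new_id(), chrom, pos, cfg, rng)
                members.append(rec)
                loci_raw.append(rec)
                gap = int(min(max(1, rng.geometric(1.0 / cfg.gap_mean)), cfg.mid))
                pos = rec["end"] + gap
            cluster_records.append(members)
            cursors[chrom] = members[-1]["end"] + cfg.isolation + int(rng.integers(0, 3_000))

    # assign origins among non-founder cluster members; cis copies derive
    # from their cluster founder (same chromosome by construction), trans
    # copies each from a distinct single locus on another chromosome
    non_founders = [rec for mem in cluster_records for rec in mem[1:]]
    idx = rng.permutation(len(non_founders))
    cis_set = [non_founders[i] for i in idx[:cfg.n_cis]]
    trans_set = [non_founders[i] for i in idx[cfg.n_cis:cfg.n_cis + cfg.n_trans]]
    for mem in cluster_records:
        truth.origins[mem[0]["id"]] = "excluded_first"
        for rec in mem[1:]:
            truth.origins[rec["id"]] = "de_novo"
    cis_source_ids: set[str] = set()
    for rec in cis_set:
        mem = next(m for m in cluster_records if rec in m)
        source = mem[0]
        cis_source_ids.add(source["id"])
        rec["mature_seq"] = _mutate(rng, source["mature_seq"], cfg.mutation_rate)
        rec["precursor_seq"] = _embed_mature(source["precursor_seq"],
                                             rec["mature_seq"], cfg)
        truth.origins[rec["id"]] = "cis_duplication"
    trans_source_ids: set[str] = set()
    available_singles = {c: list(recs) for c, recs in singles_by_chrom.items()}
    for rec in trans_set:
        other = [c for c in chroms if c != rec["chrom"] and available_singles[c]]
        if not other:
            raise ValueError("no unused single locus on another chromosome "
                             "for a trans duplication source")
        source = available_singles[other[int(rng.integers(len(other)))]].pop(0)
        trans_source_ids.add(source["id"])
        rec["mature_seq"] = _mutate(rng, source["mature_seq"], cfg.mutation_rate)
        rec["precursor_seq"] = _embed_mature(source["precursor_seq"],
                                             rec["mature_seq"], cfg)
        truth.origins[rec["id"]] = "trans_duplication"

    # conservation: conserved drawn from non-duplicate clustered members and
    # singles, excluding duplication sources — a conserved source would make
    # its copies match the reference set and shadow their planted origin
    dup_ids = {r["id"] for r in cis_set} | {r["id"] for r in trans_set}
    clustered_pool = [
        rec for mem in cluster_records for rec in mem
        if rec["id"] not in dup_ids and rec["id"] not in cis_source_ids
    ]
    single_pool = [rec for c in chroms for rec in singles_by_chrom[c]
                   if rec["id"] not in trans_source_ids]
    n_cons_clustered = min(
        int(round(cfg.n_conserved * cfg.conserved_clustered_fraction)),
        len(clustered_pool),
    )
    n_cons_single = cfg.n_conserved - n_cons_clustered
    if n_cons_single > len(single_pool):
        raise ValueError("not enough single loci for requested conserved count")
    conserved = (
        [clustered_pool[i] for i in rng.permutation(len(clustered_pool))[:n_cons_clustered]]
        + [single_pool[i] for i in rng.permutation(len(single_pool))[:n_cons_single]]
    )
    conserved_ids = {r["id"] for r in conserved}
    reference_sets: dict[str, dict[str, str]] = {
        f"refsp{i + 1}": {} for i in range(cfg.n_ref_species)
    }
    for rec in conserved:
        for sp in reference_sets:
            reference_sets[sp][f"{sp}-{rec['id']}"] = _mutate(
                rng, rec["mature_seq"], cfg.reference_mutation_rate
            )
    for rec in loci_raw:
        truth.conservation[rec["id"]] = (
            "common" if rec["id"] in conserved_ids else "specific"
        )
        # a conserved clustered non-founder is inherited, not de novo
        if rec["id"] in truth.origins and truth.origins[rec["id"]] == "de_novo" \
                and rec["id"] in conserved_ids:
            truth.origins[rec["id"]] = "inherited"

    truth.clusters = [[r["id"] for r in mem] for mem in cluster_records]

    # splice precursors into the genome and build loci
    loci: list[MirnaLocus] = []
    for rec in loci_raw:
        genome[rec["chrom"]][rec["start"]:rec["end"]] = list(rec["precursor_seq"])
        loci.append(MirnaLocus(
            id=rec["id"], chrom=rec["chrom"], start=rec["start"], end=rec["end"],
            strand="+", mature_seq=rec["mature_seq"],
            precursor_seq=rec["precursor_seq"],
            conservation=truth.conservation[rec["id"]],
        ))
    if isinstance(genome_in, dict):
        for c in chroms:
            genome_in[c] = "".join(genome[c])
    loci.sort(key=lambda l: (l.chrom, l.start))
    return loci, reference_sets, truth


def _new_locus_rec(locus_id: str, chrom: str, start: int, cfg: PlantConfig,
                   rng: np.random.Generator) -> dict:
    precursor = _random_seq(rng, cfg.precursor_len)
    offset = 10
    mature = precursor[offset:offset + cfg.mature_len]
    return {
        "id": locus_id, "chrom": chrom, "start": start,
        "end": start + cfg.precursor_len,
        "mature_seq": mature, "precursor_seq": precursor,
    }


def _embed_mature(source_precursor: str, mature: str, cfg: PlantConfig) -> str:
    offset = 10
    return (source_precursor[:offset] + mature
            + source_precursor[offset + cfg.mature_len:])


# ---------------------------------------------------------------------------
# ortholog pairs


def simulate_ortholog_pairs(
    n_pairs: int = 500,
    precursor_len: int = 80,
    q_p: float = 0.05,
    q_f: float = 0.2,
    seed: int = 0,
) -> tuple[list[OrthologPair], SyntheticTruth]:
    """Ortholog precursor + flank pairs with planted per-site substitution
    probabilities (q_p for the precursor, q_f for both flanks)."""
    if not (0 <= q_p < 0.75 and 0 <= q_f < 0.75):
        raise ValueError("q_p and q_f must lie in [0, 0.75)")
    rng = _rng(seed, "ortholog_pairs")
    pairs: list[OrthologPair] = []
    truth = SyntheticTruth(seed=seed)
    for i in range(n_pairs):
        pid = f"pair-{i + 1:04d}"
        pre = _random_seq(rng, precursor_len)
        up = _random_seq(rng, precursor_len)
        down = _random_seq(rng, precursor_len)
        pairs.append(OrthologPair(
            pair_id=pid,
            focal_precursor=pre,
            ortholog_precursor=_mutate(rng, pre, q_p),
            focal_flank_up=up,
            focal_flank_down=down,
            ortholog_flank_up=_mutate(rng, up, q_f),
            ortholog_flank_down=_mutate(rng, down, q_f),
        ))
        truth.ortholog_q[pid] = (q_p, q_f)
    return pairs, truth


# ---------------------------------------------------------------------------
# family presence/absence evolution


def simulate_family_evolution(
    tree: PhyloTree,
    n_families: int = 200,
    loss_rate: float = 0.001,
    seed: int = 0,
    root_gain_only: bool = False,
) -> tuple[FamilyPresenceMatrix, SyntheticTruth]:
    """Evolve family presence/absence by single-origin gain plus per-branch
    Poisson loss.

    Each family originates once, on a branch drawn with probability
    proportional to branch length (or on the root with
    ``root_gain_only``); below the gain, each branch loses the family with
    Poisson(loss_rate x length) >= 1 events.  Families extinct at every
    leaf are resampled so the matrix satisfies the presence invariant.
    """
    t = tree.tree
    label_internal_nodes(t)
    nodes = list(t.preorder_node_iter())
    lengths = np.array([n.edge.length or 0.0 for n in nodes])
    if lengths.sum() == 0:
        raise ValueError("tree has no positive branch lengths")
    rng = _rng(seed, "family_evolution")
    probs = lengths / lengths.sum()
    species = tree.leaf_names()
    truth = SyntheticTruth(seed=seed)
    rows = {}
    fam_i = 0
    while fam_i < n_families:
        fam = f"fam-{fam_i + 1:04d}"
        gain_node = t.seed_node if root_gain_only else nodes[rng.choice(len(nodes), p=probs)]
        present_leaves, loss_branches = _drop_losses(gain_node, loss_rate, rng)
        if not present_leaves:
            continue  # extinct everywhere; resample
        rows[fam] = {sp: int(sp in present_leaves) for sp in species}
        truth.family_gain_branch[fam] = _node_label(gain_node)
        truth.family_loss_branches[fam] = loss_branches
        fam_i += 1
    matrix = pd.DataFrame.from_dict(rows, orient="index")[species]
    return FamilyPresenceMatrix(matrix=matrix), truth


def _drop_losses(gain_node, loss_rate: float, rng) -> tuple[set[str], list[str]]:
    present: set[str] = set()
    losses: list[str] = []
    stack = [(gain_node, True)]
    while stack:
        node, alive = stack.pop()
        if alive and node is not gain_node:
            length = node.edge.length or 0.0
            if rng.poisson(loss_rate * length) >= 1:
                alive = False
                losses.append(_node_label(node))
        if node.is_leaf():
            if alive:
                present.add(node.taxon.label)
        else:
            for child in node.child_nodes():
                stack.append((child, alive))
    return present, losses


def random_dated_tree(n_leaves: int = 8, depth_my: float = 300.0,
                      seed: int = 0) -> PhyloTree:
    """Random coalescent-shaped ultrametric tree with depth in MY."""
    rng = _rng(seed, "family_evolution")
    taxa = dendropy.TaxonNamespace([f"sp{i + 1}" for i in range(n_leaves)])
    tree = dendropy.simulate.treesim.pure_kingman_tree(
        taxon_namespace=taxa,
        pop_size=1,
        rng=_PyRandomShim(rng),
    )
    max_depth = max(lf.distance_from_root() for lf in tree.leaf_node_iter())
    scale = depth_my / max_depth
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale
    return PhyloTree(tree=tree)


class _PyRandomShim:
    """Adapter exposing the random.Random surface dendropy expects on top
    of a numpy Generator."""

    def __init__(self, rng: np.random.Generator):
        self._rng = rng

    def random(self):
        return float(self._rng.random())

    def uniform(self, a, b):
        return float(self._rng.uniform(a, b))

    def randint(self, a, b):
        return int(self._rng.integers(a, b + 1))

    def expovariate(self, lambd):
        return float(self._rng.exponential(1.0 / lambd))

    def sample(self, population, k):
        population = list(population)
        idx = self._rng.choice(len(population), size=k, replace=False)
        return [population[i] for i in idx]

    def choice(self, seq):
        seq = list(seq)
        return seq[int(self._rng.integers(len(seq)))]

    def shuffle(self, x):
        self._rng.shuffle(x)


# ---------------------------------------------------------------------------
# expression simulation


@dataclass(frozen=True)
class ExpressionSimConfig:
    """Count-matrix simulation: six tissues x three replicate libraries,
    log-normal overdispersion, a per-cluster latent factor shared by
    cluster members, and strictly single-tissue planted miRNAs."""

    tissues: tuple[str, ...] = ("brain", "muscle", "gill", "intestine",
                                "heart", "hatching")
    n_libraries_per_tissue: int = 3
    cluster_loading: float = 0.8
    n_tissue_specific: int | Mapping[str, int] = 25
    dispersion: float = 0.3
    base_log_mean: float = 6.0
    tissue_sigma: float = 0.5

    def __post_init__(self):
        if not 0 <= self.cluster_loading < 1:
            raise ValueError("cluster_loading must lie in [0, 1)")


def simulate_expression(
    loci: Sequence[MirnaLocus],
    clusters: Sequence[Sequence[str]],
    config: ExpressionSimConfig = ExpressionSimConfig(),
    seed: int = 0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Simulate a raw count matrix over the given loci.

    Background miRNAs get counts ~ floor(2^x) with x = baseline + tissue
    effect + loading x cluster factor + noise (log-normal-mixed
    overdispersion); planted tissue-specific miRNAs get raw counts > 3 in
    every library of exactly one tissue and <= 3 elsewhere, so threshold
    calls can be checked exactly against the truth.
    """
    cfg = config
    rng = _rng(seed, "expression")
    libraries = [f"{t}_{r + 1}" for t in cfg.tissues
                 for r in range(cfg.n_libraries_per_tissue)]
    library_tissue = {lib: lib.rsplit("_", 1)[0] for lib in libraries}
    ids = [l.id for l in loci]

    member_cluster: dict[str, int] = {}
    for k, mem in enumerate(clusters):
        for m in mem:
            member_cluster[m] = k

    if isinstance(cfg.n_tissue_specific, Mapping):
        spec_plan = dict(cfg.n_tissue_specific)
    else:
        spec_plan = {}
        for i in range(cfg.n_tissue_specific):
            t = cfg.tissues[i % len(cfg.tissues)]
            spec_plan[t] = spec_plan.get(t, 0) + 1
    n_specific = sum(spec_plan.values())
    if n_specific > len(ids):
        raise ValueError("more planted tissue-specific miRNAs than loci")
    # prefer single (unclustered) loci as tissue-specific so cluster
    # correlation structure stays intact
    singles = [i for i in ids if i not in member_cluster]
    pool = singles + [i for i in ids if i in member_cluster]
    specific_ids = pool[:n_specific]
    truth = SyntheticTruth(seed=seed, cluster_loading=cfg.cluster_loading)
    assign_iter = iter(specific_ids)
    for tissue, count in spec_plan.items():
        if tissue not in cfg.tissues:
            raise ValueError(f"unknown tissue {tissue!r} in n_tissue_specific")
        for _ in range(count):
            truth.tissue_specific[next(assign_iter)] = tissue

    factor = rng.normal(size=(len(clusters), len(libraries)))
    counts = np.zeros((len(ids), len(libraries)), dtype=int)
    for i, mid in enumerate(ids):
        if mid in truth.tissue_specific:
            target = truth.tissue_specific[mid]
            for j, lib in enumerate(libraries):
                if library_tissue[lib] == target:
                    counts[i, j] = int(rng.integers(10, 200))
                else:
                    counts[i, j] = int(rng.integers(0, 4))  # <= 3
            continue
        base = max(4.5, rng.normal(cfg.base_log_mean, 1.0))
        tissue_eff = {t: float(np.clip(rng.normal(0, cfg.tissue_sigma), -1, 1))
                      for t in cfg.tissues}
        for j, lib in enumerate(libraries):
            x = base + tissue_eff[library_tissue[lib]]
            if mid in member_cluster:
                x += cfg.cluster_loading * factor[member_cluster[mid], j]
            x += rng.normal(0, cfg.dispersion)
            counts[i, j] = int(np.floor(2 ** x))
    em = ExpressionMatrix(
        counts=pd.DataFrame(counts, index=ids, columns=libraries),
        library_tissue=library_tissue,
        tissues=list(cfg.tissues),
    )
    return em, truth
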