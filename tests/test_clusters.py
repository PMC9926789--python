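import itertools

import numpy as np
import pytest

from mirevo.clusters import (
    MirnaCluster,
    cluster_summary,
    clustered_ids,
    detect_clusters,
    enrichment_permutation_test,
    fraction_clustered,
    gap_between,
)
from mirevo.io import MirnaLocus, ValidationError
from tests.conftest import random_loci


def oracle_components(loci, mid):
    """All-pairs gap graph connected components (independent oracle)."""
    ids = [l.id for l in loci]
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for a, b in itertools.combinations(loci, 2):
        if a.chrom == b.chrom and gap_between(a, b) <= mid:
            ra, rb = find(a.id), find(b.id)
            if ra != rb:
                parent[ra] = rb
    comps = {}
    for l in loci:
        comps.setdefault(find(l.id), set()).add(l.id)
    return {frozenset(c) for c in comps.values() if len(c) >= 2}


def test_basic_two_member_cluster(five_loci):
    clusters = detect_clusters(five_loci, mid=10_000)
    members = {frozenset(c.members) for c in clusters}
    assert frozenset({"mirA", "mirB"}) in members          # gap 4820
    assert frozenset({"mirD", "mirE"}) in members          # gap 620
    assert "mirC" not in clustered_ids(clusters)           # gap 24920


def test_single_locus_no_cluster():
    assert detect_clusters([MirnaLocus("m", "chr1", 0, 80)]) == []


def test_cluster_needs_two_members():
    with pytest.raises(ValidationError):
        MirnaCluster("c", "chr1", ("only",), (0, 80))


def test_detection_invariant_to_input_order(five_loci):
    rng = np.random.default_rng(0)
    base = detect_clusters(five_loci)
    for _ in range(5):
        shuffled = list(five_loci)
        rng.shuffle(shuffled)
        assert detect_clusters(shuffled) == base


def test_monotone_in_mid():
    rng = np.random.default_rng(3)
    loci = random_loci(rng, 100, chrom_len=500_000)
    prev = set()
    for mid in (1_000, 5_000, 20_000, 100_000):
        now = clustered_ids(detect_clusters(loci, mid))
        assert prev <= now
        prev = now


def test_each_locus_in_at_most_one_cluster():
    rng = np.random.default_rng(4)
    loci = random_loci(rng, 200, chrom_len=300_000)
    clusters = detect_clusters(loci, mid=5_000)
    all_members = [m for c in clusters for m in c.members]
    assert len(all_members) == len(set(all_members))
    assert all(c.size >= 2 for c in clusters)


def test_matches_all_pairs_gap_oracle():
    rng = np.random.default_rng(5)
    for _ in range(200):
        n = int(rng.integers(2, 40))
        loci = random_loci(rng, n, n_chrom=2, chrom_len=int(rng.integers(5_000, 300_000)))
        mid = int(rng.integers(100, 20_000))
        got = {frozenset(c.members) for c in detect_clusters(loci, mid)}
        assert got == oracle_components(loci, mid)


def test_cluster_summary_percentages(five_loci):
    loci = [
        l.with_conservation("common" if l.id in ("mirA", "mirC") else "specific")
        for l in five_loci
    ]
    clusters = detect_clusters(loci)
    summ = cluster_summary(clusters, loci)
    assert summ.n_clustered == 4
    assert summ.pct_clustered == 80.0
    assert summ.per_class_pct["common"] == 50.0    # 1 of 2 common clustered
    assert fraction_clustered(["mirA", "mirC"], clusters) == 50.0


def test_no_clusters_all_fractions_zero():
    loci = [MirnaLocus("a", "chr1", 0, 80), MirnaLocus("b", "chr1", 50_000, 50_080)]
    summ = cluster_summary(detect_clusters(loci), loci)
    assert summ.pct_clustered == 0.0
    assert summ.n_clusters == 0


def test_label_shuffle_all_common_gives_p_one(five_loci):
    loci = [l.with_conservation("common") for l in five_loci]
    res = enrichment_permutation_test(loci, n_perm=50, seed=1, mode="label_shuffle")
    assert res.p_value == 1.0
    assert all(x == res.observed for x in res.null)


def test_label_shuffle_matches_exact_enumeration():
    """Empirical label-shuffle p converges to the exact permutation p on a
    toy where all label assignments can be enumerated."""
    # 6 loci: 4 clustered (two pairs), 2 single; 2 carry the label
    loci = [
        MirnaLocus("a", "chr1", 0, 80, conservation="common"),
        MirnaLocus("b", "chr1", 500, 580, conservation="common"),
        MirnaLocus("c", "chr1", 40_000, 40_080, conservation="specific"),
        MirnaLocus("d", "chr1", 40_500, 40_580, conservation="specific"),
        MirnaLocus("e", "chr2", 0, 80, conservation="specific"),
        MirnaLocus("f", "chr2", 50_000, 50_080, conservation="specific"),
    ]
    clusters = detect_clusters(loci)
    in_cluster = clustered_ids(clusters)
    observed = sum(1 for l in loci if l.id in in_cluster and l.conservation == "common")
    # exact: count label placements with statistic >= observed
    ids = [l.id for l in loci]
    tail = total = 0
    for combo in itertools.combinations(range(6), 2):
        stat = sum(1 for i in combo if ids[i] in in_cluster)
        total += 1
        tail += stat >= observed
    exact_p = tail / total
    res = enrichment_permutation_test(loci, n_perm=4999, seed=7, mode="label_shuffle")
    assert res.p_value == pytest.approx(exact_p, abs=0.02)


def test_reposition_detects_planted_enrichment():
    """Conserved miRNAs planted mostly inside clusters give small p in
    nearly all generator seeds."""
    from mirevo.simulate import PlantConfig, generate_genome, plant_mirnas

    # background locus density is kept far below 1 per MID, as in a real
    # genome, so chance clustering stays rare under repositioning
    rejections = 0
    n_runs = 8
    for seed in range(n_runs):
        genome, ann = generate_genome(n_chrom=3, chrom_length=2_000_000, seed=seed)
        cfg = PlantConfig(n_conserved=14, conserved_clustered_fraction=0.9)
        loci, _, _ = plant_mirnas(genome, cfg, seed=seed)
        res = enrichment_permutation_test(
            loci, n_perm=199, seed=seed, mode="reposition",
            chrom_lengths=ann.chrom_lengths)
        rejections += res.p_value <= 0.05
    assert rejections >= n_runs - 1


def test_null_pvalues_superuniform():
    """Add-one permutation p-values under a null generator are (super-)
    uniform: their ECDF never exceeds the diagonal beyond DKW + grid
    slack."""
    rng = np.random.default_rng(9)
    pvals = []
    for _ in range(400):
        loci = random_loci(rng, 30, n_chrom=2, chrom_len=150_000)
        labels = rng.permutation([True] * 6 + [False] * 24)
        loci = [
            l.with_conservation("common" if lab else "specific")
            for l, lab in zip(loci, labels)
        ]
        res = enrichment_permutation_test(
            loci, n_perm=99, seed=int(rng.integers(2**31)), mode="label_shuffle")
        pvals.append(res.p_value)
    pvals = np.sort(pvals)
    grid = np.arange(1, len(pvals) + 1) / len(pvals)
    dkw = np.sqrt(np.log(2 / 0.001) / (2 * len(pvals)))
    assert np.max(grid - pvals) <= dkw + 1 / 100  # ECDF(p) <= p + slack
    assert np.mean(pvals) > 0.4


def test_reposition_requires_fitting_chromosome():
    loci = [MirnaLocus("a", "chr1", 0, 80), MirnaLocus("b", "chr1", 10, 90)]
    with pytest.raises(ValidationError):
        enrichment_permutation_test(
            loci, n_perm=9, seed=0, mode="reposition", chrom_lengths={"chr1": 50})
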