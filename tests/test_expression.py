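import numpy as np
import pandas as pd
import pytest

from mirevo.clusters import detect_clusters
from mirevo.expression import (
    assign_coexpression_modules,
    cluster_module_concordance,
    expressed_calls,
    neighbor_correlation,
    tissue_mean,
    tissue_specificity,
    tissue_specificity_score,
    tpm_normalize,
)
from mirevo.io import ExpressionMatrix, MirnaLocus


def em_from(counts, libs, tissues_of):
    return ExpressionMatrix(
        counts=pd.DataFrame(counts, columns=libs,
                            index=[f"m{i}" for i in range(len(counts))]),
        library_tissue=tissues_of,
    )


def test_tpm_direct_formula():
    em = em_from([[3], [1]], ["L1"], {"L1": "brain"})
    tpm = tpm_normalize(em)
    assert tpm["L1"].tolist() == [750_000.0, 250_000.0]


def test_tpm_single_mirna_library():
    em = em_from([[7]], ["L1"], {"L1": "brain"})
    assert tpm_normalize(em)["L1"].iloc[0] == 1e6


def test_tpm_columns_sum_to_million():
    rng = np.random.default_rng(0)
    counts = rng.integers(0, 500, size=(5, 3))
    counts[0] += 1  # no all-zero library
    em = em_from(counts, ["a", "b", "c"], {k: "t" for k in "abc"})
    tpm = tpm_normalize(em)
    assert np.allclose(tpm.sum(axis=0), 1e6, rtol=1e-6)


def test_tpm_zero_library_errors():
    em = em_from([[0, 1]], ["L1", "L2"], {"L1": "x", "L2": "x"})
    with pytest.raises(ValueError, match="L1"):
        tpm_normalize(em)


def test_expressed_calls_strict_threshold():
    libs = ["b1", "b2", "b3", "m1", "m2", "m3"]
    tmap = {l: ("brain" if l.startswith("b") else "muscle") for l in libs}
    em = em_from(
        [
            [0, 0, 0, 0, 0, 0],     # nowhere
            [3, 3, 3, 0, 0, 0],     # mean exactly 3: NOT expressed (strict >)
            [4, 4, 4, 0, 1, 0],     # brain only -> tissue-specific
            [10, 10, 10, 9, 9, 9],  # both tissues
        ],
        libs, tmap)
    calls = expressed_calls(em, threshold=3)
    assert not calls.expressed.loc["m0"].any()
    assert not calls.expressed.loc["m1", "brain"]
    assert calls.tissue_specific == {"m2": "brain"}
    assert calls.total_specific == 1
    assert calls.per_tissue_specific == {"brain": 1, "muscle": 0}


def test_expressed_calls_monotone_in_threshold():
    rng = np.random.default_rng(1)
    libs = [f"t{t}_{r}" for t in range(3) for r in range(3)]
    tmap = {l: l.split("_")[0] for l in libs}
    em = em_from(rng.integers(0, 30, size=(20, 9)), libs, tmap)
    prev = expressed_calls(em, threshold=0).expressed
    for thr in (3, 10, 25):
        now = expressed_calls(em, threshold=thr).expressed
        assert ((~prev) & now).sum().sum() == 0  # raising never adds a call
        prev = now


def test_specificity_formula_limits_and_example():
    assert tissue_specificity_score([5, 0, 0, 0, 0, 0]) == 1.0
    assert tissue_specificity_score([2, 2, 2, 2, 2, 2]) == 0.0
    assert tissue_specificity_score([10, 5, 0]) == pytest.approx(0.75)


def test_specificity_scale_invariance_and_range():
    rng = np.random.default_rng(2)
    for _ in range(50):
        a = rng.random(6) * 100
        t = tissue_specificity_score(a)
        assert 0 <= t <= 1
        assert tissue_specificity_score(a * 17.3) == pytest.approx(t)


def test_specificity_matrix_excludes_all_zero():
    df = pd.DataFrame({"t1": [5.0, 0.0], "t2": [0.0, 0.0]},
                      index=["expressed", "silent"])
    scores = tissue_specificity(df)
    assert list(scores.index) == ["expressed"]
    assert scores["expressed"] == 1.0


def test_specificity_needs_two_tissues():
    with pytest.raises(ValueError):
        tissue_specificity(pd.DataFrame({"only": [1.0]}))


def test_tissue_mean_averages_replicates():
    libs = ["b1", "b2", "m1", "m2"]
    tmap = {"b1": "brain", "b2": "brain", "m1": "muscle", "m2": "muscle"}
    em = em_from([[2, 4, 10, 20]], libs, tmap)
    means = tissue_mean(em.counts, em)
    assert means.loc["m0", "brain"] == 3 and means.loc["m0", "muscle"] == 15


def test_neighbor_correlation_trivial_values():
    loci = [
        MirnaLocus("m0", "chr1", 0, 80),
        MirnaLocus("m1", "chr1", 1000, 1080),
        MirnaLocus("m2", "chr1", 3000, 3080),
    ]
    libs = ["a", "b", "c"]
    tmap = {k: "t" for k in libs}
    em = em_from([[1, 2, 3], [1, 2, 3], [3, 2, 1]], libs, tmap)
    clusters = detect_clusters(loci)
    pairs = neighbor_correlation(loci, clusters, None, em, transform="none")
    by_key = {(p.id_a, p.id_b): p for p in pairs}
    assert by_key[("m0", "m1")].r == pytest.approx(1.0)
    assert by_key[("m1", "m2")].r == pytest.approx(-1.0)
    assert all(p.relationship == "same_cluster" for p in pairs)


def test_constant_profile_pair_excluded():
    # an all-zero miRNA keeps a constant (zero) TPM profile: r undefined
    loci = [MirnaLocus("m0", "chr1", 0, 80), MirnaLocus("m1", "chr1", 500, 580)]
    em = em_from([[0, 0, 0], [1, 2, 3]], ["a", "b", "c"], {k: "t" for k in "abc"})
    pairs = neighbor_correlation(loci, detect_clusters(loci), None, em,
                                 transform="none")
    assert pairs == []


def test_cluster_pairs_more_correlated_than_background():
    """Pairs sharing a planted latent factor correlate more strongly than
    independent pairs."""
    from mirevo.simulate import (ExpressionSimConfig, PlantConfig,
                                 generate_genome, plant_mirnas,
                                 simulate_expression)

    genome, _ = generate_genome(n_chrom=3, chrom_length=2_000_000, seed=3)
    cfg = PlantConfig(n_total=120, n_clusters=25, n_clustered=60,
                      n_cis=0, n_trans=0, n_conserved=0)
    loci, _, truth = plant_mirnas(genome, cfg, seed=3)
    em, _ = simulate_expression(
        loci, truth.clusters,
        ExpressionSimConfig(cluster_loading=0.9, n_tissue_specific=0), seed=3)
    clusters = detect_clusters(loci)
    pairs = neighbor_correlation(loci, clusters, None, em)
    same = [p.r for p in pairs if p.relationship == "same_cluster"]
    other = [p.r for p in pairs if p.relationship == "unrelated"]
    assert len(same) >= 30
    assert np.mean(same) > np.mean(other) + 0.2


def test_modules_two_perfect_blocks():
    rng = np.random.default_rng(4)
    base1, base2 = rng.random(10), rng.random(10)
    mat = pd.DataFrame(
        [base1 * s for s in (1, 2, 3)] + [base2 * s for s in (1, 2, 3)],
        index=[f"m{i}" for i in range(6)])
    modules = assign_coexpression_modules(mat, cut_height=0.25, min_size=3)
    assert modules["m0"] == modules["m1"] == modules["m2"]
    assert modules["m3"] == modules["m4"] == modules["m5"]
    assert modules["m0"] != modules["m3"]


def test_modules_min_size_unassigned():
    rng = np.random.default_rng(5)
    mat = pd.DataFrame(rng.random((20, 8)), index=[f"m{i}" for i in range(20)])
    modules = assign_coexpression_modules(mat, cut_height=0.25, min_size=30)
    assert all(v is None for v in modules.values())
    frac, _, eligible = cluster_module_concordance([], modules)
    assert frac is None and eligible == 0


def test_modules_cut_height_validated():
    mat = pd.DataFrame(np.random.default_rng(6).random((4, 5)))
    with pytest.raises(ValueError):
        assign_coexpression_modules(mat, cut_height=1.5)


def test_cluster_module_concordance_round_trip():
    """Clusters simulated with a strong shared factor land in one module
    each: concordance >= 0.8 at the default cut."""
    from mirevo.simulate import (ExpressionSimConfig, PlantConfig,
                                 generate_genome, plant_mirnas,
                                 simulate_expression)

    genome, _ = generate_genome(n_chrom=3, chrom_length=2_000_000, seed=7)
    cfg = PlantConfig(n_total=80, n_clusters=12, n_clustered=40,
                      n_cis=0, n_trans=0, n_conserved=0)
    loci, _, truth = plant_mirnas(genome, cfg, seed=7)
    em, _ = simulate_expression(
        loci, truth.clusters,
        ExpressionSimConfig(cluster_loading=0.9, n_tissue_specific=0,
                            dispersion=0.15, tissue_sigma=0.2),
        seed=7)
    tpm = tpm_normalize(em)
    modules = assign_coexpression_modules(np.log2(tpm + 1))
    clusters = detect_clusters(loci)
    frac, n_conc, n_elig = cluster_module_concordance(clusters, modules)
    assert n_elig >= 8
    assert frac >= 0.8


def test_planted_tissue_specific_recovered_exactly():
    from mirevo.simulate import (ExpressionSimConfig, PlantConfig,
                                 generate_genome, plant_mirnas,
                                 simulate_expression)

    genome, _ = generate_genome(n_chrom=2, chrom_length=1_000_000, seed=8)
    loci, _, truth = plant_mirnas(
        genome, PlantConfig(n_total=60, n_clusters=8, n_clustered=20,
                            n_cis=4, n_trans=2, n_conserved=5), seed=8)
    em, etruth = simulate_expression(
        loci, truth.clusters,
        ExpressionSimConfig(n_tissue_specific=25), seed=8)
    calls = expressed_calls(em)
    assert calls.tissue_specific == etruth.tissue_specific
    assert calls.total_specific == 25


def test_null_loading_no_excess_correlation():
    """With loading 0 the within-cluster and between-cluster mean
    correlations agree to sampling error."""
    from mirevo.simulate import (ExpressionSimConfig, PlantConfig,
                                 generate_genome, plant_mirnas,
                                 simulate_expression)

    genome, _ = generate_genome(n_chrom=3, chrom_length=3_000_000, seed=9)
    cfg = PlantConfig(n_total=150, n_clusters=30, n_clustered=75,
                      n_cis=0, n_trans=0, n_conserved=0)
    loci, _, truth = plant_mirnas(genome, cfg, seed=9)
    em, _ = simulate_expression(
        loci, truth.clusters,
        ExpressionSimConfig(cluster_loading=0.0, n_tissue_specific=0), seed=9)
    pairs = neighbor_correlation(loci, detect_clusters(loci), None, em)
    same = [p.r for p in pairs if p.relationship == "same_cluster"]
    other = [p.r for p in pairs if p.relationship == "unrelated"]
    assert len(same) >= 40 and len(other) >= 40
    se = np.sqrt(np.var(same) / len(same) + np.var(other) / len(other))
    assert abs(np.mean(same) - np.mean(other)) <= 4 * se
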