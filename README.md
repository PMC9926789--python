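# mirevo

Clustering pattern and evolutionary dynamics of a miRNA repertoire, built
around the genome-wide survey of grass carp (*Ctenopharyngodon idella*)
miRNAs and exercised end to end on a bundled synthetic-data generator with
recorded ground truth.

MicroRNA genes are not scattered independently across animal genomes: a
sizeable fraction sit in **clusters** (neighbouring loci within a maximum
inter-miRNA distance, MID = 10 kb), are often co-transcribed, and show
coordinated expression. This package implements the analyses needed to
characterize that organisation and its evolutionary consequences for a
teleost-scale miRNA set:

- **Genomic context** — assign each locus a single class
  (repeat > exon > intron > intergenic, ≥ 1 bp overlap priority rule) and
  tally the context composition.
- **Cluster detection** — single-linkage chaining of loci within the MID
  on each chromosome; conservation-class enrichment in clusters by a
  permutation test (repositioning loci uniformly on their chromosomes, or
  shuffling labels; add-one empirical p).
- **Families and conservation** — gapless best-block similarity of mature
  sequences over all offsets (aligned block ≥ 15 nt covering seed
  positions 2–8, ≤ 2 mismatches); single-linkage families; a miRNA is
  *common* when similar to a reference species' mature set, else
  *specific*.
- **Origin of clustered miRNAs** — per cluster, in genomic order: the
  5′-most member is excluded; common members are *inherited*; a
  qualifying match to another focal miRNA on the same chromosome is a
  *cis-duplication*, on a different chromosome a *trans-duplication*;
  otherwise *de novo*.
- **Evolution rate** — for orthologous precursor pairs,
  K = K<sub>p</sub>/K<sub>f</sub>: precursor divergence normalized by the
  divergence of equal-length flanking sequence (p-distance, JC69 or K2P);
  group comparisons by one-way ANOVA with Fisher's LSD post-hoc.
- **Family birth/death** — Dollo (single-origin) or unweighted Wagner
  parsimony of family presence/absence on a dated tree; per-branch gains,
  losses and gain rates in families per million years.
- **Expression** — TPM normalization; expressed calls (mean raw count
  strictly > 3 per tissue); tissue-specificity score
  T_i = 1/(n−1) · Σ_j (1 − a_ij/max_j a_ij); neighbour/duplicate-pair
  expression correlation on log2(TPM+1); a light-weight co-expression
  module detector for cluster/module concordance.
- **Synthetic data** — generators for every input with planted clusters,
  origins, conservation, substitution rates, gain/loss histories and
  expression structure, each deterministic per seed and shipping its
  ground truth; the test suite uses them as round-trip oracles.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (about a minute in total):

```bash
python analysis/01_simulate_data.py
python analysis/02_context_and_clusters.py
python analysis/03_origins.py
python analysis/04_evolution_rates.py
python analysis/05_family_birth_death.py
python analysis/06_expression.py
python analysis/07_survey_consistency.py
```

`02_context_and_clusters.py` prints, for the default 100-locus genome:

```
context counts: {'repeat': 9, 'exon': 7, 'intron': 12, 'intergenic': 72} (intergenic/intron ratio 6.0)
15 clusters covering 40 of 100 miRNAs (40.0%); planted: 15 clusters
clustered fraction per conservation class: {'specific': 35.23, 'common': 75.0}
common-in-cluster enrichment: observed 9, permutation p = 0.004 (999 repositionings)
```

— cluster detection recovers exactly the 15 planted clusters, and the
conserved miRNAs planted preferentially inside clusters are flagged as
significantly enriched. `03_origins.py` reports perfect recovery of the
planted origin partition (`agreement with planted truth: 40/40`);
`04_evolution_rates.py` prints `median K 0.2143` against the planted
q_p/q_f = 0.05/0.20 regime, and a strongly significant LSD contrast
between the slow ("common") and fast ("specific") planted rate groups;
`05_family_birth_death.py` recovers the true gain branch for 190/200
simulated families under Dollo parsimony.

Each stage is also exposed as a library call and as a CLI subcommand
(`mirevo all --config cfg.yaml --outdir out`, plus `context`, `cluster`,
`origin`, `expression`).

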