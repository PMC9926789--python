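# Methods

This note documents the models and procedures implemented in `mirevo`,
the parameter choices that matter, what the synthetic-data generators do
and do not emulate, and the numerical conventions. Everything quantitative
stated here is computed by the test suite or the analysis scripts.

## Coordinates, sequences and formats

All intervals are 0-based half-open internally. GFF3 (1-based inclusive)
converts on read/write; BED is taken as-is; the conversion is a bijection
and is round-trip tested. Sequences are stored uppercase with U→T so
RNA- and DNA-sourced files compare directly. Unknown conservation is
`unknown`, never silently `specific` — the common/specific split drives
most downstream statistics, so an unlabelled locus must not leak into
either class.

## Genomic context

A locus takes the highest-priority feature class overlapping its
precursor interval by ≥ 1 bp: repeat > exon > intron, else intergenic.
The priority order is configurable; the default mirrors the convention of
reporting repeat-derived miRNAs as such even inside genes, and produces
mutually exclusive, exhaustive classes (the counts always partition the
locus set; equivalence with a brute-force interval scan is tested).
Strand is ignored — context is a positional, not transcriptional, label.

## Cluster detection

Clusters are maximal same-chromosome chains of loci in which each locus
lies within MID (default 10 kb) of the chain so far; the gap is
end-to-start, floored at 0 for overlapping loci, and the chain end is the
running maximum of member ends, which makes the procedure exactly the
connected components of the all-pairs gap graph (tested against that
oracle). Clusters need ≥ 2 members. Clustering is strand-agnostic by
default; a same-strand flag exists in the similarity layer for users who
want transcript-unit clusters.

Enrichment of a conservation class in clusters is tested by permutation.
Default mode repositions every locus uniformly on its own chromosome
(length preserved, overlaps permitted) and re-runs detection — the
literal reading of permuting chromosomal sites; a label-shuffle mode
keeps the locus map fixed and permutes labels, which isolates the
label–cluster association from locus density. p = (1 + #{null ≥ obs}) /
(n_perm + 1), so p is never 0 and is super-uniform under the null
(calibration is tested against the DKW band). n_perm defaults to 999;
the seed is a required, recorded parameter.

The reposition null is only meaningful when background locus density is
well below 1/MID: at ~1 locus per 10–30 kb, uniform repositioning itself
produces mostly-clustered arrangements and the test loses its meaning.
Real teleost repertoires sit at ~1 locus per several hundred kb, so the
synthetic genomes used for reposition-mode analyses are generated at
~1 locus per 60 kb or sparser.

## Sequence similarity, families, conservation

Mature miRNAs are 18–30 nt, so similarity is decided by exact search: the
best gapless aligned block over all relative offsets of the two sense
strands. A pair passes when some block has length ≥ 15 nt, ≤ 2
mismatches, and covers seed positions 2–8 of the query; the reported
block maximizes length, then minimizes mismatches. This replaces a
heuristic aligner (BLAST-style) with an exact, dependency-free
equivalent; an independent brute-force enumeration over offsets × blocks
is kept in the tests as the oracle. Seed coverage is evaluated on the
query by default (the published rule names one seed region without
specifying whose); a strict mode requires both, and that mode is
symmetric. Reverse-complement matching is off by default — mature
sequences are directional.

Families are the single-linkage transitive closure of the symmetrized
pass relation, with the lexicographically smallest member id as family
id (order-invariant, tested). Conservation labelling reuses the same
criteria against reference species' mature sets: common iff any
reference mature passes. The published survey does not state its
operational conservation rule; homology to other species' annotated
matures is the natural stand-in and is documented as such.

## Origin classification of clustered miRNAs

Per cluster, in genomic order: the 5′-most member is excluded (alone it
could not seed a cluster and its own origin is not datable from within);
common members are inherited and not searched further; otherwise the
mature is compared against every other focal mature. Best partner =
maximal aligned length, then fewest mismatches, then smallest genomic
distance on the same chromosome, then smallest id — a deterministic
tie-break the published procedure leaves open. Same-chromosome best
partner ⇒ cis-duplication; different chromosome ⇒ trans-duplication;
equal-quality partners on both ⇒ undetermined (explicit, never forced);
no qualifying partner ⇒ de novo. A stricter cis definition (partner must
be in the same cluster) is available by flag. Labels always partition
the clustered set and are deterministic.

## Evolution rate K = Kp/Kf

Flanks of precursor length are extracted on both sides, strand-aware
(minus-strand flanks are reverse-complemented and up/down swapped).
Kp is the precursor-pair divergence; Kf averages the upstream and
downstream flank divergences (side-specific values are also reported —
the published analysis does not say which side it used, and averaging
halves the variance of the denominator). K = Kp/Kf is undefined when
Kf = 0 or any distance saturates; undefined pairs are excluded from
group statistics with the count logged.

Distances: p-distance, JC69 (−¾·ln(1 − 4p/3), undefined at p ≥ ¾) or K2P
(from transition/transversion proportions); K2P is the default. A
codon-based Ka/Ks machinery is deliberately not used: precursors and
flanks are non-coding, and K is a ratio, so any consistent nucleotide
model serves. Equal-length inputs are treated as aligned; unequal
lengths are globally aligned (match +1, mismatch −1, gap −2) and gap
columns dropped. Estimator behaviour: on simulated pairs with per-site
substitution probabilities (q_p, q_f) and 80-nt precursors, the median
K over hundreds of pairs tracks the model-corrected ratio to within a
few percent; the residual deviation is the discreteness/skew of a ratio
of short-sequence estimates, not bias in the formulas.

Group comparison is one-way ANOVA plus Fisher's LSD (pairwise t tests on
the pooled MSE with the ANOVA's residual df, two-sided), matching the
published figure legends' analysis.

## Family birth/death on a dated tree

Presence/absence of each family across species is reconstructed by
parsimony. Default is Dollo: one gain, on the branch above the MRCA of
the carrying species; losses on the minimal branch set explaining
absences below it (each family's hairpin arising twice is the
implausible event Dollo excludes). Wagner mode is unweighted
minimum-change (Sankoff DP, gain = loss = 1) with root-state ties
resolved to absence, favouring later gains; both modes are verified
against exhaustive enumeration of internal-state assignments on small
trees. Branch lengths are taken as given in MY (no re-dating); gain rate
is gains/length, omitted for zero-length branches; terminal and interior
mean net gain rates are reported separately.

## Expression

TPM: per-library counts scaled to 10⁶ (all-zero libraries are an error).
Expressed call: mean raw count over a tissue's replicate libraries
strictly greater than 3 — the mean is the least surprising aggregate of
three replicates for a per-tissue read-count rule, and sum/max are
selectable; the strict inequality means a count of exactly 3 is *not*
expressed. Tissue-specific = expressed in exactly one tissue.

Tissue specificity uses a_ij = mean TPM over tissue j's libraries:
T_i = 1/(n−1)·Σ_j (1 − a_ij/max_j a_ij); exactly 1 for single-tissue,
0 for uniform expression, invariant to scaling a miRNA's profile;
all-zero miRNAs are excluded and logged.

Neighbour correlation is Pearson r on log2(TPM+1) per-library profiles
(Spearman selectable) for genomically adjacent same-chromosome pairs
(classed same_cluster/unrelated) and for cis/trans duplicate pairs from
the origin labels; constant profiles are excluded. Summaries are grouped
by relationship and a <10 kb / ≥10 kb distance bin, reusing the
ANOVA/LSD machinery.

Co-expression modules are a deliberately small detector: average-linkage
hierarchical clustering on 1 − |r|, a static cut at height 0.25, modules
smaller than 3 unassigned. It is not a reimplementation of weighted
network analysis (no soft thresholding, no topological overlap); only
the cluster/module concordance statistic — the fraction of clusters
whose members all land in one module, over clusters with every member
assigned — depends on it, and that statistic, not the module algorithm,
is the claim being exercised.

## Synthetic data: what it emulates, and what passing tests show

Each generator draws from one named substream of a single integer seed,
so datasets are reproducible independently of call order, and each
returns a truth object recording every planted property.

- Genomes are i.i.d. uniform ACGT with non-overlapping fixed-length
  feature blocks placed to hit requested densities. No isochores, repeat
  families or composition bias.
- Planted repertoires (defaults: 100 loci, 15 clusters covering 40 loci,
  geometric within-cluster gaps of mean 2 kb clipped at the MID, groups
  isolated by >12 kb, 10 cis + 5 trans duplicates at per-site mutation
  rate 0.01, 12 conserved miRNAs placed 75% in clusters) give a
  desk-scale repertoire with the qualitative structure of the surveyed
  genome: a minority of loci clustered, duplications split ~2:1
  cis:trans, conserved miRNAs concentrated in clusters. Cis copies
  derive from their cluster founder, trans copies from a distinct single
  locus on another chromosome, and duplication sources are excluded from
  the conserved set so the planted origin of every copy is unambiguous.
- Ortholog pairs substitute each site independently with probability q_p
  (precursor) or q_f (flanks): no rate heterogeneity, indels or
  selection.
- Family histories are single-origin (branch chosen ∝ length) with
  Poisson per-branch losses; families extinct everywhere are resampled.
- Count matrices are log-normal-mixed integer draws: baseline + clipped
  tissue effect + per-cluster latent factor × loading + noise on the
  log2 scale; planted tissue-specific miRNAs get counts > 3 in every
  library of one tissue and ≤ 3 elsewhere. Overdispersion is generic
  (no library-size or GC effects); only the correlation and threshold
  structure the analyses consume is modelled.

Passing round-trip tests therefore show that each analysis recovers
structure *of the kind it assumes*, at benign parameters — exact cluster
recovery at gaps ≪ MID, ≥95% origin agreement at mutation rate ≤ 0.02,
median K within 10% of the planted ratio at n = 500 pairs, ≥90% gain-
branch recovery at low loss, exact tissue-specific recall — not that the
method is robust to the biological complications listed above.

A second, survey-scale construction (`mirevo.survey`) reproduces the
*composition margins* of the published grass carp survey (1,513 loci,
171 clusters of 397 members, the context, conservation, collinearity,
origin and tissue-specific margins) with synthetic coordinates, so the
summary arithmetic — percentages, ratios, totals — can be checked
against the published values by running the real pipeline rather than by
re-typing the numbers. Headline counts that require the original
sequencing data (e.g. the miRNA total itself) are inputs here, not
outputs.

## Problem sizes and numerical conventions

Analysis scripts and tests run at desk scale: 100–150-locus repertoires
on 3 × 2-Mb chromosomes, 400–500 ortholog pairs, 200 families on 8–12
leaf trees, 6 tissues × 3 libraries; the enumeration oracles cover trees
of 4–6 leaves and 10³ random instances for similarity and clustering.
Percentages are rounded to 2 decimals (overall clustered fraction to 1,
matching the precision they are compared at); ratios to 2 decimals; a
zero denominator yields an undefined (None) value, never infinity.
Permutation p-values use the add-one convention. All RNG is
`numpy.random.default_rng` seeded explicitly; derived streams use fixed
per-generator substream ids.

## Known limitations

- The conservation rule is a documented stand-in; with miRBase-style
  annotations the common/specific split may differ.
- Origin classification inherits the published procedure's blind spots:
  ancient duplicates diverged past the similarity criteria are called de
  novo, and the first cluster member is never classified.
- Dollo parsimony undercounts gains when losses are frequent; the Wagner
  mode trades that for possible multiple origins. Neither models rate
  variation across lineages.
- The module detector is intentionally minimal; its absolute module
  counts are not comparable to weighted-network pipelines, only the
  concordance statistic is.
- The published "1.34 genes per family" and "493 (32.20%)" figures are
  internally inconsistent with their own totals (1,442/244 ≈ 5.9;
  493/1,513 = 32.6%); the pipeline reports raw values and does not
  attempt to reproduce either figure.
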