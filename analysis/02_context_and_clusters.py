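#!/usr/bin/env python
"""Genomic context of each miRNA locus, cluster detection at MID = 10 kb,
and the conservation-enrichment permutation test.

Reads results/data/ (run 01_simulate_data.py first); writes
results/context_summary.tsv, results/clusters.tsv and
results/enrichment.tsv, and prints the headline fractions.
"""

import json
from pathlib import Path

import pandas as pd

from mirevo import io as mio
from mirevo.clusters import (
    cluster_summary,
    detect_clusters,
    enrichment_permutation_test,
)
from mirevo.context import classify_loci, summarize_context_labels
from mirevo.families import apply_conservation, label_conservation

SEED = 1
ROOT = Path(__file__).resolve().parent.parent / "results"
DATA = ROOT / "data"


def main() -> None:
    loci = mio.load_loci(DATA / "loci.tsv")
    annotation = mio.load_annotation(DATA / "annotation.bed", format="bed")
    annotation.chrom_lengths = {
        name: len(seq) for name, seq in mio.load_fasta(DATA / "genome.fa").items()}
    refs = {p.stem.removeprefix("reference_"): mio.load_fasta(p)
            for p in sorted(DATA.glob("reference_*.fa"))}
    labels = label_conservation({l.id: l.mature_seq for l in loci}, refs)
    loci = apply_conservation(loci, labels)

    ctx = classify_loci(loci, annotation)
    csum = summarize_context_labels(ctx)
    pd.DataFrame(
        [{"class": k, "count": csum.counts[k], "percent": csum.percents[k]}
         for k in csum.counts]
    ).to_csv(ROOT / "context_summary.tsv", sep="\t", index=False)

    clusters = detect_clusters(loci, mid=10_000)
    pd.DataFrame(
        [{"cluster_id": c.cluster_id, "chrom": c.chrom, "start": c.span[0],
          "end": c.span[1], "members": ",".join(c.members)} for c in clusters]
    ).to_csv(ROOT / "clusters.tsv", sep="\t", index=False)
    summ = cluster_summary(clusters, loci, ctx)

    enr = enrichment_permutation_test(
        loci, mid=10_000, n_perm=999, seed=SEED, mode="reposition",
        chrom_lengths=annotation.chrom_lengths)
    pd.DataFrame([{"observed": enr.observed, "p_value": enr.p_value,
                   "n_perm": enr.n_perm, "mode": enr.mode, "seed": enr.seed}]
                 ).to_csv(ROOT / "enrichment.tsv", sep="\t", index=False)

    truth = json.loads((DATA / "truth_loci.json").read_text())
    print(f"context counts: {csum.counts} "
          f"(intergenic/intron ratio {csum.intergenic_intron_ratio})")
    print(f"{summ.n_clusters} clusters covering {summ.n_clustered} of "
          f"{summ.n_total} miRNAs ({summ.pct_clustered}%); "
          f"planted: {len(truth['clusters'])} clusters")
    print(f"clustered fraction per conservation class: {summ.per_class_pct}")
    print(f"common-in-cluster enrichment: observed {enr.observed}, "
          f"permutation p = {enr.p_value} ({enr.n_perm} repositionings)")


if __name__ == "__main__":
    main()
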