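#!/usr/bin/env python
"""Generate the synthetic study inputs used by the downstream analyses.

Writes, under results/data/:
  genome + annotation (FASTA/BED), planted miRNA loci (TSV) with reference
  mature sets (FASTA), ortholog precursor/flank pairs, a dated 12-leaf
  tree with an evolved family presence/absence matrix, a 6-tissue count
  matrix — and a truth JSON per dataset recording every planted property.
"""

import json
from pathlib import Path

import pandas as pd

from mirevo import io as mio
from mirevo.simulate import (
    ExpressionSimConfig,
    PlantConfig,
    generate_genome,
    plant_mirnas,
    random_dated_tree,
    simulate_expression,
    simulate_family_evolution,
    simulate_ortholog_pairs,
)

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    # sparse genome: locus spacing far above the 10-kb cluster threshold,
    # as in a real fish genome
    genome, annotation = generate_genome(
        n_chrom=3, chrom_length=2_000_000,
        annotation_density={"exon": 0.05, "intron": 0.15, "repeat": 0.05},
        seed=SEED)
    cfg = PlantConfig()
    loci, refs, truth = plant_mirnas(genome, cfg, seed=SEED)
    mio.write_fasta(genome, OUT / "genome.fa")
    mio.write_annotation_bed(annotation, OUT / "annotation.bed")
    mio.write_loci(loci, OUT / "loci.tsv")
    for sp, seqs in refs.items():
        mio.write_fasta(seqs, OUT / f"reference_{sp}.fa")
    truth.to_json(OUT / "truth_loci.json")

    pairs, ptruth = simulate_ortholog_pairs(n_pairs=500, q_p=0.05, q_f=0.2,
                                            seed=SEED)
    pd.DataFrame([vars(p) for p in pairs]).to_csv(
        OUT / "ortholog_pairs.tsv", sep="\t", index=False)
    ptruth.to_json(OUT / "truth_pairs.json")

    tree = random_dated_tree(n_leaves=12, depth_my=600.0, seed=SEED)
    tree.tree.write(path=str(OUT / "tree.nwk"), schema="newick")
    presence, ftruth = simulate_family_evolution(tree, n_families=200,
                                                 loss_rate=0.0005, seed=SEED)
    mio.write_presence_matrix(presence, OUT / "families.tsv")
    ftruth.to_json(OUT / "truth_families.json")

    em, etruth = simulate_expression(
        loci, truth.clusters, ExpressionSimConfig(n_tissue_specific=25),
        seed=SEED)
    mio.write_expression(em, OUT / "counts.tsv", OUT / "tissue_map.tsv")
    etruth.to_json(OUT / "truth_expression.json")

    print(f"wrote synthetic inputs for {len(loci)} loci "
          f"({len(truth.clusters)} planted clusters), 500 ortholog pairs, "
          f"200 families on a 12-leaf tree, and a "
          f"{em.counts.shape[0]}x{em.counts.shape[1]} count matrix -> {OUT}")
    with open(OUT / "config.json", "w") as fh:
        json.dump({"seed": SEED, "plant": vars(cfg)}, fh, indent=1, default=str)


if __name__ == "__main__":
    main()
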