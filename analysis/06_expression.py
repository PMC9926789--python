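#!/usr/bin/env python
"""Expression analyses: TPM, expressed/tissue-specific calls, tissue
specificity by conservation class, neighbour-pair correlation by distance
and duplication type, and cluster/co-expression-module concordance.

Writes results/tissue_specificity.tsv, results/neighbor_pairs.tsv and
results/pair_group_summary.tsv.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from mirevo import io as mio
from mirevo.clusters import detect_clusters
from mirevo.expression import (
    assign_coexpression_modules,
    cluster_module_concordance,
    expressed_calls,
    neighbor_correlation,
    pair_group_summary,
    tissue_mean,
    tissue_specificity,
    tpm_normalize,
)
from mirevo.families import apply_conservation, label_conservation
from mirevo.origins import classify_origin

ROOT = Path(__file__).resolve().parent.parent / "results"
DATA = ROOT / "data"


def main() -> None:
    loci = mio.load_loci(DATA / "loci.tsv")
    refs = {p.stem.removeprefix("reference_"): mio.load_fasta(p)
            for p in sorted(DATA.glob("reference_*.fa"))}
    labels = label_conservation({l.id: l.mature_seq for l in loci}, refs)
    loci = apply_conservation(loci, labels)
    em = mio.load_expression(DATA / "counts.tsv", DATA / "tissue_map.tsv")
    truth = json.loads((DATA / "truth_expression.json").read_text())

    tpm = tpm_normalize(em)
    calls = expressed_calls(em, threshold=3)
    print(f"tissue-specific miRNAs: {calls.total_specific} called, "
          f"{len(truth['tissue_specific'])} planted; per tissue "
          f"{calls.per_tissue_specific}")

    spec = tissue_specificity(tissue_mean(tpm, em))
    spec.rename_axis("id").to_csv(ROOT / "tissue_specificity.tsv", sep="\t")
    by_class = {
        cls: spec[[l.id for l in loci if l.conservation == cls and l.id in spec]]
        for cls in ("common", "specific")}
    print("median tissue specificity T: "
          + ", ".join(f"{k} {v.median():.3f} (n={len(v)})"
                      for k, v in by_class.items()))

    clusters = detect_clusters(loci, mid=10_000)
    origin_map = classify_origin(clusters, loci)
    pairs = neighbor_correlation(loci, clusters, origin_map, em)
    pd.DataFrame([vars(p) for p in pairs]).to_csv(
        ROOT / "neighbor_pairs.tsv", sep="\t", index=False)
    summary = pair_group_summary(pairs)
    summary.to_csv(ROOT / "pair_group_summary.tsv", sep="\t", index=False)
    print("mean expression correlation by pair group:")
    print(summary.to_string(index=False))

    modules = assign_coexpression_modules(np.log2(tpm + 1))
    frac, n_conc, n_elig = cluster_module_concordance(clusters, modules)
    print(f"cluster/module concordance: {n_conc}/{n_elig} eligible clusters "
          f"in a single module"
          + (f" ({frac:.2f})" if frac is not None else " (none eligible)"))


if __name__ == "__main__":
    main()
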