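"""End-to-end orchestration: run every analysis stage from one config.

The config is a plain dict (typically loaded from YAML).  Either a
``simulate`` section generates all inputs synthetically, or an ``inputs``
section names files on disk.  Each stage writes its TSV under ``outdir``
and the headline fractions are echoed into ``summary.json``.  Identical
config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import birthdeath, clusters, context, expression, families, origins, rates
from . import io as mio
from . import simulate as sim

logger = logging.getLogger(__name__)

DEFAULTS = {
    "seed": 0,
    "mid": 10_000,
    "n_perm": 199,
    "permutation_mode": "label_shuffle",
    "expressed_threshold": 3,
    "model": "K2P",
    "cut_height": 0.25,
    "min_module_size": 3,
    "parsimony_mode": "dollo",
}


class ConfigError(ValueError):
    pass


def _validate_inputs(cfg: dict) -> None:
    inputs = cfg.get("inputs", {})
    for key, path in inputs.items():
        if key.endswith("_format"):
            continue
        paths = path.values() if isinstance(path, dict) else [path]
        for p in paths:
            if not Path(p).exists():
                raise ConfigError(f"input {key!r}: file not found: {p}")


def run_all(config: dict, outdir: str | Path) -> dict:
    """Run every applicable stage; returns the summary dict."""
    cfg = {**DEFAULTS, **(config or {})}
    _validate_inputs(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    summary: dict = {"seed": seed}

    data = _gather_inputs(cfg, seed)
    loci = data["loci"]
    criteria = families.SimilarityCriteria(
        min_align_len=int(cfg.get("min_align_len", 15)),
        max_mismatch=int(cfg.get("max_mismatch", 2)),
    )

    # conservation + families from mature sequences, when present
    matures = {l.id: l.mature_seq for l in loci if l.mature_seq}
    if matures and data.get("reference_sets"):
        labels = families.label_conservation(matures, data["reference_sets"], criteria)
        loci = families.apply_conservation(loci, labels)
        table = families.assign_families(matures, criteria)
        pd.DataFrame(
            [(fid, m) for fid, ms in table.families.items() for m in ms],
            columns=["family_id", "member_id"],
        ).to_csv(outdir / "families.tsv", sep="\t", index=False)
        summary["n_families"] = table.n_families
        summary["n_common"] = sum(1 for v in labels.values() if v == "common")
    mio.write_loci(loci, outdir / "loci.tsv")

    # genomic context
    ctx_labels = None
    if data.get("annotation") is not None:
        ctx_labels = context.classify_loci(loci, data["annotation"])
        pd.Series(ctx_labels, name="context").rename_axis("id").to_csv(
            outdir / "context.tsv", sep="\t")
        csum = context.summarize_context_labels(ctx_labels)
        summary["context_counts"] = csum.counts
        summary["context_percents"] = csum.percents
        summary["intergenic_intron_ratio"] = csum.intergenic_intron_ratio

    # clusters
    detected = clusters.detect_clusters(loci, mid=int(cfg["mid"]))
    pd.DataFrame(
        [{"cluster_id": c.cluster_id, "chrom": c.chrom,
          "start": c.span[0], "end": c.span[1],
          "members": ",".join(c.members)} for c in detected]
    ).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    csum = clusters.cluster_summary(detected, loci, ctx_labels)
    summary["n_clusters"] = csum.n_clusters
    summary["n_clustered"] = csum.n_clustered
    summary["pct_clustered"] = csum.pct_clustered
    summary["per_class_pct_clustered"] = csum.per_class_pct

    if any(l.conservation == "common" for l in loci):
        chrom_lengths = (data["annotation"].chrom_lengths
                         if data.get("annotation") is not None else None)
        mode = cfg["permutation_mode"]
        if mode == "reposition" and not chrom_lengths:
            mode = "label_shuffle"
        enr = clusters.enrichment_permutation_test(
            loci, mid=int(cfg["mid"]), n_perm=int(cfg["n_perm"]), seed=seed,
            mode=mode, chrom_lengths=chrom_lengths)
        summary["enrichment"] = {
            "observed": enr.observed, "p_value": enr.p_value,
            "n_perm": enr.n_perm, "mode": enr.mode,
        }

    # origins
    origin_map = None
    if matures and detected:
        origin_map = origins.classify_origin(detected, loci, criteria)
        pd.DataFrame(
            [{"id": k, "label": v.value, "partner_id": v.partner_id,
              "aligned_len": v.aligned_len, "mismatches": v.mismatches}
             for k, v in sorted(origin_map.items())]
        ).to_csv(outdir / "origins.tsv", sep="\t", index=False)
        osum = origins.origin_summary(origin_map)
        summary["origin_counts"] = osum.counts
        summary["duplication_total"] = osum.duplication_total

    # evolution rates
    if data.get("ortholog_pairs"):
        results = rates.rates_for_pairs(data["ortholog_pairs"], model=cfg["model"])
        df = pd.DataFrame([vars(r) for r in results])
        df.to_csv(outdir / "rates.tsv", sep="\t", index=False)
        ok = df[df["status"] == "ok"]
        summary["rates"] = {"n": len(df), "n_ok": len(ok),
                            "median_K": float(ok["K"].median()) if len(ok) else None}

    # family birth/death
    if data.get("tree") is not None and data.get("presence") is not None:
        events = birthdeath.infer_events(data["tree"], data["presence"],
                                         mode=cfg["parsimony_mode"])
        birthdeath.write_events_tsv(events, outdir / "events.tsv")
        (outdir / "events_annotated.nwk").write_text(
            birthdeath.annotated_newick(data["tree"], events) + "\n")
        summary["birth_death"] = {
            "total_gains": events.total_gains,
            "total_losses": events.total_losses,
        }

    # expression
    if data.get("expression") is not None:
        em = data["expression"]
        tpm = expression.tpm_normalize(em)
        tpm.to_csv(outdir / "tpm.tsv", sep="\t")
        calls = expression.expressed_calls(em, threshold=float(cfg["expressed_threshold"]))
        calls.expressed.to_csv(outdir / "expressed_calls.tsv", sep="\t")
        spec = expression.tissue_specificity(
            expression.tissue_mean(tpm, em))
        spec.rename_axis("id").to_csv(outdir / "tissue_specificity.tsv", sep="\t")
        summary["expression"] = {
            "n_tissue_specific": calls.total_specific,
            "per_tissue_specific": calls.per_tissue_specific,
            "median_T": float(spec.median()),
        }
        pairs = expression.neighbor_correlation(loci, detected, origin_map, em)
        pd.DataFrame([vars(p) for p in pairs]).to_csv(
            outdir / "neighbor_pairs.tsv", sep="\t", index=False)
        mat = np.log2(tpm + 1)
        if mat.shape[0] >= 3:
            modules = expression.assign_coexpression_modules(
                mat, cut_height=float(cfg["cut_height"]),
                min_size=int(cfg["min_module_size"]))
            frac, n_conc, n_elig = expression.cluster_module_concordance(
                detected, modules)
            summary["cluster_module_concordance"] = {
                "fraction": frac, "concordant": n_conc, "eligible": n_elig}

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary


def _gather_inputs(cfg: dict, seed: int) -> dict:
    data: dict = {}
    if "simulate" in cfg:
        s = cfg["simulate"] or {}
        genome, annotation = sim.generate_genome(
            n_chrom=int(s.get("n_chrom", 3)),
            chrom_length=int(s.get("chrom_length", 400_000)),
            annotation_density=s.get("annotation_density",
                                     {"exon": 0.05, "intron": 0.15, "repeat": 0.05}),
            seed=seed,
        )
        plant = sim.PlantConfig(**(s.get("plant") or {}))
        loci, refs, truth = sim.plant_mirnas(genome, plant, seed=seed)
        data.update(loci=loci, annotation=annotation, reference_sets=refs,
                    genome=genome, truth=truth)
        pairs, _ = sim.simulate_ortholog_pairs(
            n_pairs=int(s.get("n_pairs", 200)), seed=seed)
        data["ortholog_pairs"] = pairs
        tree = sim.random_dated_tree(n_leaves=int(s.get("n_leaves", 8)), seed=seed)
        presence, _ = sim.simulate_family_evolution(
            tree, n_families=int(s.get("n_families", 100)), seed=seed)
        data.update(tree=tree, presence=presence)
        em, _ = sim.simulate_expression(loci, truth.clusters, seed=seed)
        data["expression"] = em
        return data

    inputs = cfg.get("inputs", {})
    if "loci" not in inputs:
        raise ConfigError("config needs either a 'simulate' section or inputs.loci")
    data["loci"] = mio.load_loci(inputs["loci"], format=inputs.get("loci_format", "tsv"))
    if "annotation" in inputs:
        data["annotation"] = mio.load_annotation(
            inputs["annotation"], format=inputs.get("annotation_format", "bed"))
    if "reference_fastas" in inputs:
        data["reference_sets"] = {
            sp: mio.load_fasta(p) for sp, p in inputs["reference_fastas"].items()}
    if "counts" in inputs and "tissue_map" in inputs:
        data["expression"] = mio.load_expression(inputs["counts"], inputs["tissue_map"])
    if "tree" in inputs and "presence" in inputs:
        data["tree"] = mio.load_tree(inputs["tree"])
        data["presence"] = mio.load_presence_matrix(inputs["presence"])
    return data
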