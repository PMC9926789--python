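"""Domain types and readers/writers for miRNA locus, annotation, expression,
tree and family-presence data.

All genomic coordinates are held internally as 0-based half-open intervals.
GFF3 input (1-based, inclusive) is converted on read and back on write; BED
input is taken as-is.  Sequences are normalized to uppercase DNA (U -> T) so
that mixed RNA/DNA sources compare directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

CONSERVATION_LABELS = ("common", "specific", "unknown")
ANNOTATION_FEATURES = ("exon", "intron", "repeat")

MATURE_MIN_LEN = 18
MATURE_MAX_LEN = 30


class ParseError(ValueError):
    """Malformed input file; message carries the offending line number."""


class ValidationError(ValueError):
    """Input parsed but violates a domain invariant."""


def normalize_seq(seq: str) -> str:
    """Uppercase and convert RNA (U) to DNA (T)."""
    return seq.strip().upper().replace("U", "T")


@dataclass(frozen=True)
class MirnaLocus:
    """One miRNA gene: precursor coordinates plus mature/precursor sequence.

    ``start``/``end`` are 0-based half-open on ``chrom``; ``strand`` is
    '+' or '-'.  ``conservation`` records whether the miRNA is conserved
    beyond the focal species ("common"), found only in it ("specific"),
    or not yet labelled ("unknown").
    """

    id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    mature_seq: str = ""
    precursor_seq: str = ""
    conservation: str = "unknown"

    def __post_init__(self):
        if self.start >= self.end:
            raise ValidationError(
                f"locus {self.id}: start ({self.start}) must be < end ({self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"locus {self.id}: bad strand {self.strand!r}")
        if self.conservation not in CONSERVATION_LABELS:
            raise ValidationError(
                f"locus {self.id}: bad conservation label {self.conservation!r}"
            )
        object.__setattr__(self, "mature_seq", normalize_seq(self.mature_seq))
        object.__setattr__(self, "precursor_seq", normalize_seq(self.precursor_seq))
        if self.mature_seq and not (
            MATURE_MIN_LEN <= len(self.mature_seq) <= MATURE_MAX_LEN
        ):
            raise ValidationError(
                f"locus {self.id}: mature sequence length {len(self.mature_seq)} "
                f"outside [{MATURE_MIN_LEN}, {MATURE_MAX_LEN}]"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def with_conservation(self, label: str) -> "MirnaLocus":
        return replace(self, conservation=label)


@dataclass
class AnnotationSet:
    """Genome feature intervals (exon / intron / repeat) plus chromosome sizes.

    Intervals are (chrom, start, end, feature) with 0-based half-open
    coordinates.  ``chrom_lengths`` may be empty, in which case bounds are
    not checked.
    """

    intervals: list[tuple[str, int, int, str]] = field(default_factory=list)
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        for chrom, start, end, feat in self.intervals:
            if feat not in ANNOTATION_FEATURES:
                raise ValidationError(f"unknown feature class {feat!r}")
            if start < 0 or start >= end:
                raise ValidationError(
                    f"bad interval ({chrom}, {start}, {end}, {feat})"
                )
            if self.chrom_lengths:
                if chrom not in self.chrom_lengths:
                    raise ValidationError(f"interval on unknown chromosome {chrom!r}")
                if end > self.chrom_lengths[chrom]:
                    raise ValidationError(
                        f"interval ({chrom}, {start}, {end}) exceeds chromosome "
                        f"length {self.chrom_lengths[chrom]}"
                    )

    def by_chrom(self) -> dict[str, list[tuple[int, int, str]]]:
        out: dict[str, list[tuple[int, int, str]]] = {}
        for chrom, start, end, feat in self.intervals:
            out.setdefault(chrom, []).append((start, end, feat))
        return out


@dataclass
class ExpressionMatrix:
    """Raw miRNA x library read counts with a library -> tissue map."""

    counts: pd.DataFrame  # index = miRNA ids, columns = library ids
    library_tissue: dict[str, str]
    tissues: list[str] = field(default_factory=list)

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValidationError("negative counts are not allowed")
        missing = [lib for lib in self.counts.columns if lib not in self.library_tissue]
        if missing:
            raise ValidationError(f"libraries without a tissue mapping: {missing}")
        if not self.tissues:
            seen: list[str] = []
            for lib in self.counts.columns:
                t = self.library_tissue[lib]
                if t not in seen:
                    seen.append(t)
            self.tissues = seen

    @property
    def n_tissues(self) -> int:
        return len(self.tissues)

    def libraries_of(self, tissue: str) -> list[str]:
        return [l for l in self.counts.columns if self.library_tissue[l] == tissue]


@dataclass
class PhyloTree:
    """Rooted dated tree; branch lengths in million years (MY)."""

    tree: dendropy.Tree

    def __post_init__(self):
        leaves = self.leaf_names()
        if len(leaves) != len(set(leaves)):
            raise ValidationError("duplicate leaf names in tree")
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValidationError("negative branch length in tree")

    def leaf_names(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]


@dataclass
class FamilyPresenceMatrix:
    """Binary family x species matrix; 1 = family present in the species."""

    matrix: pd.DataFrame  # index = family ids, columns = species

    def __post_init__(self):
        vals = set(pd.unique(self.matrix.values.ravel()))
        if not vals <= {0, 1}:
            raise ValidationError(f"presence matrix entries must be 0/1, got {vals}")

    @property
    def families(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def species(self) -> list[str]:
        return list(self.matrix.columns)


# ---------------------------------------------------------------------------
# loci

LOCUS_COLUMNS = [
    "id", "chrom", "start", "end", "strand",
    "mature_seq", "precursor_seq", "conservation",
]


def _check_unique_ids(loci: Sequence[MirnaLocus]) -> None:
    seen: set[str] = set()
    for loc in loci:
        if loc.id in seen:
            raise ValidationError(f"duplicate locus id {loc.id!r}")
        seen.add(loc.id)


def load_loci(
    path: str | Path,
    format: str = "tsv",
    column_map: Mapping[str, str] | None = None,
) -> list[MirnaLocus]:
    """Load miRNA loci from TSV (0-based half-open) or GFF3 (1-based inclusive).

    ``column_map`` renames TSV columns onto the canonical names in
    ``LOCUS_COLUMNS`` (e.g. ``{"Chromosome": "chrom"}``), accommodating
    supplementary-table layouts.
    """
    path = Path(path)
    if format == "tsv":
        loci = _load_loci_tsv(path, column_map)
    elif format == "gff3":
        loci = _load_loci_gff3(path)
    else:
        raise ValueError(f"unknown locus format {format!r}")
    _check_unique_ids(loci)
    return loci


def _load_loci_tsv(path: Path, column_map) -> list[MirnaLocus]:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#",
                         keep_default_na=False)
    except pd.errors.EmptyDataError:
        return []
    if column_map:
        df = df.rename(columns=dict(column_map))
    required = {"id", "chrom", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing required columns {sorted(missing)}")
    loci = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict()
        try:
            loci.append(
                MirnaLocus(
                    id=row["id"],
                    chrom=row["chrom"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    strand=row.get("strand") or "+",
                    mature_seq=row.get("mature_seq") or "",
                    precursor_seq=row.get("precursor_seq") or "",
                    conservation=row.get("conservation") or "unknown",
                )
            )
        except (TypeError, ValueError) as exc:
            if isinstance(exc, ValidationError):
                raise
            raise ParseError(f"{path}: line {i}: {exc}") from exc
    return loci


def _parse_gff3_attrs(attrs: str) -> dict[str, str]:
    out = {}
    for item in attrs.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def _load_loci_gff3(path: Path) -> list[MirnaLocus]:
    loci = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(f"{path}: line {lineno}: expected 9 GFF3 columns")
            chrom, _, _, start, end, _, strand, _, attrs = parts
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            a = _parse_gff3_attrs(attrs)
            locus_id = a.get("ID") or a.get("Name")
            if not locus_id:
                raise ParseError(f"{path}: line {lineno}: no ID attribute")
            loci.append(
                MirnaLocus(
                    id=locus_id,
                    chrom=chrom,
                    start=start_i - 1,  # GFF3 is 1-based inclusive
                    end=end_i,
                    strand=strand if strand in "+-" else "+",
                    mature_seq=a.get("mature_seq", ""),
                    precursor_seq=a.get("precursor_seq", ""),
                    conservation=a.get("conservation", "unknown"),
                )
            )
    return loci


def write_loci(loci: Iterable[MirnaLocus], path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    loci = list(loci)
    if format == "tsv":
        df = pd.DataFrame(
            [[getattr(l, c) for c in LOCUS_COLUMNS] for l in loci],
            columns=LOCUS_COLUMNS,
        )
        df.to_csv(path, sep="\t", index=False)
    elif format == "gff3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for l in loci:
                attrs = f"ID={l.id}"
                if l.mature_seq:
                    attrs += f";mature_seq={l.mature_seq}"
                if l.precursor_seq:
                    attrs += f";precursor_seq={l.precursor_seq}"
                attrs += f";conservation={l.conservation}"
                fh.write(
                    f"{l.chrom}\tmirevo\tmiRNA_primary_transcript\t{l.start + 1}\t"
                    f"{l.end}\t.\t{l.strand}\t.\t{attrs}\n"
                )
    else:
        raise ValueError(f"unknown locus format {format!r}")


# ---------------------------------------------------------------------------
# annotation


def load_annotation(
    path: str | Path,
    format: str = "bed",
    chrom_lengths: Mapping[str, int] | None = None,
    derive_introns: bool = False,
) -> AnnotationSet:
    """Load feature annotation from BED4 (0-based) or GFF3 (1-based).

    Features outside {exon, intron, repeat} are dropped with a warning.
    With ``derive_introns`` gene spans minus their exons become intron
    intervals (used when the annotation records genes and exons only).
    """
    path = Path(path)
    intervals: list[tuple[str, int, int, str]] = []
    genes: dict[str, list[tuple[str, int, int]]] = {}
    dropped: set[str] = set()

    def _add(chrom: str, start: int, end: int, feat: str) -> None:
        feat = feat.lower()
        if feat in ANNOTATION_FEATURES:
            intervals.append((chrom, start, end, feat))
        elif feat == "gene" and derive_introns:
            genes.setdefault(chrom, []).append((chrom, start, end))
        else:
            dropped.add(feat)

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                if format == "bed":
                    if len(parts) < 4:
                        raise ParseError(
                            f"{path}: line {lineno}: BED4 needs 4 columns"
                        )
                    _add(parts[0], int(parts[1]), int(parts[2]), parts[3])
                elif format == "gff3":
                    if len(parts) != 9:
                        raise ParseError(
                            f"{path}: line {lineno}: expected 9 GFF3 columns"
                        )
                    _add(parts[0], int(parts[3]) - 1, int(parts[4]), parts[2])
                else:
                    raise ValueError(f"unknown annotation format {format!r}")
            except ValueError as exc:
                if isinstance(exc, (ParseError, ValidationError)):
                    raise
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc

    if dropped:
        logger.warning("dropped features outside exon/intron/repeat: %s", sorted(dropped))
    if derive_introns:
        intervals.extend(_introns_from_genes(genes, intervals))
    return AnnotationSet(
        intervals=intervals,
        chrom_lengths=dict(chrom_lengths or {}),
    )


def _introns_from_genes(genes, intervals) -> list[tuple[str, int, int, str]]:
    """Gene span minus its exon spans, per chromosome (set difference)."""
    exons: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end, feat in intervals:
        if feat == "exon":
            exons.setdefault(chrom, []).append((start, end))
    introns = []
    for chrom, gene_list in genes.items():
        ex = sorted(exons.get(chrom, []))
        for _, gstart, gend in gene_list:
            pos = gstart
            for estart, eend in ex:
                if eend <= gstart or estart >= gend:
                    continue
                if estart > pos:
                    introns.append((chrom, pos, min(estart, gend), "intron"))
                pos = max(pos, eend)
            if pos < gend:
                introns.append((chrom, pos, gend, "intron"))
    return introns


def write_annotation_bed(annotation: AnnotationSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, feat in annotation.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{feat}\n")


# ---------------------------------------------------------------------------
# expression


def load_expression(
    path_counts: str | Path, path_tissue_map: str | Path
) -> ExpressionMatrix:
    """Load a raw count TSV (rows = miRNAs, columns = libraries) and a
    two-column library -> tissue TSV."""
    counts = pd.read_csv(path_counts, sep="\t", index_col=0)
    bad = counts.columns[
        ~counts.apply(lambda c: (c == c.astype(int)).all() & (c >= 0).all())
    ]
    if len(bad):
        raise ValidationError(f"non-integer or negative counts in libraries {list(bad)}")
    counts = counts.astype(int)
    tmap = pd.read_csv(path_tissue_map, sep="\t", header=None, names=["library", "tissue"])
    library_tissue = dict(zip(tmap["library"].astype(str), tmap["tissue"].astype(str)))
    unmapped = [c for c in counts.columns if c not in library_tissue]
    if unmapped:
        raise ValidationError(f"libraries missing from tissue map: {unmapped}")
    return ExpressionMatrix(counts=counts, library_tissue=library_tissue)


def write_expression(em: ExpressionMatrix, path_counts: str | Path,
                     path_tissue_map: str | Path) -> None:
    em.counts.to_csv(path_counts, sep="\t")
    with open(path_tissue_map, "w") as fh:
        for lib in em.counts.columns:
            fh.write(f"{lib}\t{em.library_tissue[lib]}\n")


# ---------------------------------------------------------------------------
# tree + presence matrix


def load_tree(path: str | Path) -> PhyloTree:
    tree = dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)
    return PhyloTree(tree=tree)


def load_presence_matrix(path: str | Path) -> FamilyPresenceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return FamilyPresenceMatrix(matrix=df.astype(int))


def write_presence_matrix(fpm: FamilyPresenceMatrix, path: str | Path) -> None:
    fpm.matrix.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# FASTA


def load_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into {id: normalized sequence}."""
    return {rec.id: normalize_seq(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")
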