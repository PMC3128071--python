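"""Readers and writers for the external formats the pipeline touches.

All coordinates are held internally as 1-based inclusive spans (the GFF3
convention). BED input (0-based, half-open) is converted on read. Every
tabular writer emits TSV with a header line starting ``#`` so that files
round-trip through the matching reader.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy

logger = logging.getLogger(__name__)

STRAND_PLUS = "+"
STRAND_MINUS = "-"
_STRAND_ALIASES = {
    "+": STRAND_PLUS,
    "plus": STRAND_PLUS,
    "1": STRAND_PLUS,
    "-": STRAND_MINUS,
    "minus": STRAND_MINUS,
    "-1": STRAND_MINUS,
}


class ValidationError(ValueError):
    """Raised when an input file violates a format or domain invariant."""


def _norm_strand(symbol: str, context: str = "") -> str:
    try:
        return _STRAND_ALIASES[str(symbol).strip()]
    except KeyError:
        raise ValidationError(
            f"unknown strand symbol {symbol!r}{' at ' + context if context else ''}"
        ) from None


@dataclass(frozen=True, order=True)
class GeneRecord:
    """One protein-coding gene's CDS span (ORF boundaries) on a chromosome."""

    species: str
    chromosome: str
    cds_start: int  # 1-based inclusive
    cds_end: int  # 1-based inclusive
    gene_id: str
    strand: str
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.cds_start < 1:
            raise ValidationError(
                f"gene {self.gene_id}: cds_start {self.cds_start} < 1"
            )
        if self.cds_end < self.cds_start:
            raise ValidationError(
                f"gene {self.gene_id}: cds_end {self.cds_end} < cds_start {self.cds_start}"
            )
        if self.strand not in (STRAND_PLUS, STRAND_MINUS):
            raise ValidationError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )


@dataclass(frozen=True)
class HomologyHit:
    """A pairwise sequence-similarity hit; only query, subject, bitscore kept."""

    query_id: str
    subject_id: str
    bitscore: float

    def __post_init__(self) -> None:
        if self.bitscore < 0:
            raise ValidationError(f"negative bitscore for ({self.query_id}, {self.subject_id})")


@dataclass(frozen=True)
class OrthologPair:
    species_a: str
    gene_a: str
    species_b: str
    gene_b: str
    confidence: float

    def __post_init__(self) -> None:
        if self.species_a == self.species_b:
            raise ValidationError(
                f"ortholog pair within one species: {self.species_a} "
                f"({self.gene_a}, {self.gene_b})"
            )
        if not 0.0 <= self.confidence <= 1.0:
            raise ValidationError(f"confidence {self.confidence} outside [0, 1]")


@dataclass(frozen=True)
class RepeatInterval:
    """A repeat-masked interval, stored 1-based inclusive after BED conversion."""

    species: str
    chromosome: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValidationError(
                f"repeat interval {self.chromosome}:{self.start}-{self.end} invalid"
            )


@dataclass
class SpeciesTree:
    """A rooted species tree with unique leaf labels (species codes)."""

    tree: dendropy.Tree

    @property
    def leaves(self) -> list[str]:
        return sorted(t.label for t in self.tree.taxon_namespace)

    def __contains__(self, species: str) -> bool:
        return species in set(self.leaves)


# ---------------------------------------------------------------------------
# annotation readers


def _sort_genes(genes: Iterable[GeneRecord]) -> list[GeneRecord]:
    return sorted(genes, key=lambda g: (g.chromosome, g.cds_start, g.cds_end, g.gene_id))


def read_annotation(path: str | os.PathLike, format: str = "tabular") -> list[GeneRecord]:
    """Read gene annotations from a GFF3 file or the simple tabular dialect.

    Multi-segment CDS features (one row per exon in GFF3) are collapsed to the
    union span min(start)..max(end) per gene id. The returned list is sorted by
    (chromosome, cds_start, cds_end, gene_id) and gene ids are checked for
    uniqueness within each species.
    """
    if format == "tabular":
        genes = _read_tabular_genes(path)
    elif format == "gff3":
        genes = _read_gff3_genes(path)
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    seen: set[tuple[str, str]] = set()
    for g in genes:
        key = (g.species, g.gene_id)
        if key in seen:
            raise ValidationError(f"duplicate gene id {g.gene_id} in species {g.species}")
        seen.add(key)
    return _sort_genes(genes)


TABULAR_GENE_COLUMNS = ("gene_id", "species", "chromosome", "strand", "cds_start", "cds_end")


def _read_tabular_genes(path: str | os.PathLike) -> list[GeneRecord]:
    genes: list[GeneRecord] = []
    with open(path) as fh:
        header: list[str] | None = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                header = line.lstrip("#").strip().split("\t")
                continue
            fields = line.split("\t")
            if header is None:
                header = list(TABULAR_GENE_COLUMNS)
            row = dict(zip(header, fields))
            missing = [c for c in TABULAR_GENE_COLUMNS if c not in row]
            if missing:
                raise ValidationError(f"{path} line {lineno}: missing columns {missing}")
            try:
                start, end = int(row["cds_start"]), int(row["cds_end"])
            except ValueError:
                raise ValidationError(
                    f"{path} line {lineno}: non-integer coordinates"
                ) from None
            try:
                genes.append(
                    GeneRecord(
                        gene_id=row["gene_id"],
                        species=row["species"],
                        chromosome=row["chromosome"],
                        strand=_norm_strand(row["strand"], f"line {lineno}"),
                        cds_start=start,
                        cds_end=end,
                        biotype=row.get("biotype", "protein_coding"),
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"{path} line {lineno}: {exc}") from None
    return genes


def _read_gff3_genes(path: str | os.PathLike) -> list[GeneRecord]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    species_default = os.path.splitext(os.path.basename(str(path)))[0]
    spans: dict[str, dict] = {}
    feature_types = set(db.featuretypes())
    use_cds = "CDS" in feature_types
    for feat in db.all_features(featuretype="CDS" if use_cds else "gene"):
        parent = feat.attributes.get("Parent", [None])[0] if use_cds else None
        gene_id = (
            feat.attributes.get("gene_id", [None])[0]
            or parent
            or feat.attributes.get("ID", [feat.id])[0]
        )
        if feat.end < feat.start:
            raise ValidationError(f"{path}: feature {gene_id} has end < start")
        strand = _norm_strand(feat.strand, f"feature {gene_id}")
        rec = spans.setdefault(
            gene_id,
            {
                "chromosome": feat.seqid,
                "strand": strand,
                "start": feat.start,
                "end": feat.end,
                "species": feat.attributes.get("species", [species_default])[0],
            },
        )
        rec["start"] = min(rec["start"], feat.start)
        rec["end"] = max(rec["end"], feat.end)
    return [
        GeneRecord(
            gene_id=gid,
            species=rec["species"],
            chromosome=rec["chromosome"],
            strand=rec["strand"],
            cds_start=rec["start"],
            cds_end=rec["end"],
        )
        for gid, rec in spans.items()
    ]


def write_annotation(genes: Sequence[GeneRecord], path: str | os.PathLike) -> None:
    """Write genes in the tabular dialect (round-trips through read_annotation)."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(TABULAR_GENE_COLUMNS + ("biotype",)) + "\n")
        for g in _sort_genes(genes):
            fh.write(
                "\t".join(
                    [g.gene_id, g.species, g.chromosome, g.strand,
                     str(g.cds_start), str(g.cds_end), g.biotype]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# homology / ortholog tables


def read_homology_table(path: str | os.PathLike) -> list[HomologyHit]:
    """Read a BLAST-style tabular hit file (12-column outfmt-6 or 3-column).

    Only query id, subject id and bitscore are retained; duplicate
    (query, subject) rows collapse to the maximum bitscore.
    """
    best: dict[tuple[str, str], float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) >= 12:
                query, subject, score_str = fields[0], fields[1], fields[11]
            elif len(fields) == 3:
                query, subject, score_str = fields
            else:
                raise ValidationError(
                    f"{path} line {lineno}: expected 3 or >=12 columns, got {len(fields)}"
                )
            try:
                score = float(score_str)
            except ValueError:
                raise ValidationError(
                    f"{path} line {lineno}: non-numeric bitscore {score_str!r}"
                ) from None
            if score < 0:
                raise ValidationError(f"{path} line {lineno}: negative bitscore")
            key = (query, subject)
            best[key] = max(best.get(key, 0.0), score)
    return [HomologyHit(q, s, b) for (q, s), b in sorted(best.items())]


def write_homology_table(hits: Sequence[HomologyHit], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("#query_id\tsubject_id\tbitscore\n")
        for h in sorted(hits, key=lambda h: (h.query_id, h.subject_id)):
            fh.write(f"{h.query_id}\t{h.subject_id}\t{h.bitscore:g}\n")


def read_ortholog_table(
    path: str | os.PathLike, min_confidence: float = 1.0
) -> list[OrthologPair]:
    """Read a 5-column ortholog table; keep rows with confidence >= threshold.

    The default threshold of 1.0 mirrors keeping only fully supported
    orthologous groups.
    """
    pairs: list[OrthologPair] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ValidationError(
                    f"{path} line {lineno}: expected 5 columns, got {len(fields)}"
                )
            sp_a, gene_a, sp_b, gene_b, conf_str = fields
            try:
                conf = float(conf_str)
            except ValueError:
                raise ValidationError(
                    f"{path} line {lineno}: non-numeric confidence {conf_str!r}"
                ) from None
            try:
                pair = OrthologPair(sp_a, gene_a, sp_b, gene_b, conf)
            except ValidationError as exc:
                raise ValidationError(f"{path} line {lineno}: {exc}") from None
            if conf >= min_confidence:
                pairs.append(pair)
    return pairs


def write_ortholog_table(pairs: Sequence[OrthologPair], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("#species_a\tgene_a\tspecies_b\tgene_b\tconfidence\n")
        for p in pairs:
            fh.write(f"{p.species_a}\t{p.gene_a}\t{p.species_b}\t{p.gene_b}\t{p.confidence:g}\n")


# ---------------------------------------------------------------------------
# trees and repeat intervals


def read_tree(path_or_string: str | os.PathLike) -> SpeciesTree:
    """Read a rooted newick species tree; leaf labels must be unique."""
    src = str(path_or_string)
    if os.path.exists(src):
        with open(src) as fh:
            newick = fh.read()
    else:
        newick = src
    try:
        tree = dendropy.Tree.get(data=newick, schema="newick")
    except dendropy.utility.error.DataParseError as exc:
        if "same taxa" in str(exc) or "duplicate" in str(exc).lower():
            raise ValidationError(f"duplicate leaf label in tree: {exc}") from exc
        raise ValidationError(f"invalid newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise ValidationError(f"duplicate leaf labels in tree: {sorted(dupes)}")
    root_children = tree.seed_node.child_nodes()
    if len(root_children) > 2:
        logger.warning(
            "tree root has %d children (unrooted trifurcation?); treating as rooted",
            len(root_children),
        )
    tree.is_rooted = True
    return SpeciesTree(tree)


def read_repeat_bed(path: str | os.PathLike, species: str) -> list[RepeatInterval]:
    """Read a BED3+ file of repeat intervals (0-based half-open on disk)."""
    intervals: list[RepeatInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValidationError(f"{path} line {lineno}: fewer than 3 BED columns")
            chrom = fields[0]
            try:
                start0, end0 = int(fields[1]), int(fields[2])
            except ValueError:
                raise ValidationError(
                    f"{path} line {lineno}: non-integer BED coordinates"
                ) from None
            if start0 >= end0:
                raise ValidationError(
                    f"{path} line {lineno}: start {start0} >= end {end0}"
                )
            if start0 < 0:
                raise ValidationError(f"{path} line {lineno}: negative start")
            # half-open [start0, end0) -> 1-based inclusive [start0+1, end0]
            intervals.append(RepeatInterval(species, chrom, start0 + 1, end0))
    intervals.sort(key=lambda r: (r.chromosome, r.start, r.end))
    return intervals
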