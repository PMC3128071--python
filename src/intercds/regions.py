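"""Adjacent gene pairs, orientation classes, inter-CDS lengths and filters.

An inter-CDS region is the stretch strictly between the ORF boundaries of two
neighbouring protein-coding genes. Pairs are classified by the relative
orientation of the flanking genes, reading the chromosome left to right:

* convergent      ``-> <-``  (plus, minus): flanked by two 3' ends, no promoter
* unidirectional  ``-> ->`` or ``<- <-``: one 5' end faces the region
* divergent       ``<- ->``  (minus, plus): two 5' ends, shared promoter space

Pairs whose ORFs overlap or abut (length <= 0) are dropped; pairs of putative
tandem duplicates (similarity hit with bitscore >= 50 between the flanking
genes) and repeat-containing regions are flagged for exclusion from the
statistics.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .io_formats import (
    STRAND_MINUS,
    STRAND_PLUS,
    GeneRecord,
    HomologyHit,
    RepeatInterval,
    ValidationError,
)

CONVERGENT = "convergent"
UNIDIRECTIONAL = "unidirectional"
DIVERGENT = "divergent"
ORIENTATIONS = (DIVERGENT, UNIDIRECTIONAL, CONVERGENT)

AGE_UNASSIGNED = "unassigned"
AGE_YOUNG = "young"
AGE_OLD = "old"

DEFAULT_TANDEM_BITSCORE = 50.0


@dataclass(frozen=True)
class InterCDSRegion:
    species: str
    chromosome: str
    left_gene: str
    right_gene: str
    left_strand: str
    right_strand: str
    # 1-based inclusive coordinates of the region itself (between the ORFs)
    start: int
    end: int
    orientation: str
    length: int
    tandem_flag: bool = False
    repeat_flag: bool = False
    age_label: str = AGE_UNASSIGNED
    age_class: str | None = None

    @property
    def region_id(self) -> str:
        return f"{self.species}:{self.left_gene}|{self.right_gene}"

    @property
    def retained(self) -> bool:
        """True if the region survives the tandem and repeat filters."""
        return not (self.tandem_flag or self.repeat_flag)


def classify_orientation(left_strand: str, right_strand: str) -> str:
    """Classify a neighbouring pair by the strands of its flanking genes.

    Total over the four strand combinations; invariant under reading the
    chromosome from the other end (both strands flipped, left/right swapped).
    """
    if left_strand == STRAND_PLUS and right_strand == STRAND_MINUS:
        return CONVERGENT
    if left_strand == STRAND_MINUS and right_strand == STRAND_PLUS:
        return DIVERGENT
    return UNIDIRECTIONAL


def inter_cds_length(left: GeneRecord, right: GeneRecord) -> int:
    """Number of nucleotides strictly between two ORFs (may be <= 0 on overlap)."""
    if left.chromosome != right.chromosome:
        raise ValueError(
            f"genes {left.gene_id} and {right.gene_id} are on different chromosomes"
        )
    if left.species != right.species:
        raise ValueError("genes from different species")
    return right.cds_start - left.cds_end - 1


def build_neighbor_pairs(
    genes: Iterable[GeneRecord],
    adjacency_scope: str = "protein_coding_only",
) -> list[InterCDSRegion]:
    """Build inter-CDS regions for directly adjacent gene pairs per chromosome.

    ``adjacency_scope`` controls what counts as an intervening gene:
    ``protein_coding_only`` ignores non-coding records entirely, while
    ``all_features`` lets any annotated feature break adjacency (regions are
    still only formed between protein-coding genes). Pairs with inter-CDS
    length <= 0 are excluded (overlapping or abutting ORFs).
    """
    if adjacency_scope not in ("protein_coding_only", "all_features"):
        raise ValueError(f"unknown adjacency_scope {adjacency_scope!r}")
    genes = list(genes)
    species = {g.species for g in genes}
    if len(species) > 1:
        raise ValidationError(f"genes from multiple species: {sorted(species)}")
    if adjacency_scope == "protein_coding_only":
        # non-coding records neither form pairs nor break adjacency
        genes = [g for g in genes if g.biotype == "protein_coding"]

    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)

    regions: list[InterCDSRegion] = []
    for chrom in sorted(by_chrom):
        chrom_genes = sorted(
            by_chrom[chrom], key=lambda g: (g.cds_start, g.cds_end, g.gene_id)
        )
        for left, right in zip(chrom_genes, chrom_genes[1:]):
            if left.biotype != "protein_coding" or right.biotype != "protein_coding":
                continue  # a pair is only formed between protein-coding genes
            length = inter_cds_length(left, right)
            if length <= 0:
                continue
            regions.append(
                InterCDSRegion(
                    species=left.species,
                    chromosome=chrom,
                    left_gene=left.gene_id,
                    right_gene=right.gene_id,
                    left_strand=left.strand,
                    right_strand=right.strand,
                    start=left.cds_end + 1,
                    end=right.cds_start - 1,
                    orientation=classify_orientation(left.strand, right.strand),
                    length=length,
                )
            )
    regions.sort(key=lambda r: (r.chromosome, r.start, r.end))
    return regions


def filter_tandem(
    regions: Sequence[InterCDSRegion],
    hits: Iterable[HomologyHit],
    bitscore_threshold: float = DEFAULT_TANDEM_BITSCORE,
) -> list[InterCDSRegion]:
    """Flag regions whose flanking genes look like tandem duplicates.

    A region is flagged when max of the two directional hit bitscores between
    its flanking genes is >= the threshold (boundary inclusive). Self-hits in
    the table are ignored. Idempotent; flags are recomputed, not accumulated.
    """
    score: dict[tuple[str, str], float] = {}
    for h in hits:
        if h.query_id == h.subject_id:
            continue
        key = (h.query_id, h.subject_id)
        score[key] = max(score.get(key, 0.0), h.bitscore)
    out = []
    for r in regions:
        s = max(
            score.get((r.left_gene, r.right_gene), 0.0),
            score.get((r.right_gene, r.left_gene), 0.0),
        )
        out.append(replace(r, tandem_flag=s >= bitscore_threshold))
    return out


def filter_repeats(
    regions: Sequence[InterCDSRegion],
    repeats: Iterable[RepeatInterval],
) -> list[InterCDSRegion]:
    """Flag regions overlapped by >= 1 bp of any repeat interval."""
    by_chrom: dict[str, list[RepeatInterval]] = {}
    for rep in repeats:
        by_chrom.setdefault(rep.chromosome, []).append(rep)
    for ivs in by_chrom.values():
        ivs.sort(key=lambda r: (r.start, r.end))
    out = []
    for r in regions:
        flagged = any(
            rep.start <= r.end and rep.end >= r.start
            for rep in by_chrom.get(r.chromosome, ())
        )
        out.append(replace(r, repeat_flag=flagged))
    return out


# ---------------------------------------------------------------------------
# region table I/O (TSV dialect consumed by every downstream module)

REGION_COLUMNS = (
    "species", "chromosome", "left_gene", "right_gene", "left_strand",
    "right_strand", "start", "end", "orientation", "length", "tandem_flag",
    "repeat_flag", "age_label", "age_class",
)


def write_region_table(regions: Sequence[InterCDSRegion], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(REGION_COLUMNS) + "\n")
        for r in regions:
            fh.write(
                "\t".join(
                    [r.species, r.chromosome, r.left_gene, r.right_gene,
                     r.left_strand, r.right_strand, str(r.start), str(r.end),
                     r.orientation, str(r.length), str(int(r.tandem_flag)),
                     str(int(r.repeat_flag)), r.age_label, r.age_class or "."]
                )
                + "\n"
            )


def read_region_table(path: str | os.PathLike) -> list[InterCDSRegion]:
    regions = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != len(REGION_COLUMNS):
                raise ValidationError(f"{path} line {lineno}: wrong column count")
            regions.append(
                InterCDSRegion(
                    species=f[0], chromosome=f[1], left_gene=f[2], right_gene=f[3],
                    left_strand=f[4], right_strand=f[5], start=int(f[6]),
                    end=int(f[7]), orientation=f[8], length=int(f[9]),
                    tandem_flag=bool(int(f[10])), repeat_flag=bool(int(f[11])),
                    age_label=f[12], age_class=None if f[13] == "." else f[13],
                )
            )
    return regions
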