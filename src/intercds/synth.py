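"""Synthetic multi-species genome bundles with known, controllable truth.

The generator emulates the statistical structure a comparative analysis of
inter-CDS regions rests on, so the whole pipeline is testable without any
genome download:

* a rooted species tree over a small clade;
* an ancestral genome whose inter-CDS gaps are drawn per orientation class
  from log-normal (convergent), left-truncated log-normal (unidirectional)
  or two-component truncated mixture (divergent) length distributions;
* rearrangements along each branch — reciprocal translocations, or
  inversions when both breakpoints fall on one chromosome — with both
  breakpoints chosen with probability proportional to gap length (uniform
  per-nucleotide breakage), each event destroying two ancestral regions and
  creating two *young* junction regions with freshly drawn, longer and more
  variable lengths;
* optional "stabilising selection": the longest ancestral promoter-containing
  regions can be made unbreakable, planting a right-tail excess relative to
  a purely neutral expectation;
* orthology by descent, written as pairwise tables with confidence 1.0.

Everything is a pure function of (CladeSpec, seed); ``truth.json`` records
each extant region's birth branch, conservation profile and stratum so every
downstream assertion has an oracle.
"""

from __future__ import annotations

import json
import os
import zlib
from dataclasses import dataclass, field, replace as dc_replace
from typing import Mapping

import dendropy
import numpy as np
from scipy.stats import norm

from .io_formats import (
    STRAND_MINUS,
    STRAND_PLUS,
    GeneRecord,
    HomologyHit,
    OrthologPair,
    RepeatInterval,
    write_annotation,
    write_homology_table,
    write_ortholog_table,
)
from .regions import CONVERGENT, DIVERGENT, UNIDIRECTIONAL, classify_orientation

PROMOTER_ORIENTATIONS = (DIVERGENT, UNIDIRECTIONAL)


@dataclass(frozen=True)
class StratumSpec:
    """Length distribution of one orientation stratum (log10 scale)."""

    orientation: str
    mean_log10: float
    sd_log10: float
    truncation_bp: int = 0
    second_mean_log10: float | None = None
    second_sd_log10: float | None = None
    second_weight: float = 0.0  # weight of the second component

    def __post_init__(self) -> None:
        if self.sd_log10 <= 0:
            raise ValueError("sd_log10 must be positive")
        if self.truncation_bp < 0:
            raise ValueError("truncation_bp must be >= 0")
        if self.second_mean_log10 is not None:
            if not 0.0 < self.second_weight < 1.0:
                raise ValueError("second_weight must lie in (0, 1)")
            if self.second_sd_log10 is None or self.second_sd_log10 <= 0:
                raise ValueError("second component needs a positive sd")

    @property
    def components(self) -> list[tuple[float, float, float]]:
        """(weight, mean, sd) per mixture component."""
        if self.second_mean_log10 is None:
            return [(1.0, self.mean_log10, self.sd_log10)]
        return [
            (1.0 - self.second_weight, self.mean_log10, self.sd_log10),
            (self.second_weight, self.second_mean_log10, self.second_sd_log10),
        ]


def default_old_strata() -> dict[str, StratumSpec]:
    """Ancestral per-orientation length distributions.

    Magnitudes follow compact yeast genomes: log10 means around 2.3-2.9,
    log10 sds 0.15-0.35, left truncation of 160-170 bp for the
    promoter-containing classes (the minimal regulatory space) and a
    two-component divergent stratum (shared vs. two independent promoters).
    """
    return {
        CONVERGENT: StratumSpec(CONVERGENT, 2.30, 0.33, truncation_bp=10),
        UNIDIRECTIONAL: StratumSpec(UNIDIRECTIONAL, 2.60, 0.33, truncation_bp=160),
        DIVERGENT: StratumSpec(
            DIVERGENT, 2.45, 0.13, truncation_bp=170,
            second_mean_log10=2.95, second_sd_log10=0.16, second_weight=0.45,
        ),
    }


@dataclass(frozen=True)
class CladeSpec:
    """Everything needed to grow a synthetic clade, reproducibly."""

    newick: str = "((sp1,sp2),(sp3,sp4));"
    chromosomes: int = 2
    genes_per_chromosome: int = 150
    cds_length_bp: int = 1000
    old_strata: Mapping[str, StratumSpec] = field(default_factory=default_old_strata)
    rearrangements_per_terminal_branch: int = 20
    rearrangements_per_internal_branch: int = 10
    branch_rearrangements: Mapping[str, int] = field(default_factory=dict)
    young_inflation: float = 1.6  # multiplicative shift of young median length
    young_sd_inflation: float = 1.3
    protect_top_fraction: Mapping[str, float] = field(
        default_factory=lambda: {DIVERGENT: 0.10, UNIDIRECTIONAL: 0.10, CONVERGENT: 0.0}
    )
    n_tandem_pairs: int = 0
    n_repeat_regions: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.young_inflation < 1.0:
            raise ValueError("young_inflation must be >= 1")
        if self.genes_per_chromosome < 2:
            raise ValueError("need at least 2 genes per chromosome")

    def young_spec(self, orientation: str) -> StratumSpec:
        old = self.old_strata[orientation]
        shift = float(np.log10(self.young_inflation))
        return dc_replace(
            old,
            mean_log10=old.mean_log10 + shift,
            sd_log10=old.sd_log10 * self.young_sd_inflation,
            second_mean_log10=(
                None if old.second_mean_log10 is None
                else old.second_mean_log10 + shift
            ),
            second_sd_log10=(
                None if old.second_sd_log10 is None
                else old.second_sd_log10 * self.young_sd_inflation
            ),
            truncation_bp=0,
        )


def sample_lengths(spec: StratumSpec, n: int, seed) -> np.ndarray:
    """Draw n integer lengths from the (possibly bimodal) truncated log-normal.

    Rejection sampling above ``truncation_bp``; the analytic acceptance
    probability must exceed 1e-3. Values are rounded and floored at
    max(1, truncation_bp).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    floor = max(1, spec.truncation_bp)
    if spec.truncation_bp > 0:
        log_t = np.log10(spec.truncation_bp)
        accept = sum(
            w * norm.sf((log_t - mu) / sd) for w, mu, sd in spec.components
        )
        if accept < 1e-3:
            raise ValueError(
                f"truncation {spec.truncation_bp} bp leaves acceptance "
                f"{accept:.2g} < 1e-3 for stratum {spec.orientation!r}"
            )
    out = np.empty(0)
    while out.size < n:
        batch = max(n - out.size, 32) * 2
        comps = spec.components
        weights = np.array([w for w, _, _ in comps])
        idx = rng.choice(len(comps), size=batch, p=weights)
        mus = np.array([c[1] for c in comps])[idx]
        sds = np.array([c[2] for c in comps])[idx]
        draws = 10 ** rng.normal(mus, sds)
        if spec.truncation_bp > 0:
            draws = draws[draws >= spec.truncation_bp]
        out = np.concatenate([out, draws])
    lengths = np.maximum(np.round(out[:n]).astype(int), floor)
    return lengths


# ---------------------------------------------------------------------------
# internal mutable genome representation


@dataclass
class _Gap:
    length: int
    birth: str  # branch name ("root" for ancestral gaps)
    protected: bool = False


@dataclass
class _Chromosome:
    genes: list[int]  # ancestral gene indexes, left to right
    strands: list[str]
    gaps: list[_Gap]  # len(genes) - 1


def _gap_orientation(chrom: _Chromosome, gap_idx: int) -> str:
    return classify_orientation(chrom.strands[gap_idx], chrom.strands[gap_idx + 1])


class _Genome:
    def __init__(self, chromosomes: list[_Chromosome]):
        self.chromosomes = chromosomes

    def copy(self) -> "_Genome":
        return _Genome(
            [
                _Chromosome(
                    list(c.genes), list(c.strands),
                    [_Gap(g.length, g.birth, g.protected) for g in c.gaps],
                )
                for c in self.chromosomes
            ]
        )

    def junctions(self) -> list[tuple[int, int]]:
        return [
            (ci, gi)
            for ci, c in enumerate(self.chromosomes)
            for gi in range(len(c.gaps))
        ]


def _build_ancestor(clade: CladeSpec, rng) -> _Genome:
    chroms: list[_Chromosome] = []
    gene_counter = 0
    for _ in range(clade.chromosomes):
        n = clade.genes_per_chromosome
        genes = list(range(gene_counter, gene_counter + n))
        gene_counter += n
        strands = [STRAND_PLUS if rng.random() < 0.5 else STRAND_MINUS for _ in range(n)]
        gaps = []
        for i in range(n - 1):
            orientation = classify_orientation(strands[i], strands[i + 1])
            length = int(
                sample_lengths(
                    clade.old_strata[orientation], 1, rng.integers(2**31 - 1)
                )[0]
            )
            gaps.append(_Gap(length, "root"))
        chroms.append(_Chromosome(genes, strands, gaps))
    genome = _Genome(chroms)
    _mark_protected(genome, clade)
    return genome


def _mark_protected(genome: _Genome, clade: CladeSpec) -> None:
    """Make the longest fraction of each promoter stratum unbreakable."""
    by_orient: dict[str, list[_Gap]] = {}
    for c in genome.chromosomes:
        for gi, gap in enumerate(c.gaps):
            by_orient.setdefault(_gap_orientation(c, gi), []).append(gap)
    for orientation, gaps in by_orient.items():
        frac = clade.protect_top_fraction.get(orientation, 0.0)
        if frac <= 0:
            continue
        lengths = np.array([g.length for g in gaps])
        cutoff = np.quantile(lengths, 1.0 - frac)
        for g in gaps:
            if g.length >= cutoff:
                g.protected = True


def _new_gap(clade: CladeSpec, orientation: str, branch: str, rng) -> _Gap:
    length = int(
        sample_lengths(clade.young_spec(orientation), 1, rng.integers(2**31 - 1))[0]
    )
    return _Gap(length, branch)


def _apply_rearrangement(genome: _Genome, clade: CladeSpec, branch: str, rng) -> None:
    """One event: pick two junctions length-weighted, translocate or invert."""
    juncs = genome.junctions()
    weights = np.array(
        [
            0.0
            if genome.chromosomes[ci].gaps[gi].protected
            else float(genome.chromosomes[ci].gaps[gi].length)
            for ci, gi in juncs
        ]
    )
    if int((weights > 0).sum()) < 2:
        raise ValueError("fewer than 2 breakable regions left for rearrangement")
    p = weights / weights.sum()
    i1 = rng.choice(len(juncs), p=p)
    w2 = weights.copy()
    w2[i1] = 0.0
    i2 = rng.choice(len(juncs), p=w2 / w2.sum())
    (c1, g1), (c2, g2) = juncs[i1], juncs[i2]
    if c1 == c2:
        lo, hi = sorted((g1, g2))
        chrom = genome.chromosomes[c1]
        # invert the block strictly between junctions lo and hi
        block = slice(lo + 1, hi + 1)
        chrom.genes[block] = chrom.genes[block][::-1]
        chrom.strands[block] = [
            STRAND_MINUS if s == STRAND_PLUS else STRAND_PLUS
            for s in chrom.strands[block][::-1]
        ]
        chrom.gaps[lo + 1 : hi] = chrom.gaps[lo + 1 : hi][::-1]
        chrom.gaps[lo] = _new_gap(clade, _gap_orientation(chrom, lo), branch, rng)
        chrom.gaps[hi] = _new_gap(clade, _gap_orientation(chrom, hi), branch, rng)
    else:
        a, b = genome.chromosomes[c1], genome.chromosomes[c2]
        new_a = _Chromosome(
            a.genes[: g1 + 1] + b.genes[g2 + 1 :],
            a.strands[: g1 + 1] + b.strands[g2 + 1 :],
            a.gaps[:g1] + [None] + b.gaps[g2 + 1 :],  # type: ignore[list-item]
        )
        new_b = _Chromosome(
            b.genes[: g2 + 1] + a.genes[g1 + 1 :],
            b.strands[: g2 + 1] + a.strands[g1 + 1 :],
            b.gaps[:g2] + [None] + a.gaps[g1 + 1 :],  # type: ignore[list-item]
        )
        new_a.gaps[g1] = _new_gap(clade, _gap_orientation(new_a, g1), branch, rng)
        new_b.gaps[g2] = _new_gap(clade, _gap_orientation(new_b, g2), branch, rng)
        genome.chromosomes[c1] = new_a
        genome.chromosomes[c2] = new_b


# ---------------------------------------------------------------------------
# clade evolution


@dataclass
class CladeBundle:
    """In-memory result of evolve_clade."""

    clade: CladeSpec
    newick: str
    species: list[str]
    genomes: dict[str, list[GeneRecord]]
    orthologs: list[OrthologPair]
    truth: dict
    tandem_hits: list[HomologyHit] = field(default_factory=list)
    repeats: dict[str, list[RepeatInterval]] = field(default_factory=dict)


def _branch_name(node) -> str:
    if node.is_leaf():
        return node.taxon.label
    return "+".join(sorted(l.taxon.label for l in node.leaf_iter()))


def _gene_id(species: str, ancestral_idx: int) -> str:
    return f"{species}_g{ancestral_idx:05d}"


def _materialize(species: str, genome: _Genome, clade: CladeSpec) -> list[GeneRecord]:
    records = []
    for ci, chrom in enumerate(genome.chromosomes):
        pos = 1
        chrom_name = f"chr{ci + 1}"
        for idx, (gene, strand) in enumerate(zip(chrom.genes, chrom.strands)):
            start = pos
            end = pos + clade.cds_length_bp - 1
            records.append(
                GeneRecord(
                    gene_id=_gene_id(species, gene),
                    species=species,
                    chromosome=chrom_name,
                    strand=strand,
                    cds_start=start,
                    cds_end=end,
                )
            )
            if idx < len(chrom.gaps):
                pos = end + 1 + chrom.gaps[idx].length
    return records


def generate_species_genome(clade: CladeSpec, species: str) -> list[GeneRecord]:
    """A standalone genome for one species drawn from the ancestral strata."""
    tag = zlib.crc32(species.encode()) % (2**31)
    seed = np.random.SeedSequence([clade.seed, tag])
    rng = np.random.default_rng(seed)
    genome = _build_ancestor(clade, rng)
    return _materialize(species, genome, clade)


def _facing(strand: str, side: str) -> str:
    # side: "L" = gene left of the region, "R" = gene right of it
    if side == "L":
        return "3" if strand == STRAND_PLUS else "5"
    return "5" if strand == STRAND_PLUS else "3"


def _adjacency_map(genome: _Genome) -> dict[frozenset[int], tuple[str, str, _Gap]]:
    """Unordered ancestral-gene pair -> (facing end of min gene, of max gene, gap)."""
    out = {}
    for chrom in genome.chromosomes:
        for gi, gap in enumerate(chrom.gaps):
            a, b = chrom.genes[gi], chrom.genes[gi + 1]
            fa = _facing(chrom.strands[gi], "L")
            fb = _facing(chrom.strands[gi + 1], "R")
            if a > b:
                a, b, fa, fb = b, a, fb, fa
            out[frozenset((a, b))] = (fa, fb, gap)
    return out


def evolve_clade(clade: CladeSpec) -> CladeBundle:
    """Grow the clade: ancestor at the root, rearrangements along each branch.

    Branches are processed in a deterministic preorder; each branch applies
    its configured number of rearrangement events (override via
    ``branch_rearrangements``, keyed by leaf name or by the '+'-joined sorted
    leaf set of the subtended clade).
    """
    tree = dendropy.Tree.get(data=clade.newick, schema="newick")
    master = np.random.default_rng(np.random.SeedSequence([clade.seed, 7]))
    ancestor = _build_ancestor(clade, master)

    leaf_genomes: dict[str, _Genome] = {}
    branch_counter = [0]

    def descend(node, genome: _Genome) -> None:
        for child in node.child_nodes():
            name = _branch_name(child)
            n_events = clade.branch_rearrangements.get(
                name,
                clade.rearrangements_per_terminal_branch
                if child.is_leaf()
                else clade.rearrangements_per_internal_branch,
            )
            branch_counter[0] += 1
            rng = np.random.default_rng(
                np.random.SeedSequence([clade.seed, 1000 + branch_counter[0]])
            )
            child_genome = genome.copy()
            for _ in range(n_events):
                _apply_rearrangement(child_genome, clade, name, rng)
            if child.is_leaf():
                leaf_genomes[child.taxon.label] = child_genome
            else:
                descend(child, child_genome)

    descend(tree.seed_node, ancestor)
    species = sorted(leaf_genomes)

    adjacency = {sp: _adjacency_map(g) for sp, g in leaf_genomes.items()}
    truth_regions: dict[str, list[dict]] = {}
    for sp in species:
        entries = []
        for pair, (fa, fb, gap) in sorted(
            adjacency[sp].items(), key=lambda kv: sorted(kv[0])
        ):
            a, b = sorted(pair)
            conserved = sorted(
                other
                for other in species
                if other != sp
                and adjacency[other].get(pair) is not None
                and adjacency[other][pair][:2] == (fa, fb)
            )
            entries.append(
                {
                    "gene_a": _gene_id(sp, a),
                    "gene_b": _gene_id(sp, b),
                    "length": gap.length,
                    "birth": gap.birth,
                    "protected": gap.protected,
                    "conserved_in": conserved,
                    "age_label": "old" if conserved else "young",
                }
            )
        truth_regions[sp] = entries

    orthologs = []
    all_genes = sorted(
        {g for genome in leaf_genomes.values() for c in genome.chromosomes for g in c.genes}
    )
    for i, sp_a in enumerate(species):
        genes_a = {g for c in leaf_genomes[sp_a].chromosomes for g in c.genes}
        for sp_b in species[i + 1 :]:
            genes_b = {g for c in leaf_genomes[sp_b].chromosomes for g in c.genes}
            for g in sorted(genes_a & genes_b):
                orthologs.append(
                    OrthologPair(sp_a, _gene_id(sp_a, g), sp_b, _gene_id(sp_b, g), 1.0)
                )

    genomes = {sp: _materialize(sp, leaf_genomes[sp], clade) for sp in species}
    truth = {
        "seed": clade.seed,
        "species": species,
        "newick": clade.newick,
        "n_genes": len(all_genes),
        "strata": {
            o: {
                "mean_log10": s.mean_log10,
                "sd_log10": s.sd_log10,
                "truncation_bp": s.truncation_bp,
                "second_mean_log10": s.second_mean_log10,
                "second_sd_log10": s.second_sd_log10,
                "second_weight": s.second_weight,
            }
            for o, s in clade.old_strata.items()
        },
        "young_inflation": clade.young_inflation,
        "regions": truth_regions,
        "n_young": {
            sp: sum(1 for e in truth_regions[sp] if e["age_label"] == "young")
            for sp in species
        },
        "tandem_pairs": [],
        "repeat_regions": [],
    }

    bundle = CladeBundle(
        clade=clade,
        newick=clade.newick,
        species=species,
        genomes=genomes,
        orthologs=orthologs,
        truth=truth,
    )
    _plant_tandems(bundle, leaf_genomes)
    _plant_repeats(bundle, leaf_genomes)
    return bundle


def _plant_tandems(bundle: CladeBundle, leaf_genomes: dict[str, _Genome]) -> None:
    clade = bundle.clade
    rng = np.random.default_rng(np.random.SeedSequence([clade.seed, 555]))
    hits: list[HomologyHit] = []
    planted = []
    if clade.n_tandem_pairs > 0:
        sp = bundle.species[0]
        chrom = leaf_genomes[sp].chromosomes[0]
        n_gaps = len(chrom.gaps)
        picks = rng.choice(n_gaps, size=min(clade.n_tandem_pairs, n_gaps), replace=False)
        for gi in sorted(int(x) for x in picks):
            ga = _gene_id(sp, chrom.genes[gi])
            gb = _gene_id(sp, chrom.genes[gi + 1])
            hits.append(HomologyHit(ga, gb, float(rng.uniform(55, 200))))
            planted.append({"species": sp, "gene_a": ga, "gene_b": gb})
        # background sub-threshold noise hits
        for _ in range(clade.n_tandem_pairs):
            i, j = rng.choice(len(chrom.genes), size=2, replace=False)
            hits.append(
                HomologyHit(
                    _gene_id(sp, chrom.genes[int(i)]),
                    _gene_id(sp, chrom.genes[int(j)]),
                    float(rng.uniform(20, 45)),
                )
            )
    bundle.tandem_hits = hits
    bundle.truth["tandem_pairs"] = planted


def _plant_repeats(bundle: CladeBundle, leaf_genomes: dict[str, _Genome]) -> None:
    clade = bundle.clade
    rng = np.random.default_rng(np.random.SeedSequence([clade.seed, 777]))
    planted = []
    repeats: dict[str, list[RepeatInterval]] = {}
    if clade.n_repeat_regions > 0:
        sp = bundle.species[0]
        genes = {g.gene_id: g for g in bundle.genomes[sp]}
        chrom = leaf_genomes[sp].chromosomes[0]
        candidates = [
            gi for gi, gap in enumerate(chrom.gaps) if gap.length >= 20
        ]
        picks = rng.choice(
            len(candidates), size=min(clade.n_repeat_regions, len(candidates)),
            replace=False,
        )
        ivs = []
        for ci in sorted(int(x) for x in picks):
            gi = candidates[ci]
            left = genes[_gene_id(sp, chrom.genes[gi])]
            region_start = left.cds_end + 1
            rep_start = region_start + 5
            rep_end = rep_start + 10
            ivs.append(RepeatInterval(sp, left.chromosome, rep_start, rep_end))
            planted.append(
                {
                    "species": sp,
                    "gene_a": _gene_id(sp, chrom.genes[gi]),
                    "gene_b": _gene_id(sp, chrom.genes[gi + 1]),
                }
            )
        repeats[sp] = ivs
    bundle.repeats = repeats
    bundle.truth["repeat_regions"] = planted


# ---------------------------------------------------------------------------
# bundle serialization


def make_fixture_bundle(clade: CladeSpec, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write a full bundle in the dialects the io layer reads; return paths."""
    bundle = evolve_clade(clade)
    return write_bundle(bundle, out_dir)


def write_bundle(bundle: CladeBundle, out_dir: str | os.PathLike) -> dict[str, str]:
    out = str(out_dir)
    os.makedirs(out, exist_ok=True)
    paths: dict[str, str] = {}

    for sp, genes in bundle.genomes.items():
        p = os.path.join(out, f"genes_{sp}.tsv")
        write_annotation(genes, p)
        paths[f"genes_{sp}"] = p

    tree_path = os.path.join(out, "tree.nwk")
    with open(tree_path, "w") as fh:
        fh.write(bundle.newick.strip() + "\n")
    paths["tree"] = tree_path

    for i, sp_a in enumerate(bundle.species):
        for sp_b in bundle.species[i + 1 :]:
            pairs = [
                p
                for p in bundle.orthologs
                if {p.species_a, p.species_b} == {sp_a, sp_b}
            ]
            p = os.path.join(out, f"orthologs_{sp_a}_{sp_b}.tsv")
            write_ortholog_table(pairs, p)
            paths[f"orthologs_{sp_a}_{sp_b}"] = p

    hom_path = os.path.join(out, "homology.tsv")
    write_homology_table(bundle.tandem_hits, hom_path)
    paths["homology"] = hom_path

    for sp, ivs in bundle.repeats.items():
        p = os.path.join(out, f"repeats_{sp}.bed")
        with open(p, "w") as fh:
            for iv in ivs:
                fh.write(f"{iv.chromosome}\t{iv.start - 1}\t{iv.end}\n")
        paths[f"repeats_{sp}"] = p

    truth_path = os.path.join(out, "truth.json")
    with open(truth_path, "w") as fh:
        json.dump(bundle.truth, fh, indent=1, sort_keys=True)
    paths["truth"] = truth_path
    return paths
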