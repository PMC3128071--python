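"""Neighborhood conservation and age assignment for inter-CDS regions.

A region in a focal species is *conserved* in another species when both
flanking genes have orthologs there, those orthologs are themselves a
retained adjacent pair, and each gene presents the same end (5' or 3') to the
region as its ortholog does. The end-matching formulation makes the test
invariant to the arbitrary reading direction of either chromosome: a pair
carried to the opposite strand by an inversion of the whole neighbourhood
still counts as "same orientation".

Regions conserved nowhere are *young*; all others are *old*. Old regions are
further binned into age classes by the most distal clade of a rooted species
tree in which conservation was found (e.g. the PO / VO / XO grouping used for
S. cerevisiae against its ten relatives).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .io_formats import STRAND_PLUS, SpeciesTree
from .regions import AGE_OLD, AGE_YOUNG, InterCDSRegion

logger = logging.getLogger(__name__)

FIVE_PRIME = "5'"
THREE_PRIME = "3'"


def facing_ends(region: InterCDSRegion) -> dict[str, str]:
    """Which end (5'/3') each flanking gene presents to the region.

    A plus-strand gene to the left of the region ends with its 3' terminus at
    the region boundary; a plus-strand gene to the right begins with its 5'
    terminus there; minus-strand genes are the mirror image.
    """
    left = THREE_PRIME if region.left_strand == STRAND_PLUS else FIVE_PRIME
    right = FIVE_PRIME if region.right_strand == STRAND_PLUS else THREE_PRIME
    return {region.left_gene: left, region.right_gene: right}


@dataclass(frozen=True)
class ConservationProfile:
    region_id: str
    focal_species: str
    conserved_in: frozenset[str]

    def __post_init__(self) -> None:
        if self.focal_species in self.conserved_in:
            raise ValueError("focal species cannot appear in conserved_in")

    @property
    def age_label(self) -> str:
        return AGE_OLD if self.conserved_in else AGE_YOUNG


@dataclass(frozen=True)
class AgeClassScheme:
    """Ordered (nearest-to-farthest) clade classes for one focal species."""

    classes: tuple[tuple[str, frozenset[str]], ...]
    young_label: str = AGE_YOUNG

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for label, species in self.classes:
            if seen & species:
                raise ValueError(f"age class {label!r} overlaps an earlier class")
            seen |= species

    @property
    def all_species(self) -> frozenset[str]:
        return frozenset().union(*(s for _, s in self.classes))


class RegionIndex:
    """Retained regions of one species indexed by unordered flanking-gene pair."""

    def __init__(self, regions: Iterable[InterCDSRegion]):
        self._by_pair: dict[frozenset[str], InterCDSRegion] = {}
        for r in regions:
            if r.tandem_flag:
                # tandem-filtered pairs are excluded from the analysis and
                # cannot witness conservation in either direction
                continue
            self._by_pair[frozenset((r.left_gene, r.right_gene))] = r

    def get(self, gene_a: str, gene_b: str) -> InterCDSRegion | None:
        return self._by_pair.get(frozenset((gene_a, gene_b)))

    def __iter__(self):
        return iter(self._by_pair.values())

    def __len__(self) -> int:
        return len(self._by_pair)


def build_ortholog_map(pairs, species_a: str, species_b: str) -> dict[str, set[str]]:
    """Map genes of species_a to their ortholog sets in species_b (one-to-many)."""
    out: dict[str, set[str]] = {}
    for p in pairs:
        if p.species_a == species_a and p.species_b == species_b:
            out.setdefault(p.gene_a, set()).add(p.gene_b)
        elif p.species_a == species_b and p.species_b == species_a:
            out.setdefault(p.gene_b, set()).add(p.gene_a)
    return out


def is_region_conserved(
    region: InterCDSRegion,
    other_regions: RegionIndex,
    ortholog_map: Mapping[str, set[str]],
) -> bool:
    """Does the region have an orthologous inter-CDS region in the other species?

    True iff both flanking genes have orthologs, some ortholog combination is a
    retained adjacent pair in the other species, and the facing 5'/3' ends
    match gene-by-gene. Any witnessing ortholog combination suffices.
    """
    ends = facing_ends(region)
    left_orths = ortholog_map.get(region.left_gene, ())
    right_orths = ortholog_map.get(region.right_gene, ())
    for oa in left_orths:
        for ob in right_orths:
            if oa == ob:
                continue
            other = other_regions.get(oa, ob)
            if other is None:
                continue
            other_ends = facing_ends(other)
            if (
                other_ends[oa] == ends[region.left_gene]
                and other_ends[ob] == ends[region.right_gene]
            ):
                return True
    return False


def conservation_profile(
    region: InterCDSRegion,
    focal_species: str,
    species_indexes: Mapping[str, RegionIndex],
    ortholog_maps: Mapping[str, Mapping[str, set[str]]],
) -> ConservationProfile:
    """Collect the set of other species in which the region is conserved.

    ``species_indexes`` maps each non-focal species to its RegionIndex;
    ``ortholog_maps`` maps each non-focal species to a focal->other ortholog
    map. A species with no ortholog map is treated as not conserving the
    region (with a warning), so partial datasets degrade gracefully.
    """
    conserved = set()
    for sp, index in species_indexes.items():
        if sp == focal_species:
            continue
        omap = ortholog_maps.get(sp)
        if omap is None:
            logger.warning("no ortholog table for %s vs %s", focal_species, sp)
            continue
        if is_region_conserved(region, index, omap):
            conserved.add(sp)
    return ConservationProfile(region.region_id, focal_species, frozenset(conserved))


def assign_age_class(profile: ConservationProfile, scheme: AgeClassScheme) -> str:
    """Age class = the class of the MOST DISTAL clade with conservation."""
    unknown = profile.conserved_in - scheme.all_species
    if unknown:
        raise ValueError(f"species {sorted(unknown)} missing from age-class scheme")
    if not profile.conserved_in:
        return scheme.young_label
    for label, species in reversed(scheme.classes):
        if species & profile.conserved_in:
            return label
    raise AssertionError("unreachable: nonempty profile covered by scheme")


def scheme_from_tree(
    tree: SpeciesTree,
    focal: str,
    n_classes: int,
    labels: Sequence[str] | None = None,
) -> AgeClassScheme:
    """Build nested-clade age classes from a rooted species tree.

    Walking root-ward from the focal leaf, each internal node contributes one
    "attachment step": the set of leaves first joined there. The farthest
    ``n_classes - 1`` steps each form their own class; all nearer steps merge
    into the first (youngest) class. With the 11-yeast tree, focal ``sce`` and
    ``n_classes=3`` this reproduces the PO / VO / XO grouping.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    dtree = tree.tree
    focal_leaf = None
    for leaf in dtree.leaf_node_iter():
        if leaf.taxon.label == focal:
            focal_leaf = leaf
            break
    if focal_leaf is None:
        raise ValueError(f"focal species {focal!r} is not a leaf of the tree")

    steps: list[frozenset[str]] = []
    covered = {focal}
    node = focal_leaf
    while node.parent_node is not None:
        node = node.parent_node
        leaves = {l.taxon.label for l in node.leaf_iter()}
        new = leaves - covered
        if new:
            steps.append(frozenset(new))
            covered |= new
    if n_classes > len(steps):
        raise ValueError(
            f"n_classes={n_classes} exceeds the {len(steps)} attachment steps "
            f"available for focal {focal!r}"
        )
    n_merge = len(steps) - (n_classes - 1)
    merged = frozenset().union(*steps[:n_merge])
    class_sets = [merged] + steps[n_merge:]
    if labels is None:
        labels = [f"class{i + 1}" for i in range(n_classes)]
    if len(labels) != n_classes:
        raise ValueError("labels length must equal n_classes")
    return AgeClassScheme(tuple(zip(labels, class_sets)))


def annotate_ages(
    regions: Sequence[InterCDSRegion],
    focal_species: str,
    species_indexes: Mapping[str, RegionIndex],
    ortholog_maps: Mapping[str, Mapping[str, set[str]]],
    scheme: AgeClassScheme | None = None,
) -> tuple[list[InterCDSRegion], list[ConservationProfile]]:
    """Label every retained focal region young/old (and age class if a scheme).

    Tandem-flagged regions stay unassigned: they are excluded from the
    analysis entirely.
    """
    out: list[InterCDSRegion] = []
    profiles: list[ConservationProfile] = []
    for r in regions:
        if r.tandem_flag:
            out.append(r)
            continue
        prof = conservation_profile(r, focal_species, species_indexes, ortholog_maps)
        profiles.append(prof)
        age_class = assign_age_class(prof, scheme) if scheme is not None else None
        out.append(replace(r, age_label=prof.age_label, age_class=age_class))
    return out, profiles
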