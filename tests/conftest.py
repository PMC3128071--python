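"""Shared fixtures: small synthetic clades reused across the suite."""

from __future__ import annotations

import pytest
from hypothesis import settings

from intercds.synth import CladeSpec, evolve_clade, write_bundle

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def clade4():
    """A 4-species clade at realistic per-stratum magnitudes.

    ~3200 regions per species (comparable to a compact yeast genome), ~10%
    young, stabilising-selection protection on the promoter-containing
    strata; used for end-to-end checks.
    """
    return CladeSpec(
        newick="((sp1,sp2),(sp3,sp4));",
        chromosomes=4,
        genes_per_chromosome=800,
        rearrangements_per_terminal_branch=160,
        rearrangements_per_internal_branch=80,
        seed=7,
    )


@pytest.fixture(scope="session")
def bundle4(clade4):
    return evolve_clade(clade4)


@pytest.fixture(scope="session")
def bundle4_dir(bundle4, tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle4")
    paths = write_bundle(bundle4, out)
    return paths


@pytest.fixture(scope="session")
def clade11():
    """An 11-species clade on the yeast topology, small genomes, few events."""
    newick = "((((sce,sba),sca),(cgl,(kpo,zro))),((kth,kwa),(skl,(ago,kla))));"
    return CladeSpec(
        newick=newick,
        chromosomes=1,
        genes_per_chromosome=120,
        rearrangements_per_terminal_branch=5,
        rearrangements_per_internal_branch=3,
        seed=11,
    )


@pytest.fixture(scope="session")
def bundle11(clade11):
    return evolve_clade(clade11)
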