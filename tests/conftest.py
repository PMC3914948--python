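"""Shared fixtures: synthetic structures and pairing-list topologies."""

from __future__ import annotations

import pytest

from rna2ss.pair_geometry import detect_base_pairs, detect_stacking
from rna2ss.synth_fixtures import (
    make_bulged_hairpin,
    make_ideal_duplex,
    make_topology,
    pairs_from_list,
)


@pytest.fixture(scope="session")
def duplex8():
    """Ideal A-form 8-bp duplex: (structure, ground-truth pairs)."""
    return make_ideal_duplex("GCGCGCGC")


@pytest.fixture(scope="session")
def duplex8_detected(duplex8):
    structure, truth = duplex8
    return detect_base_pairs(structure), detect_stacking(structure), truth


@pytest.fixture(scope="session")
def bulged_hairpin():
    """Hairpin with stem 8, bulge 2, loop 4: (structure, pairs, bridge stacks)."""
    return make_bulged_hairpin(8, 2, 4)


@pytest.fixture()
def duplex_cif(tmp_path):
    path = tmp_path / "duplex.cif"
    structure, truth = make_ideal_duplex("GCGCGCGC", path)
    return path, structure, truth


@pytest.fixture(scope="session")
def figure2_fixture():
    return make_topology("figure2")


@pytest.fixture(scope="session")
def central_pseudoknot_fixture():
    return make_topology("central_pseudoknot")


@pytest.fixture(scope="session")
def triple_fixture():
    return make_topology("triple_a915")


def as_base_pairs(fixture):
    return pairs_from_list(fixture.pairs)
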