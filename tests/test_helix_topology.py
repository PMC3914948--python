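"""Helix assembly, unique membership, nesting/pseudoknot layers, triples."""

from __future__ import annotations

from itertools import combinations

import pytest

from rna2ss.helix_topology import (
    DomainScheme,
    DomainSchemeError,
    InfeasibleConstraintError,
    SECONDARY,
    TERTIARY,
    apply_helix_labels,
    assemble_helices,
    assign_domains,
    classify_nesting,
    classify_pair_roles,
    decompose_triples,
    enforce_unique_membership,
    helices_cross,
)
from rna2ss.pair_geometry import StackContact, detect_base_pairs, detect_stacking
from rna2ss.synth_fixtures import make_topology, pairs_from_list


def _stack(i, j):
    return StackContact(i=i, j=j, center_distance=3.5, normal_angle=5.0, overlap=2.0)


def _crosses(a, b):
    """Independent crossing oracle straight from the interleaving definition."""
    for (i, q) in a:
        for (j, p) in b:
            if i < j < q < p or j < i < p < q:
                return True
    return False


def _brute_force_layer0_weight(helix_pair_lists):
    """Exhaustive max-weight crossing-free subset over all 2^n subsets."""
    n = len(helix_pair_lists)
    best = 0
    for mask in range(1 << n):
        chosen = [helix_pair_lists[k] for k in range(n) if mask >> k & 1]
        if any(_crosses(a, b) for a, b in combinations(chosen, 2)):
            continue
        best = max(best, sum(len(h) for h in chosen))
    return best


class TestAssembly:
    def test_empty_pair_list(self):
        assert assemble_helices([], [], 10) == []

    def test_figure2_topology_gives_four_helices(self, figure2_fixture):
        helices = assemble_helices(
            pairs_from_list(figure2_fixture.pairs), [], figure2_fixture.n_residues
        )
        assert len(helices) == figure2_fixture.expected["helix_count"]

    def test_out_of_range_pair_rejected(self):
        with pytest.raises(ValueError):
            assemble_helices(pairs_from_list([(1, 30)]), [], 20)

    def test_bulge_bridged_by_stack_is_one_helix(self, bulged_hairpin):
        structure, truth, bridge = bulged_hairpin
        pairs = detect_base_pairs(structure)
        stacks = detect_stacking(structure)
        assert [(p.i, p.j) for p in pairs] == truth
        helices = assemble_helices(pairs, stacks, structure.n_residues)
        assert len(helices) == 1
        assert helices[0].has_defect is True

    def test_bulge_without_bridging_stack_splits_helix(self, bulged_hairpin):
        structure, _, bridge = bulged_hairpin
        pairs = detect_base_pairs(structure)
        stacks = [s for s in detect_stacking(structure) if (s.i, s.j) not in bridge]
        helices = assemble_helices(pairs, stacks, structure.n_residues)
        assert len(helices) == 2
        assert all(not h.has_defect for h in helices)

    def test_noncanonical_pairs_chain_like_canonical(self):
        pairs = pairs_from_list([(1, 20, True), (2, 19, False), (3, 18, True)])
        helices = assemble_helices(pairs, [], 20)
        assert len(helices) == 1 and helices[0].weight == 3

    def test_strand_connectivity_invariant(self, figure2_fixture):
        helices = assemble_helices(
            pairs_from_list(figure2_fixture.pairs), [], figure2_fixture.n_residues
        )
        for h in helices:
            for a, b in zip(h.pairs, h.pairs[1:]):
                assert a.i < b.i and b.j < a.j


class TestUniqueMembership:
    def test_disjoint_helices_unchanged(self, figure2_fixture):
        helices = assemble_helices(
            pairs_from_list(figure2_fixture.pairs), [], figure2_fixture.n_residues
        )
        out, demoted = enforce_unique_membership(helices, pairs_from_list(figure2_fixture.pairs))
        assert demoted == []
        assert [len(h.pairs) for h in out] == [len(h.pairs) for h in helices]

    def test_longer_helix_keeps_shared_residue(self):
        # residue 15 shared between a 3-pair and a 2-pair helix via a triple
        big = [(13, 42), (14, 41), (15, 40)]
        small = [(15, 60), (16, 59)]
        all_pairs = pairs_from_list(big) + pairs_from_list(small)
        helices = assemble_helices(all_pairs, [], 60)
        out, demoted = enforce_unique_membership(helices, all_pairs)
        kept = {p.key() for h in out for p in h.pairs}
        assert set(k[:2] for k in [(15, 40)]) <= kept
        assert [(p.i, p.j) for p in demoted] == [(15, 60)]

    def test_equal_size_tie_prefers_earlier_start(self):
        first = [(10, 40), (11, 39), (12, 38)]
        second = [(12, 60), (13, 59), (14, 58)]  # shares residue 12
        all_pairs = pairs_from_list(first) + pairs_from_list(second)
        helices = assemble_helices(all_pairs, [], 60)
        out, demoted = enforce_unique_membership(helices, all_pairs)
        assert (12, 60) in [(p.i, p.j) for p in demoted]
        assert (12, 38) in {p.key() for h in out for p in h.pairs}

    def test_triple_partner_demoted_helix_intact(self, triple_fixture):
        all_pairs = pairs_from_list(triple_fixture.pairs)
        helices = assemble_helices(all_pairs, [], triple_fixture.n_residues)
        out, demoted = enforce_unique_membership(helices, all_pairs)
        assert len(out) == triple_fixture.expected["helix_count"]
        assert [(p.i, p.j) for p in demoted] == triple_fixture.expected["demoted"]
        out[0].validate()

    def test_idempotence(self, triple_fixture):
        all_pairs = pairs_from_list(triple_fixture.pairs)
        helices = assemble_helices(all_pairs, [], triple_fixture.n_residues)
        once, dem1 = enforce_unique_membership(helices, all_pairs)
        twice, dem2 = enforce_unique_membership(once, all_pairs)
        assert dem2 == []
        assert [[p.key() for p in h.pairs] for h in twice] == [
            [p.key() for p in h.pairs] for h in once]


class TestPairRoles:
    def test_helix_pairs_secondary_rest_tertiary(self, triple_fixture):
        all_pairs = pairs_from_list(triple_fixture.pairs)
        helices = assemble_helices(all_pairs, [], triple_fixture.n_residues)
        helices, _ = enforce_unique_membership(helices, all_pairs)
        ann = classify_pair_roles(helices, all_pairs)
        assert ann.pair_role[(15, 915)] == SECONDARY
        assert ann.pair_role[(15, 20)] == TERTIARY
        # conservation: every detected pair got exactly one role
        assert set(ann.pair_role) == {p.key() for p in all_pairs}

    def test_noncanonical_extension_is_secondary(self):
        pairs = pairs_from_list([(1, 20, True), (2, 19, True), (3, 18, False)])
        helices = assemble_helices(pairs, [], 20)
        ann = classify_pair_roles(helices, pairs)
        assert ann.pair_role[(3, 18)] == SECONDARY

    def test_isolated_unchainable_pair_is_tertiary(self):
        pairs = pairs_from_list([(1, 40), (2, 39), (20, 70)])
        helices = assemble_helices(pairs, [], 80)
        ann = classify_pair_roles(helices, pairs)
        assert ann.pair_role[(20, 70)] == TERTIARY


class TestNesting:
    def test_single_helix_layer0(self):
        helices = assemble_helices(pairs_from_list([(1, 10), (2, 9)]), [], 10)
        ann = classify_nesting(helices)
        assert ann.layer[helices[0].helix_id] == 0
        assert ann.helix_class[helices[0].helix_id] == "nested_secondary"

    def test_figure2_blue_helix_in_layer1(self, figure2_fixture):
        helices = assemble_helices(
            pairs_from_list(figure2_fixture.pairs), [], figure2_fixture.n_residues
        )
        ann = classify_nesting(helices)
        nonzero = [h for h in helices if ann.layer[h.helix_id] > 0]
        assert len(nonzero) == figure2_fixture.expected["nonnested_count"]
        assert nonzero[0].strand5_range[0] == figure2_fixture.expected["nonnested_strand5_start"]
        assert ann.helix_class[nonzero[0].helix_id] == "non_nested_tertiary"
        assert ann.layer[nonzero[0].helix_id] == 1

    def test_layer0_pairwise_noncrossing(self, figure2_fixture):
        helices = assemble_helices(
            pairs_from_list(figure2_fixture.pairs), [], figure2_fixture.n_residues
        )
        ann = classify_nesting(helices)
        layer0 = [h for h in helices if ann.layer[h.helix_id] == 0]
        for a, b in combinations(layer0, 2):
            assert not helices_cross(a, b)

    @pytest.mark.parametrize("seed", range(25))
    def test_exact_search_matches_exhaustive_oracle(self, seed):
        fixture = make_topology("random", n_helices=8, seed=seed)
        helices = assemble_helices(pairs_from_list(fixture.pairs), [], fixture.n_residues)
        ann = classify_nesting(helices)
        got = sum(h.weight for h in helices if ann.layer[h.helix_id] == 0)
        oracle = _brute_force_layer0_weight(
            [[p.key() for p in h.pairs] for h in helices]
        )
        assert got == oracle

    def test_forced_secondary_overrides_weight(self, central_pseudoknot_fixture):
        fx = central_pseudoknot_fixture
        helices = assemble_helices(pairs_from_list(fx.pairs), [], fx.n_residues)
        apply_helix_labels(helices, fx.labels)
        forced = next(h for h in helices if h.label == "Helix 2")
        other = next(h for h in helices if h.label is None)
        assert forced.weight < other.weight  # forcing must go against weight
        ann = classify_nesting(helices, forced_secondary=["Helix 2"])
        assert ann.layer[forced.helix_id] == 0
        assert ann.helix_class[forced.helix_id] == "forced_secondary"
        assert ann.layer[other.helix_id] == 1

    def test_unforced_result_is_max_weight(self, central_pseudoknot_fixture):
        fx = central_pseudoknot_fixture
        helices = assemble_helices(pairs_from_list(fx.pairs), [], fx.n_residues)
        ann = classify_nesting(helices)
        weight0 = sum(h.weight for h in helices if ann.layer[h.helix_id] == 0)
        assert weight0 == fx.expected["unforced_layer0_weight"]

    def test_mutually_crossing_forced_helices_infeasible(self):
        pairs = pairs_from_list([(1, 30), (2, 29), (10, 50), (11, 49)])
        helices = assemble_helices(pairs, [], 50)
        helices[0].label = "X"
        helices[1].label = "Y"
        with pytest.raises(InfeasibleConstraintError):
            classify_nesting(helices, forced_secondary=["X", "Y"])

    def test_monotonicity_noncrossing_addition(self, figure2_fixture):
        base_pairs = pairs_from_list(figure2_fixture.pairs)
        helices = assemble_helices(base_pairs, [], figure2_fixture.n_residues)
        ann0 = classify_nesting(helices)
        layer0_before = {
            h.strand5_range for h in helices if ann0.layer[h.helix_id] == 0}
        # append a helix far downstream that crosses nothing
        extra = pairs_from_list([(90, 99), (91, 98)])
        helices2 = assemble_helices(base_pairs + extra, [], 100)
        ann1 = classify_nesting(helices2)
        layer0_after = {
            h.strand5_range for h in helices2 if ann1.layer[h.helix_id] == 0}
        assert layer0_before <= layer0_after


class TestTriples:
    def test_central_pseudoknot_triple_partners(self, triple_fixture):
        all_pairs = pairs_from_list(triple_fixture.pairs)
        helices = assemble_helices(all_pairs, [], triple_fixture.n_residues)
        helices, _ = enforce_unique_membership(helices, all_pairs)
        ann = classify_pair_roles(helices, all_pairs)
        partners = decompose_triples(all_pairs, ann, triple_fixture.n_residues)
        assert partners[15] == triple_fixture.expected["partners_15"]
        assert partners[20] == triple_fixture.expected["partners_20"]
        assert partners[915] == triple_fixture.expected["partners_915"]

    def test_duplex_has_single_partners(self, figure2_fixture):
        all_pairs = pairs_from_list(figure2_fixture.pairs)
        helices = assemble_helices(all_pairs, [], figure2_fixture.n_residues)
        ann = classify_pair_roles(helices, all_pairs)
        partners = decompose_triples(all_pairs, ann, figure2_fixture.n_residues)
        for p in all_pairs:
            assert partners[p.i] == [p.j]
            assert partners[p.j] == [p.i]

    def test_two_triples_survive_as_four_pairs(self):
        # two hub-and-spoke triples entered as two pairs each
        pairs = pairs_from_list([(12, 22), (22, 912), (13, 20), (20, 914)])
        helices = assemble_helices(pairs, [], 920)
        helices, _ = enforce_unique_membership(helices, pairs)
        ann = classify_pair_roles(helices, pairs)
        partners = decompose_triples(pairs, ann, 920)
        edges = {(min(a, b), max(a, b)) for a in partners for b in partners[a]}
        assert edges == {(12, 22), (22, 912), (13, 20), (20, 914)}

    def test_decomposition_conserves_pair_multiset(self, triple_fixture):
        all_pairs = pairs_from_list(triple_fixture.pairs)
        helices = assemble_helices(all_pairs, [], triple_fixture.n_residues)
        helices, _ = enforce_unique_membership(helices, all_pairs)
        ann = classify_pair_roles(helices, all_pairs)
        partners = decompose_triples(all_pairs, ann, triple_fixture.n_residues)
        edges = {(min(a, b), max(a, b)) for a in partners for b in partners[a]}
        assert edges == {p.key() for p in all_pairs}


class TestDomains:
    def test_direct_lookup(self):
        scheme = DomainScheme(domains=[
            ("A", "blue", [(1, 10)]), ("B", "red", [(11, 20)])])
        labels = assign_domains(20, scheme)
        assert labels[:10] == ["A"] * 10 and labels[10:] == ["B"] * 10

    def test_empty_scheme_unassigned(self):
        assert assign_domains(5, DomainScheme()) == ["unassigned"] * 5

    def test_overlapping_ranges_rejected(self):
        scheme = DomainScheme(domains=[
            ("A", "blue", [(1, 10)]), ("B", "red", [(5, 20)])])
        with pytest.raises(DomainSchemeError):
            assign_domains(20, scheme)

    def test_range_beyond_structure_rejected(self):
        scheme = DomainScheme(domains=[("A", "blue", [(1, 30)])])
        with pytest.raises(DomainSchemeError):
            assign_domains(20, scheme)
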