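import numpy as np
import pytest

from tdbn import (
    BooleanFunction,
    CountTable,
    InsufficientDataError,
    Relation,
    RelationType,
    Side,
    basic_relations,
    combine,
    consistent_basic_relations,
    equivalent,
    exhaustive_transitions,
    infer_network_noiseless,
    networks_equivalent,
    random_network,
)
from tdbn.simulate import TransitionSample

from .conftest import row_order_counts


def table(counts, target=1, inputs=(1, 2)):
    counts = np.asarray(counts)
    return CountTable(target, inputs, counts, int(counts.sum()))


class TestBasicRelations:
    def test_eight_patterns_for_a_pair(self):
        basics = basic_relations((1, 2))
        assert len(basics) == 8
        sides = [b.side for b in basics]
        assert sides[1::2] == [Side.LEFT] * 4 and sides[0::2] == [Side.RIGHT] * 4
        # each implied OR-form vanishes exactly at its forbidden input pattern
        for b in basics:
            assert b.func.table[b.forbidden_cell >> 1] == 0
            assert sum(b.func.table) == 3


class TestConsistency:
    def test_single_zero_in_output1_row(self):
        counts = row_order_counts((30, 12, 10, 15), (0, 9, 5, 17))  # m_001 = 0
        found = consistent_basic_relations(table(counts))
        assert len(found) == 1
        b = found[0]
        assert b.side is Side.LEFT
        assert equivalent(b.func, BooleanFunction((1, 2), (0, 1, 1, 1)))

    def test_all_positive_means_no_relation(self):
        counts = row_order_counts((3, 1, 2, 4), (2, 2, 1, 1))
        assert consistent_basic_relations(table(counts)) == []

    def test_similarity_footprint_gives_two_per_side(self):
        # v_h ~ target: zeros at m_010, m_110, m_001, m_101
        counts = row_order_counts((5, 0, 7, 0), (0, 6, 0, 8))
        found = consistent_basic_relations(table(counts))
        assert sum(b.side is Side.LEFT for b in found) == 2
        assert sum(b.side is Side.RIGHT for b in found) == 2

    def test_empty_table_is_an_error(self):
        with pytest.raises(InsufficientDataError):
            consistent_basic_relations(table(np.zeros(8, dtype=int)))


class TestCombine:
    def pick(self, inputs, cells):
        basics = basic_relations(inputs)
        return [basics[c] for c in cells]

    def test_three_left_or_forms_conjoin_to_and(self):
        # forbidden input patterns 00, 01, 10 in the output-1 row
        rel = combine(self.pick((1, 2), [0b001, 0b011, 0b101]), target=3)
        assert rel.rtype is RelationType.PREREQ_TARGET
        assert equivalent(rel.func, BooleanFunction((1, 2), (0, 0, 0, 1)))

    def test_similarity_pattern_yields_similar_relation(self):
        rel = combine(self.pick((1, 2), [0b001, 0b101, 0b010, 0b110]), target=3)
        assert rel.rtype is RelationType.SIMILAR
        assert equivalent(rel.func, BooleanFunction((2,), (0, 1)))

    def test_non_dual_pair_is_dropped(self):
        # LEFT (v1 or v2), RIGHT (v1 or not v2): duals do not match
        assert combine(self.pick((1, 2), [0b001, 0b010]), target=3) is None

    def test_right_only_targets_the_dual(self):
        rel = combine(self.pick((1, 2), [0b000]), target=3)
        assert rel.rtype is RelationType.PREREQ_DUAL
        assert equivalent(rel.func, BooleanFunction((1, 2), (0, 1, 1, 1)))

    def test_contradictory_left_set_is_vacuous(self):
        # all four output-1 cells forbidden: the conjunction is constant 0
        assert combine(self.pick((1, 2), [0b001, 0b011, 0b101, 0b111]), 3) is None

    def test_no_basics_no_relation(self):
        assert combine([], target=1) is None


class TestInferNoiseless:
    def test_recovers_e3_from_exhaustive_data(self, e3):
        rec = infer_network_noiseless(exhaustive_transitions(e3), 3, 2)
        assert networks_equivalent(rec, e3)

    def test_recovers_e3_from_a_superset(self, e3):
        samples = exhaustive_transitions(e3) * 3
        assert networks_equivalent(infer_network_noiseless(samples, 3, 2), e3)

    def test_unregulated_single_gene(self):
        samples = [
            TransitionSample(np.array([a], dtype=np.int8), np.array([b], dtype=np.int8))
            for a in (0, 1)
            for b in (0, 1)
        ]
        rec = infer_network_noiseless(samples, 1, 1)
        assert rec.relations == ()

    def test_incomplete_inputs_do_not_invent_a_relation(self, e3):
        # only inputs with v1 = 1: the v1' rule is not identifiable
        samples = [s for s in exhaustive_transitions(e3) if s.input[0] == 1]
        rec = infer_network_noiseless(samples, 3, 2)
        assert rec.relation_for(1) is None

    def test_no_samples_is_an_error(self):
        with pytest.raises(InsufficientDataError):
            infer_network_noiseless([], 3, 2)

    def test_exact_recovery_on_random_networks(self):
        # the uniqueness guarantee: complete input/output data identify the
        # network exactly, across 200 random topologies
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(3, 9))
            net = random_network(n, 2, int(rng.integers(0, 2**31)))
            rec = infer_network_noiseless(exhaustive_transitions(net), n, 2)
            assert networks_equivalent(rec, net), net.to_json()
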