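import numpy as np
import pytest

from tdbn import (
    ConflictError,
    RelationType,
    ScoredHypothesis,
    add_noise,
    assemble,
    basic_relations,
    equivalent,
    generate_transitions,
    has_conflict,
    identification_probability,
    maximum_compatibility_threshold,
    networks_equivalent,
    p_score_table,
    score_all,
)
from tdbn.boolean_logic import BooleanFunction


def hyp(inputs, cell, score, target=1):
    return ScoredHypothesis(target, tuple(inputs), cell, score,
                            basic_relations(inputs)[cell])


class TestScoreAll:
    def test_entry_count(self, e3):
        rng = np.random.default_rng(0)
        samples = add_noise(generate_transitions(e3, 60, rng), 0.05, rng)
        scored = score_all(samples, 3, 2)
        assert len(scored) == 3 * 3 * 8  # C(3,2) tuples x 3 targets x 8 cells

    def test_agrees_with_p_score_table(self, e3):
        rng = np.random.default_rng(1)
        samples = add_noise(generate_transitions(e3, 60, rng), 0.05, rng)
        scored = score_all(samples, 3, 2)
        row = sorted(
            (s for s in scored if s.inputs == (1, 3) and s.target == 1),
            key=lambda s: s.cell,
        )
        expected = p_score_table(samples, 1, (1, 3))
        assert np.allclose([s.score for s in row], expected)

    def test_deterministic(self, e3):
        rng = np.random.default_rng(2)
        samples = add_noise(generate_transitions(e3, 60, rng), 0.05, rng)
        a = [s.score for s in score_all(samples, 3, 2)]
        b = [s.score for s in score_all(samples, 3, 2)]
        assert a == b


# the selected hypotheses of the canonical worked example: every structural
# zero of the three-gene network, expressed as (inputs, cell, target)
E3_TRUE_CELLS = [
    ((1, 3), 0b001, 1),
    ((1, 3), 0b001, 2), ((1, 3), 0b011, 2), ((1, 3), 0b101, 2),
    ((1, 2), 0b001, 2), ((1, 2), 0b011, 2),
    ((2, 3), 0b001, 2), ((2, 3), 0b101, 2),
    ((1, 2), 0b001, 3), ((1, 2), 0b101, 3), ((1, 2), 0b010, 3), ((1, 2), 0b110, 3),
    ((2, 3), 0b001, 3), ((2, 3), 0b011, 3), ((2, 3), 0b100, 3), ((2, 3), 0b110, 3),
]


def e3_true_selection(score=0.02):
    return [hyp(i, c, score, t) for i, c, t in E3_TRUE_CELLS]


class TestHasConflict:
    def test_two_prerequisites_exceeding_indegree(self):
        sel = [hyp((1, 3), 0b001, 0.016, 1), hyp((2, 3), 0b101, 0.138, 1)]
        conflicted, why = has_conflict(sel, 2)
        assert conflicted and "v'1" in why

    def test_true_relation_set_is_compatible(self):
        conflicted, _ = has_conflict(e3_true_selection(), 2)
        assert not conflicted

    def test_empty_selection(self):
        assert has_conflict([], 2) == (False, None)

    def test_all_left_cells_of_one_table_are_contradictory(self):
        sel = [hyp((1, 2), c, 0.01, 1) for c in (0b001, 0b011, 0b101, 0b111)]
        conflicted, why = has_conflict(sel, 2)
        assert conflicted and "constant" in why

    def test_partial_similarity_evidence_is_not_a_conflict(self):
        # one flank from each pair table: individually inconclusive, jointly
        # harmless — admitted evidence that has not yet completed a pattern
        sel = [hyp((1, 2), 0b010, 0.01, 3), hyp((1, 2), 0b101, 0.01, 3),
               hyp((2, 3), 0b110, 0.01, 3), hyp((2, 3), 0b011, 0.01, 3)]
        conflicted, _ = has_conflict(sel, 2)
        assert not conflicted


class TestThreshold:
    def test_first_conflicting_score_caps_the_selection(self):
        sel = [
            hyp((1, 3), 0b001, 0.016, 1),
            hyp((1, 3), 0b001, 0.039, 2),
            hyp((2, 3), 0b101, 0.138, 1),  # admitting this needs 3 genes
            hyp((1, 2), 0b001, 0.200, 1),
        ]
        res = maximum_compatibility_threshold(sel, 2)
        assert res.threshold == 0.138
        assert {s.score for s in res.selected} == {0.016, 0.039}
        assert not has_conflict(res.selected, 2)[0]

    def test_all_compatible_gives_the_cap(self):
        sel = e3_true_selection()
        res = maximum_compatibility_threshold(sel, 2, cap=0.5)
        assert res.threshold == 0.5
        assert len(res.selected) == len(sel)

    def test_tied_scores_at_the_conflict_point_are_both_excluded(self):
        sel = [
            hyp((1, 3), 0b001, 0.01, 1),
            hyp((2, 3), 0b101, 0.138, 1),
            hyp((2, 3), 0b011, 0.138, 2),
        ]
        res = maximum_compatibility_threshold(sel, 2)
        assert res.threshold == 0.138
        assert {s.score for s in res.selected} == {0.01}

    def test_transient_conflict_is_swept_past(self):
        # two lone dual-side flanks conflict on their own but are completed
        # into a similarity by later admissions: the bigger prefix wins
        sel = [hyp((1, 2), 0b010, 0.01, 3), hyp((2, 3), 0b100, 0.02, 3),
               hyp((1, 2), 0b001, 0.03, 3), hyp((1, 2), 0b101, 0.04, 3),
               hyp((1, 2), 0b110, 0.04, 3), hyp((2, 3), 0b001, 0.05, 3),
               hyp((2, 3), 0b011, 0.05, 3), hyp((2, 3), 0b110, 0.06, 3)]
        res = maximum_compatibility_threshold(sel, 2, cap=0.5)
        assert res.threshold == 0.5
        assert len(res.selected) == len(sel)

    def test_must_include_lower_bounds_the_threshold(self):
        sel = [
            hyp((1, 3), 0b001, 0.01, 1),
            hyp((2, 3), 0b101, 0.138, 1),
            hyp((1, 2), 0b001, 0.30, 2),
        ]
        res = maximum_compatibility_threshold(
            sel, 2, must_include=[(1, (2, 3), 0b101)]
        )
        assert any(s.score == 0.138 for s in res.selected)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            maximum_compatibility_threshold([], 2)


class TestAssemble:
    def test_true_selection_reassembles_e3(self, e3):
        net = assemble(e3_true_selection(), 3, 2)
        assert networks_equivalent(net, e3)

    def test_empty_selection_gives_empty_network(self):
        net = assemble([], 3, 2)
        assert net.relations == ()

    def test_similarity_cells_only(self):
        sel = [hyp((1, 2), c, 0.01, 3)
               for c in (0b001, 0b101, 0b010, 0b110)]
        net = assemble(sel, 3, 2)
        rel = net.relation_for(3)
        assert rel.rtype is RelationType.SIMILAR
        assert equivalent(rel.func, BooleanFunction((2,), (0, 1)))

    def test_conflicting_selection_is_a_hard_error(self):
        sel = [hyp((1, 3), 0b001, 0.016, 1), hyp((2, 3), 0b101, 0.138, 1)]
        with pytest.raises(ConflictError):
            assemble(sel, 3, 2)


class TestIdentificationProbability:
    def test_noiseless_e3_nearly_certain_at_m200(self, e3):
        assert identification_probability(e3, 200, 0.0, 50, seed=5) >= 0.95

    def test_monotone_in_sample_size(self, e3):
        low = identification_probability(e3, 25, 0.0, 30, seed=6)
        high = identification_probability(e3, 400, 0.0, 30, seed=6)
        assert high >= low

    def test_single_sample_never_identifies(self, e3):
        assert identification_probability(e3, 1, 0.0, 20, seed=7) <= 0.05


class TestComplexityContract:
    def test_scored_hypothesis_count_scales_as_designed(self):
        # C(n, K) * n * 2^(K+1) EM fits, each with bounded iterations: the
        # advertised complexity of the scoring stage
        from tdbn import random_network

        for n in (3, 4, 5):
            net = random_network(n, 2, seed=n)
            rng = np.random.default_rng(n)
            samples = add_noise(generate_transitions(net, 40, rng), 0.05, rng)
            scored = score_all(samples, n, 2, max_iter=400)
            from math import comb

            assert len(scored) == comb(n, 2) * n * 8
            assert all(s.em_iterations <= 400 for s in scored)
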