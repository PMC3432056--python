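"""Exact network identification from noise-free transition data.

With no observation noise, a relation betrays itself through *structural
zeros* in the count tables.  Eight basic single-zero patterns exist for a
pair of inputs (2^(k+1) in general): a zero in the output-1 row at input
pattern c says "inputs at c force the target off", i.e. the OR-of-literals
function vanishing exactly at c is prerequisite to the target (a LEFT basic
relation); a zero in the output-0 row says the same function is
prerequisite to the target's dual (RIGHT).  Every observed basic relation
is a true constraint, so all of them are combined by conjunction: the AND
of the LEFT functions is prerequisite to the target, the AND of the RIGHT
functions to its dual, and when the two sides are duals of one another the
relation is the deterministic similarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from functools import reduce as _fold
from typing import Sequence

from .boolean_logic import BooleanFunction, conjunction, dual, equivalent, maxterm
from .boolean_logic import reduce as breduce
from .counts import CountTable, build_count_table
from .model import Relation, RelationType, TimeDelayBooleanNetwork
from .simulate import TransitionSample, canonical_tuples, stack_transitions

__all__ = [
    "Side",
    "BasicRelation",
    "InsufficientDataError",
    "basic_relations",
    "consistent_basic_relations",
    "combine",
    "combine_across_tuples",
    "infer_network_noiseless",
]

logger = logging.getLogger(__name__)


class InsufficientDataError(ValueError):
    """Raised when a count table holds no samples at all."""


class Side(Enum):
    LEFT = "prereq_target"   # forbidden cell in the output-1 row
    RIGHT = "prereq_dual"    # forbidden cell in the output-0 row


@dataclass(frozen=True)
class BasicRelation:
    """One single-forbidden-cell pattern and the OR-form function it implies."""

    forbidden_cell: int
    side: Side
    func: BooleanFunction


def basic_relations(inputs: Sequence[int]) -> list[BasicRelation]:
    """The ``2**(k+1)`` basic relations for an ordered input tuple.

    Cell ``c`` (input pattern in the high bits, output bit lowest) maps to
    the function that is 0 exactly at that input pattern; output bit 1 gives
    a LEFT (prerequisite-to-target) relation, output bit 0 a RIGHT one.
    """
    inputs = tuple(int(g) for g in inputs)
    out = []
    for cell in range(2 ** (len(inputs) + 1)):
        pattern, outbit = cell >> 1, cell & 1
        side = Side.LEFT if outbit == 1 else Side.RIGHT
        out.append(BasicRelation(cell, side, maxterm(inputs, pattern)))
    return out


def consistent_basic_relations(tab: CountTable) -> list[BasicRelation]:
    """Basic relations whose forbidden cell has zero count in ``tab``."""
    if tab.N == 0:
        raise InsufficientDataError(
            f"no samples for inputs {tab.inputs}, target {tab.target}"
        )
    return [
        b for b in basic_relations(tab.inputs) if tab.counts[b.forbidden_cell] == 0
    ]


def _conjoin(funcs: list[BooleanFunction]) -> BooleanFunction | None:
    if not funcs:
        return None
    return breduce(_fold(conjunction, funcs))


def _combine_sides(
    f_left: BooleanFunction | None,
    f_right: BooleanFunction | None,
    target: int,
) -> tuple[Relation | None, str]:
    """Turn combined LEFT/RIGHT functions into a relation and a status.

    status: ``ok``, ``empty``, ``constant`` (a side is vacuous or
    contradictory), ``dual_mismatch`` (both sides present, not duals of each
    other, but jointly satisfiable — not enough information to decide) or
    ``unsatisfiable`` (some input would force the target both on and off).
    """
    if f_left is None and f_right is None:
        return None, "empty"
    if (f_left is not None and f_left.is_constant()) or (
        f_right is not None and f_right.is_constant()
    ):
        return None, "constant"
    if f_left is not None and f_right is None:
        return Relation(f_left, target, RelationType.PREREQ_TARGET), "ok"
    if f_right is not None and f_left is None:
        return Relation(f_right, target, RelationType.PREREQ_DUAL), "ok"
    if equivalent(dual(f_right), f_left):
        return Relation(breduce(f_left), target, RelationType.SIMILAR), "ok"
    # both sides fire together at some input <=> NOT (f_l OR f_r) satisfiable
    both_off = breduce(conjunction(dual(f_left), dual(f_right)))
    if both_off.is_constant() and both_off.table[0] == 0:
        return None, "dual_mismatch"
    return None, "unsatisfiable"


def _combine_status(
    basics: Sequence[BasicRelation], target: int
) -> tuple[Relation | None, str]:
    """Combine the basic relations of a single count table for one target."""
    f_left = _conjoin([b.func for b in basics if b.side is Side.LEFT])
    f_right = _conjoin([b.func for b in basics if b.side is Side.RIGHT])
    return _combine_sides(f_left, f_right, target)


def combine_across_tuples(
    basics: Sequence[BasicRelation], target: int, K: int
) -> tuple[Relation | None, bool, str | None]:
    """Merge basic relations gathered from several input tuples.

    The basics of each tuple are combined *within the tuple* first: a table
    whose two prerequisite sides are neither dual-equivalent nor
    contradictory simply contributes nothing (partial evidence, e.g. an
    incompletely detected similarity).  The surviving per-tuple relations
    are then conjoined per side — a similarity contributes its function to
    the target side and its dual to the dual side — and the sides are
    resolved once more.  Returns ``(relation, conflicted, reason)``; a
    conflict is a per-tuple or combined contradiction (constant or
    unsatisfiable) or a combined function needing more than K genes.
    """
    per_tuple: dict[tuple[int, ...], list[BasicRelation]] = {}
    for b in basics:
        per_tuple.setdefault(b.func.inputs, []).append(b)
    left: list[BooleanFunction] = []
    right: list[BooleanFunction] = []
    for tup, tup_basics in sorted(per_tuple.items()):
        rel, status = _combine_status(tup_basics, target)
        if status == "constant":
            return None, True, (
                f"target v'{target}, inputs {tup}: combined function is constant"
            )
        if status == "unsatisfiable":
            return None, True, (
                f"target v'{target}, inputs {tup}: some input forces the "
                "gene both on and off"
            )
        if rel is None:
            continue
        if rel.rtype is RelationType.PREREQ_TARGET:
            left.append(rel.func)
        elif rel.rtype is RelationType.PREREQ_DUAL:
            right.append(rel.func)
        else:  # SIMILAR constrains both the target and its dual
            left.append(rel.func)
            right.append(dual(rel.func))
    f_left = _conjoin(left)
    f_right = _conjoin(right)
    for side, f in (("prerequisite", f_left), ("dual prerequisite", f_right)):
        if f is not None and not f.is_constant() and len(f.inputs) > K:
            return None, True, (
                f"target v'{target}: combined {side} function needs "
                f"{len(f.inputs)} genes, above the indegree bound K={K}"
            )
    rel, status = _combine_sides(f_left, f_right, target)
    if status in ("constant", "unsatisfiable"):
        return None, True, f"target v'{target}: combined relations are {status}"
    return rel, False, None


def combine(basics: Sequence[BasicRelation], target: int) -> Relation | None:
    """AND-combine basic relations into at most one relation for ``target``.

    The LEFT functions are conjoined into one prerequisite-to-target
    function, the RIGHT ones into a prerequisite-to-dual function.  If both
    sides exist they must be duals of each other, giving a similarity
    relation; otherwise the evidence is contradictory and no relation is
    returned.  A side whose conjunction is constant is vacuous and likewise
    yields nothing.
    """
    rel, _ = _combine_status(basics, target)
    return rel


def infer_network_noiseless(
    samples: Sequence[TransitionSample], n: int, K: int = 2
) -> TimeDelayBooleanNetwork:
    """Reconstruct a TDBN from noise-free transitions.

    For every target, the consistent basic relations of *all* canonical
    input tuples are pooled and combined.  Under the completeness condition
    (every K-gene input assignment observed with all of its possible
    outputs) the result is the unique generating network.  A target whose
    combined function needs more than K genes, or whose evidence is
    otherwise contradictory, is flagged and left unregulated — the method
    never guesses.
    """
    X, Y = stack_transitions(samples)
    if X.shape[0] == 0:
        raise InsufficientDataError("no samples")
    relations = []
    for target in range(1, n + 1):
        basics: list[BasicRelation] = []
        for tup in canonical_tuples(n, K):
            tab = build_count_table((X, Y), target, tup)
            basics.extend(consistent_basic_relations(tab))
        rel, conflicted, reason = combine_across_tuples(basics, target, K)
        if conflicted:
            logger.warning("%s; leaving target unregulated", reason)
        if rel is not None:
            relations.append(rel)
    return TimeDelayBooleanNetwork(n=n, relations=tuple(relations), K=K)
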