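"""Noisy-data network reconstruction by maximum compatibility.

Every (input tuple, target, zero-cell hypothesis) combination receives a
p-score.  Small scores flag plausible basic relations, but admitting too
many eventually produces contradictions — e.g. a target whose combined
prerequisite function would need more input genes than the indegree bound
allows.  The *maximum compatibility criterion* sweeps the scores in
ascending order and stops at the first score whose admission creates a
conflict; everything strictly below that threshold is kept and assembled
into the final network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .counts import build_count_table
from .em import em_fit
from .model import (
    Relation,
    TimeDelayBooleanNetwork,
    networks_equivalent,
)
from .noiseless import (
    BasicRelation,
    basic_relations,
    combine_across_tuples,
    infer_network_noiseless,
)
from .simulate import (
    NoiseModel,
    TransitionSample,
    add_noise,
    canonical_tuples,
    generate_transitions,
    stack_transitions,
)

__all__ = [
    "ScoredHypothesis",
    "ThresholdResult",
    "ConflictError",
    "score_all",
    "has_conflict",
    "maximum_compatibility_threshold",
    "assemble",
    "infer_network",
    "identification_probability",
]

logger = logging.getLogger(__name__)

#: Absolute fallback cap on the threshold when no conflict ever occurs:
#: the identifiability bound on the flip probability itself.
SCORE_CAP_DEFAULT = 0.5


class ConflictError(ValueError):
    """Raised when a supposedly conflict-free selection is contradictory."""


@dataclass(frozen=True)
class ScoredHypothesis:
    """One zero-cell hypothesis for one table, with its p-score."""

    target: int
    inputs: tuple[int, ...]
    cell: int
    score: float
    basic: BasicRelation
    em_iterations: int = 0


@dataclass(frozen=True)
class ThresholdResult:
    """Outcome of the maximum-compatibility sweep."""

    threshold: float
    selected: tuple[ScoredHypothesis, ...]
    sweep: tuple[tuple[float, bool], ...]  # (candidate score, conflicted?)


def score_all(
    samples: Sequence[TransitionSample], n: int, K: int = 2, **em_kwargs
) -> list[ScoredHypothesis]:
    """Score every (canonical input tuple, target, hypothesis) combination.

    Returns ``C(n, K) * n * 2**(K+1)`` entries in deterministic order
    (tuples lexicographic, targets ascending, cells ascending).
    """
    X, Y = stack_transitions(samples)
    out: list[ScoredHypothesis] = []
    for tup in canonical_tuples(n, K):
        basics = basic_relations(tup)
        for target in range(1, n + 1):
            tab = build_count_table((X, Y), target, tup)
            for cell in range(2 ** (K + 1)):
                res = em_fit(tab, cell, **em_kwargs)
                out.append(
                    ScoredHypothesis(
                        target, tup, cell, res.p_hat, basics[cell], res.iterations
                    )
                )
    return out


def _targets(selected: Iterable[ScoredHypothesis]) -> dict[int, list[BasicRelation]]:
    grouped: dict[int, list[BasicRelation]] = {}
    for s in selected:
        grouped.setdefault(s.target, []).append(s.basic)
    return grouped


def has_conflict(
    selected: Sequence[ScoredHypothesis], K: int
) -> tuple[bool, str | None]:
    """Check a selection of scored basic relations for contradictions.

    Per target, the selected basics are combined exactly as in the
    noise-free algorithm (within each input tuple, then across tuples).  A
    conflict arises when a combined function collapses to a constant, when
    some input would force a gene both on and off, or when the combined
    prerequisite for a target needs more input genes than the indegree
    bound K allows — the signature of incompatible relations admitted
    together.
    """
    for target, basics in _targets(selected).items():
        _, conflicted, reason = combine_across_tuples(basics, target, K)
        if conflicted:
            return True, reason
    return False, None


def maximum_compatibility_threshold(
    scored: Sequence[ScoredHypothesis],
    K: int,
    cap: float = SCORE_CAP_DEFAULT,
    must_include: Sequence[tuple[int, tuple[int, ...], int]] | None = None,
) -> ThresholdResult:
    """Find the maximum-compatibility threshold by an ascending sweep.

    Distinct score values are admitted all-or-none (ties enter together).
    Every prefix {score <= t} is checked for conflicts; the winning prefix
    is the *largest* conflict-free one — compatibility is not monotone, as
    a contradiction apparent from partial evidence (say, one flank of a
    similarity pattern) can dissolve once the remaining cells of the
    pattern are admitted.  The threshold reported is the next (conflicting)
    score above that prefix, or ``cap`` when the prefix is the whole list,
    and the selection is every hypothesis with score *strictly below* the
    threshold.  In the common monotone case this is simply the smallest
    score whose admission first creates a conflict.

    ``must_include`` optionally lists (target, inputs, cell) keys of
    relations known to be true; the threshold is lower-bounded so that all
    of them are selected even through a conflicted region.
    """
    if not scored:
        raise ValueError("no scored hypotheses to sweep")
    floor = -np.inf
    if must_include:
        keys = {(t, tuple(i), c) for t, i, c in must_include}
        forced = [s.score for s in scored if (s.target, s.inputs, s.cell) in keys]
        if len(forced) != len(keys):
            raise KeyError("must_include entry not found among scored hypotheses")
        floor = max(forced)
    order = sorted(scored, key=lambda s: (s.score, s.inputs, s.target, s.cell))
    unique_scores = sorted({s.score for s in order})
    sweep: list[tuple[float, bool]] = []
    best_idx = -1  # index into unique_scores of the largest feasible prefix
    for i, t in enumerate(unique_scores):
        admitted = [s for s in order if s.score <= t]
        conflicted, why = has_conflict(admitted, K)
        sweep.append((t, conflicted))
        if conflicted:
            logger.debug("prefix at score %.6g conflicts: %s", t, why)
        if not conflicted or t <= floor:
            best_idx = i
    if best_idx + 1 < len(unique_scores):
        threshold = unique_scores[best_idx + 1]
    else:
        threshold = cap
    threshold = min(threshold, cap)
    selected = tuple(s for s in order if s.score < threshold)
    logger.info(
        "maximum compatible threshold %.6g (%d of %d hypotheses selected)",
        threshold, len(selected), len(order),
    )
    return ThresholdResult(threshold, selected, tuple(sweep))


def assemble(
    selected: Sequence[ScoredHypothesis], n: int, K: int = 2
) -> TimeDelayBooleanNetwork:
    """Combine a conflict-free selection into a network.

    Per target the selected basic relations are conjoined exactly as in the
    noise-free algorithm (LEFT side, RIGHT side, dual check for
    similarity).  A selection that still conflicts is a caller error.
    """
    conflicted, why = has_conflict(selected, K)
    if conflicted:
        raise ConflictError(why)
    relations = []
    for target, basics in sorted(_targets(selected).items()):
        rel, _, _ = combine_across_tuples(basics, target, K)
        if rel is not None:
            relations.append(rel)
    return TimeDelayBooleanNetwork(n=n, relations=tuple(relations), K=K)


def infer_network(
    samples: Sequence[TransitionSample],
    n: int,
    K: int = 2,
    cap: float = SCORE_CAP_DEFAULT,
    must_include=None,
    **em_kwargs,
) -> tuple[TimeDelayBooleanNetwork, ThresholdResult]:
    """Full noisy pipeline: score, sweep for the threshold, assemble."""
    scored = score_all(samples, n, K, **em_kwargs)
    res = maximum_compatibility_threshold(scored, K, cap=cap, must_include=must_include)
    net = assemble(res.selected, n, K)
    return net, res


def identification_probability(
    net: TimeDelayBooleanNetwork,
    m: int,
    p: float,
    trials: int,
    seed: int,
    K: int | None = None,
) -> float:
    """Fraction of trials in which the pipeline recovers ``net`` exactly.

    Each trial draws ``m`` uniform transitions (plus flip noise when
    ``p > 0``), runs the noise-free algorithm when ``p == 0`` and the
    p-score pipeline otherwise, and checks equivalence with the generating
    network.  Per-trial seeds are spawned deterministically from ``seed``,
    so runs at different ``m`` are paired.
    """
    if trials < 1:
        raise ValueError("need at least one trial")
    K = net.K if K is None else K
    children = np.random.SeedSequence(seed).spawn(trials)
    hits = 0
    for child in children:
        rng = np.random.default_rng(child)
        samples = generate_transitions(net, m, rng)
        if p > 0:
            samples = add_noise(samples, NoiseModel(p), rng)
            try:
                recovered, _ = infer_network(samples, net.n, K)
            except ValueError:
                continue
        else:
            try:
                recovered = infer_network_noiseless(samples, net.n, K)
            except ValueError:
                continue
        if networks_equivalent(recovered, net):
            hits += 1
    return hits / trials
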