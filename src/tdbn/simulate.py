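"""Sampling transitions from a TDBN and corrupting them with flip noise.

The inference method consumes *independent* state-transition pairs, not
trajectories: each sample draws an input state uniformly from {0,1}^n and
then, gene by gene, an output bit uniformly from that gene's allowed set
(forced bits have a single allowed value; delayed/free bits are on or off
with equal probability).  Observation noise is modelled as independent
symmetric misclassification: every recorded bit — input and output alike —
is flipped with probability p < 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product
from typing import NamedTuple, Sequence

import numpy as np

from .boolean_logic import BooleanFunction, K_MAX_DEFAULT
from .model import (
    Relation,
    RelationType,
    TimeDelayBooleanNetwork,
    eval_function,
    possible_outputs,
)

__all__ = [
    "TransitionSample",
    "NoiseModel",
    "generate_transitions",
    "add_noise",
    "random_network",
    "exhaustive_transitions",
    "stack_transitions",
]


class TransitionSample(NamedTuple):
    """One observed (time t, time t+1) state pair."""

    input: np.ndarray
    output: np.ndarray


@dataclass(frozen=True)
class NoiseModel:
    """Independent symmetric bit-flip noise with probability ``p``.

    ``p`` must lie in [0, 0.5): at p = 1/2 the observed bits carry no
    information and the flip probability is unidentifiable.
    """

    p: float

    def __post_init__(self) -> None:
        if not 0 <= self.p < 0.5:
            raise ValueError(f"misclassification probability {self.p} not in [0, 0.5)")


def stack_transitions(samples: Sequence[TransitionSample]) -> tuple[np.ndarray, np.ndarray]:
    """Stack a sample list into (m, n) input/output 0/1 matrices."""
    if isinstance(samples, tuple) and len(samples) == 2 and isinstance(samples[0], np.ndarray):
        X, Y = samples
        return np.asarray(X, dtype=np.int8), np.asarray(Y, dtype=np.int8)
    if len(samples) == 0:
        return np.zeros((0, 0), dtype=np.int8), np.zeros((0, 0), dtype=np.int8)
    X = np.stack([np.asarray(s.input, dtype=np.int8) for s in samples])
    Y = np.stack([np.asarray(s.output, dtype=np.int8) for s in samples])
    return X, Y


def _to_samples(X: np.ndarray, Y: np.ndarray) -> list[TransitionSample]:
    return [TransitionSample(X[i].copy(), Y[i].copy()) for i in range(X.shape[0])]


def generate_transitions(
    net: TimeDelayBooleanNetwork, m: int, seed: int | np.random.Generator
) -> list[TransitionSample]:
    """Draw ``m`` noise-free transitions from ``net``.

    Inputs are i.i.d. uniform on {0,1}^n; each gene's output bit is drawn
    uniformly from its allowed set, independently across genes (free bits on
    or off with equal probability, forced bits deterministic).
    """
    if m < 0:
        raise ValueError("m must be >= 0")
    rng = np.random.default_rng(seed)
    X = rng.integers(0, 2, size=(m, net.n), dtype=np.int8)
    Y = rng.integers(0, 2, size=(m, net.n), dtype=np.int8)  # free bits
    for i in range(1, net.n + 1):
        rel = net.relation_for(i)
        if rel is None:
            continue
        fx = eval_function(rel.func, X)
        col = Y[:, i - 1]
        if rel.rtype is RelationType.SIMILAR:
            Y[:, i - 1] = fx
        elif rel.rtype is RelationType.PREREQ_TARGET:
            Y[:, i - 1] = np.where(fx == 0, 0, col)
        else:  # PREREQ_DUAL
            Y[:, i - 1] = np.where(fx == 0, 1, col)
    return _to_samples(X, Y)


def add_noise(
    samples: Sequence[TransitionSample],
    noise: NoiseModel | float,
    seed: int | np.random.Generator,
) -> list[TransitionSample]:
    """Flip every input and output bit independently with probability ``p``.

    Returns a new list; the originals are left untouched.
    """
    if not isinstance(noise, NoiseModel):
        noise = NoiseModel(float(noise))
    X, Y = stack_transitions(samples)
    rng = np.random.default_rng(seed)
    if X.size:
        X = X ^ (rng.random(X.shape) < noise.p)
        Y = Y ^ (rng.random(Y.shape) < noise.p)
    return _to_samples(X.astype(np.int8), Y.astype(np.int8))


def random_network(
    n: int,
    K: int,
    seed: int | np.random.Generator,
    relation_prob: float = 1.0,
    k_max: int | None = None,
) -> TimeDelayBooleanNetwork:
    """Sample a random TDBN with indegree bound ``K``.

    Each target independently receives a relation with probability
    ``relation_prob`` (default: every target regulated).  A relation draws
    its indegree uniformly from 1..K, its input genes without replacement,
    its truth table uniformly among non-constant tables, and its type
    uniformly among the three relation types.
    """
    if not n >= K >= 1:
        raise ValueError(f"need n >= K >= 1, got n={n}, K={K}")
    if k_max is None:
        k_max = min(K, K_MAX_DEFAULT)
    rng = np.random.default_rng(seed)
    rtypes = list(RelationType)
    relations = []
    for target in range(1, n + 1):
        if rng.random() >= relation_prob:
            continue
        k = int(rng.integers(1, min(K, k_max) + 1))
        inputs = tuple(sorted(rng.choice(n, size=k, replace=False) + 1))
        while True:  # uniform over non-constant tables
            table = tuple(int(b) for b in rng.integers(0, 2, size=2**k))
            if len(set(table)) > 1:
                break
        rtype = rtypes[int(rng.integers(0, len(rtypes)))]
        relations.append(Relation(BooleanFunction(inputs, table), target, rtype))
    return TimeDelayBooleanNetwork(n=n, relations=tuple(relations), K=K)


def exhaustive_transitions(net: TimeDelayBooleanNetwork) -> list[TransitionSample]:
    """Every input state paired with every one of its possible outputs.

    This is the completeness condition under which noise-free identification
    is unique: all 2^n inputs present, each with its full output set.
    """
    samples = []
    for bits in product((0, 1), repeat=net.n):
        x = np.array(bits, dtype=np.int8)
        for y in sorted(possible_outputs(net, x)):
            samples.append(TransitionSample(x.copy(), np.array(y, dtype=np.int8)))
    return samples


def canonical_tuples(n: int, K: int) -> list[tuple[int, ...]]:
    """All ascending input tuples of size K drawn from genes 1..n."""
    return [tuple(c) for c in combinations(range(1, n + 1), K)]
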