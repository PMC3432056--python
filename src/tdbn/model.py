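"""The time-delay Boolean network (TDBN) and its transition semantics.

A classical Boolean network updates every gene deterministically:
``v'_i = f_i(v)``.  Real regulation is noisier and slower — an activated
rule may only switch its target on at some *later* step.  The TDBN keeps
the Boolean rule but weakens the coupling between rule and target to one of
two pairwise relation types:

* **prerequisite** (``f ≻ v'``): the rule being on at time t is *necessary*
  for the target being on at t+1.  When ``f(v)=0`` the target is forced off;
  when ``f(v)=1`` the target may be on or off (the delay).
* **similarity** (``f ∼ v'``): the deterministic classical update,
  ``v' = f(v)``.

A rule may also be prerequisite to the *dual* (complement) of its target,
``f ≻ ¬v'``: then ``f(v)=0`` forces the target on.  Duals of functions are
never needed as a fourth type because ``¬f ≻ v'`` can always be rewritten
with another plain function, so three relation types are exhaustive.

One step of the network therefore maps an input state to a *set* of
possible output states: the Cartesian product of each gene's allowed
values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np

from .boolean_logic import BooleanFunction, dual, equivalent

__all__ = [
    "RelationType",
    "Relation",
    "TimeDelayBooleanNetwork",
    "possible_outputs_per_gene",
    "possible_outputs",
    "networks_equivalent",
    "eval_function",
    "three_gene_example",
]


class RelationType(str, Enum):
    """How a Boolean rule constrains its target at the next time step."""

    PREREQ_TARGET = "prereq_target"  # f ≻ v'  : f=0 forces v'=0
    PREREQ_DUAL = "prereq_dual"      # f ≻ ¬v' : f=0 forces v'=1
    SIMILAR = "similar"              # f ∼ v'  : v' = f always


@dataclass(frozen=True)
class Relation:
    """One regulatory relation: a Boolean function tied to a target gene."""

    func: BooleanFunction
    target: int
    rtype: RelationType

    def __post_init__(self) -> None:
        object.__setattr__(self, "rtype", RelationType(self.rtype))
        if self.target < 1:
            raise ValueError("target is a 1-based gene index")

    def to_json_dict(self) -> dict:
        return {
            "target": self.target,
            "rtype": self.rtype.value,
            "func": self.func.to_json_dict(),
        }

    @classmethod
    def from_json_dict(cls, d: Mapping) -> "Relation":
        return cls(
            BooleanFunction.from_json_dict(d["func"]),
            int(d["target"]),
            RelationType(d["rtype"]),
        )


@dataclass(frozen=True)
class TimeDelayBooleanNetwork:
    """n genes, an indegree bound K, and at most one relation per target."""

    n: int
    relations: tuple[Relation, ...] = field(default_factory=tuple)
    K: int = 2

    def __post_init__(self) -> None:
        object.__setattr__(self, "relations", tuple(self.relations))
        if self.n < 1:
            raise ValueError("need at least one gene")
        seen = set()
        for rel in self.relations:
            if rel.target in seen:
                raise ValueError(f"two relations for target {rel.target}")
            seen.add(rel.target)
            if not 1 <= rel.target <= self.n:
                raise ValueError(f"target {rel.target} outside 1..{self.n}")
            if any(not 1 <= g <= self.n for g in rel.func.inputs):
                raise ValueError(f"input gene outside 1..{self.n} in {rel}")
            if len(rel.func.inputs) > self.K:
                raise ValueError(
                    f"indegree {len(rel.func.inputs)} exceeds bound K={self.K}"
                )

    def relation_for(self, target: int) -> Relation | None:
        for rel in self.relations:
            if rel.target == target:
                return rel
        return None

    # ------------------------------------------------------------ serializers

    def to_json_dict(self) -> dict:
        return {
            "n": self.n,
            "K": self.K,
            "relations": [r.to_json_dict() for r in self.relations],
        }

    def to_json(self, indent: int | None = 2) -> str:
        return json.dumps(self.to_json_dict(), indent=indent)

    @classmethod
    def from_json_dict(cls, d: Mapping) -> "TimeDelayBooleanNetwork":
        return cls(
            int(d["n"]),
            tuple(Relation.from_json_dict(r) for r in d["relations"]),
            int(d.get("K", 2)),
        )

    @classmethod
    def from_json(cls, s: str) -> "TimeDelayBooleanNetwork":
        return cls.from_json_dict(json.loads(s))

    def to_sif(self) -> str:
        """SIF export: one line per (input gene, relation keyword, target)."""
        keywords = {
            RelationType.PREREQ_TARGET: "prereq",
            RelationType.PREREQ_DUAL: "prereq_dual",
            RelationType.SIMILAR: "similar",
        }
        lines = []
        for rel in self.relations:
            kw = keywords[rel.rtype]
            for g in rel.func.inputs:
                lines.append(f"v{g}\t{kw}\tv{rel.target}")
        return "\n".join(lines) + ("\n" if lines else "")

    def to_dot(self) -> str:
        """DOT export: directed arrows for prerequisite edges, undirected
        (``dir=none``) edges for similarity — the conventional drawing."""
        lines = ["digraph tdbn {"]
        for i in range(1, self.n + 1):
            lines.append(f'  v{i} [label="v{i}"];')
        for rel in self.relations:
            if rel.rtype is RelationType.SIMILAR:
                attr = "dir=none"
            elif rel.rtype is RelationType.PREREQ_DUAL:
                attr = 'label="dual"'
            else:
                attr = ""
            attrs = f" [{attr}]" if attr else ""
            for g in rel.func.inputs:
                lines.append(f"  v{g} -> v{rel.target}{attrs};")
        lines.append("}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------- semantics


def _as_state(x, n: int) -> np.ndarray:
    x = np.asarray(x, dtype=np.int8).ravel()
    if x.shape[0] != n:
        raise ValueError(f"state has length {x.shape[0]}, expected {n}")
    if not np.isin(x, (0, 1)).all():
        raise ValueError("state entries must be 0/1")
    return x


def possible_outputs_per_gene(
    net: TimeDelayBooleanNetwork, x, i: int
) -> frozenset[int]:
    """Allowed next-step values of gene ``i`` given input state ``x``.

    similarity forces ``{f(x)}``; prerequisite-to-target forces ``{0}`` when
    the rule is off and frees the gene (``{0,1}``) when it is on;
    prerequisite-to-dual is the mirror image; an unregulated gene is free.
    """
    if not 1 <= i <= net.n:
        raise IndexError(f"gene index {i} outside 1..{net.n}")
    x = _as_state(x, net.n)
    rel = net.relation_for(i)
    if rel is None:
        return frozenset((0, 1))
    fx = rel.func(x)
    if rel.rtype is RelationType.SIMILAR:
        return frozenset((fx,))
    if rel.rtype is RelationType.PREREQ_TARGET:
        return frozenset((0,)) if fx == 0 else frozenset((0, 1))
    # PREREQ_DUAL: f=0 forces the dual off, i.e. the target on
    return frozenset((1,)) if fx == 0 else frozenset((0, 1))


def possible_outputs(net: TimeDelayBooleanNetwork, x) -> set[tuple[int, ...]]:
    """All next-step states: the product of the per-gene allowed sets."""
    per_gene = [
        sorted(possible_outputs_per_gene(net, x, i)) for i in range(1, net.n + 1)
    ]
    return {tuple(bits) for bits in product(*per_gene)}


def networks_equivalent(
    a: TimeDelayBooleanNetwork, b: TimeDelayBooleanNetwork
) -> bool:
    """Structural equality up to function reduction, target by target."""
    if a.n != b.n:
        return False
    for i in range(1, a.n + 1):
        ra, rb = a.relation_for(i), b.relation_for(i)
        if (ra is None) != (rb is None):
            return False
        if ra is None:
            continue
        if ra.rtype is not rb.rtype or not equivalent(ra.func, rb.func):
            return False
    return True


def eval_function(f: BooleanFunction, X: np.ndarray) -> np.ndarray:
    """Vectorised evaluation of ``f`` on rows of an (m, n) 0/1 state matrix."""
    if f.k == 0:
        return np.full(X.shape[0], f.table[0], dtype=np.int8)
    idx = np.zeros(X.shape[0], dtype=np.int64)
    for g in f.inputs:
        idx = (idx << 1) | X[:, g - 1].astype(np.int64)
    return np.asarray(f.table, dtype=np.int8)[idx]


def three_gene_example() -> TimeDelayBooleanNetwork:
    """The canonical three-gene network used throughout the documentation:
    ``(v1 OR v3) ≻ v'1``, ``(v1 AND v3) ≻ v'2``, ``v2 ∼ v'3``."""
    return TimeDelayBooleanNetwork(
        n=3,
        relations=(
            Relation(BooleanFunction((1, 3), (0, 1, 1, 1)), 1, RelationType.PREREQ_TARGET),
            Relation(BooleanFunction((1, 3), (0, 0, 0, 1)), 2, RelationType.PREREQ_TARGET),
            Relation(BooleanFunction((2,), (0, 1)), 3, RelationType.SIMILAR),
        ),
        K=2,
    )
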