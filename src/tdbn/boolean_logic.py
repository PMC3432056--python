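"""Truth-table algebra for Boolean functions over small ordered gene sets.

A regulatory rule is a Boolean function of at most a few genes (the bounded
indegree assumption standard in Boolean-network inference).  Functions are
stored as explicit truth tables, which keeps the algebra — complementation
("dual"), AND-combination and removal of dummy inputs — exact and trivially
enumerable for the small input counts this model allows.

Conventions
-----------
* Gene indices are 1-based, matching the usual ``v_1 .. v_n`` notation.
* ``inputs`` is an ordered tuple; the *first* listed input is the most
  significant bit of the truth-table index, so for inputs ``(j, h)`` the
  table entries correspond to assignments ``(v_j, v_h)`` = 00, 01, 10, 11
  in that order.
* Constant functions have ``inputs == ()`` and a single-entry table.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Mapping

#: Default cap on the number of inputs a single function may take.  Truth
#: tables have 2**k entries and the search over input tuples is O(n**k), so
#: small k is both a modelling assumption and a tractability requirement.
K_MAX_DEFAULT = 3


@dataclass(frozen=True)
class BooleanFunction:
    """A Boolean function given by an ordered input tuple and a truth table.

    Parameters
    ----------
    inputs
        Ordered tuple of distinct 1-based gene indices (may be empty for a
        constant function).
    table
        Tuple of ``2**len(inputs)`` bits; entry ``a`` is the output for the
        assignment whose bits, first input most significant, encode ``a``.
    """

    inputs: tuple[int, ...]
    table: tuple[int, ...]

    def __post_init__(self) -> None:
        inputs = tuple(int(g) for g in self.inputs)
        table = tuple(int(b) for b in self.table)
        object.__setattr__(self, "inputs", inputs)
        object.__setattr__(self, "table", table)
        if len(set(inputs)) != len(inputs):
            raise ValueError(f"duplicate gene indices in inputs {inputs}")
        if any(g < 1 for g in inputs):
            raise ValueError("gene indices are 1-based and must be >= 1")
        if len(table) != 2 ** len(inputs):
            raise ValueError(
                f"table length {len(table)} != 2**{len(inputs)} for inputs {inputs}"
            )
        if any(b not in (0, 1) for b in table):
            raise ValueError("table entries must be 0 or 1")

    # ------------------------------------------------------------------ eval

    @property
    def k(self) -> int:
        """Number of inputs."""
        return len(self.inputs)

    def value_at(self, bits: Iterable[int]) -> int:
        """Output for the assignment ``bits`` aligned with ``self.inputs``."""
        idx = 0
        n = 0
        for b in bits:
            idx = (idx << 1) | (b & 1)
            n += 1
        if n != self.k:
            raise ValueError(f"expected {self.k} bits, got {n}")
        return self.table[idx]

    def value_under(self, assignment: Mapping[int, int]) -> int:
        """Output under a gene-index -> bit mapping covering all inputs."""
        return self.value_at(assignment[g] for g in self.inputs)

    def __call__(self, state) -> int:
        """Evaluate on a full length-n state vector (gene i at position i-1)."""
        return self.value_at(int(state[g - 1]) for g in self.inputs)

    def is_constant(self) -> bool:
        return len(set(self.table)) == 1

    # ------------------------------------------------------------ serializers

    def to_json_dict(self) -> dict:
        return {"inputs": list(self.inputs), "table": list(self.table)}

    @classmethod
    def from_json_dict(cls, d: Mapping) -> "BooleanFunction":
        return cls(tuple(d["inputs"]), tuple(d["table"]))


def constant(bit: int) -> BooleanFunction:
    """The constant-0 or constant-1 function (no inputs)."""
    return BooleanFunction((), (int(bit),))


def dual(f: BooleanFunction) -> BooleanFunction:
    """Bitwise complement of a function's output (0↔1 on every row)."""
    return BooleanFunction(f.inputs, tuple(1 - b for b in f.table))


def conjunction(f: BooleanFunction, g: BooleanFunction) -> BooleanFunction:
    """AND of two functions, defined over the union of their inputs.

    The result's inputs are the union of the operands' inputs in ascending
    gene order; its value at every assignment of the union is
    ``f(x) AND g(x)``.
    """
    genes = tuple(sorted(set(f.inputs) | set(g.inputs)))
    table = []
    for bits in product((0, 1), repeat=len(genes)):
        assignment = dict(zip(genes, bits))
        table.append(f.value_under(assignment) & g.value_under(assignment))
    return BooleanFunction(genes, tuple(table))


def reduce(f: BooleanFunction) -> BooleanFunction:
    """Canonical form: drop dummy inputs and sort the rest ascending.

    An input is a dummy when flipping it never changes the output.  Constant
    functions reduce to zero inputs.  ``reduce`` is idempotent and the result
    is truth-table-equivalent to ``f`` on the surviving inputs.
    """
    genes = tuple(sorted(f.inputs))
    essential = []
    for g in genes:
        others = [h for h in genes if h != g]
        for bits in product((0, 1), repeat=len(others)):
            a = dict(zip(others, bits))
            a[g] = 0
            v0 = f.value_under(a)
            a[g] = 1
            if f.value_under(a) != v0:
                essential.append(g)
                break
    table = []
    for bits in product((0, 1), repeat=len(essential)):
        a = dict(zip(essential, bits))
        for g in genes:  # dummies: value independent of these
            a.setdefault(g, 0)
        table.append(f.value_under(a))
    return BooleanFunction(tuple(essential), tuple(table))


def equivalent(f: BooleanFunction, g: BooleanFunction) -> bool:
    """True iff the two functions are identical after reduction."""
    fr, gr = reduce(f), reduce(g)
    return fr.inputs == gr.inputs and fr.table == gr.table


def maxterm(inputs: tuple[int, ...], pattern: int) -> BooleanFunction:
    """The OR-of-literals function over ``inputs`` that is 0 only at ``pattern``.

    ``pattern`` encodes one assignment of ``inputs`` (first input most
    significant); the returned function is the disjunction of one literal per
    input, each complementing that input's bit in the pattern.  E.g. for
    inputs ``(j, h)`` and pattern ``01`` the function is ``v_j OR NOT v_h``.
    """
    k = len(inputs)
    if not 0 <= pattern < 2**k:
        raise ValueError(f"pattern {pattern} out of range for {k} inputs")
    table = tuple(0 if a == pattern else 1 for a in range(2**k))
    return BooleanFunction(tuple(inputs), table)
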