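"""Transition count tables: the sufficient statistics of the method.

For one target gene ``v'_i`` and one ordered tuple of input genes
``(v_j, v_h, ...)`` the 2 x 2^k contingency table counts, over all samples,
how often each joint pattern ``(v_j, ..., v'_i)`` occurred.  Cells are
addressed by a single index whose bits are the input bits (first input most
significant) followed by the output bit: for k = 2 the cell ``m_001`` is
input column "00", output row 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .simulate import TransitionSample, stack_transitions

__all__ = [
    "CountTable",
    "build_count_table",
    "positivity_pattern",
    "cell_index",
    "dump_tables_csv",
]


@dataclass(frozen=True)
class CountTable:
    """Counts for one (input tuple, target) combination.

    ``counts`` has length ``2**(k+1)``; ``counts[cell]`` is the number of
    samples matching that joint input/output pattern and the entries sum to
    ``N``, the total sample count.
    """

    target: int
    inputs: tuple[int, ...]
    counts: np.ndarray
    N: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "inputs", tuple(self.inputs))
        k = len(self.inputs)
        if counts.shape != (2 ** (k + 1),):
            raise ValueError(
                f"counts shape {counts.shape} != (2**{k + 1},) for inputs {self.inputs}"
            )
        if (counts < 0).any():
            raise ValueError("negative count")
        if counts.sum() != self.N:
            raise ValueError(f"counts sum {counts.sum()} != N={self.N}")

    @property
    def k(self) -> int:
        return len(self.inputs)


def cell_index(input_bits: Sequence[int], out_bit: int) -> int:
    """Flat cell index: input bits (first most significant) then output bit."""
    idx = 0
    for b in input_bits:
        idx = (idx << 1) | (b & 1)
    return (idx << 1) | (out_bit & 1)


def _counts_from_arrays(
    X: np.ndarray, Y: np.ndarray, target: int, inputs: tuple[int, ...]
) -> np.ndarray:
    k = len(inputs)
    idx = np.zeros(X.shape[0], dtype=np.int64)
    for g in inputs:
        idx = (idx << 1) | X[:, g - 1].astype(np.int64)
    idx = (idx << 1) | Y[:, target - 1].astype(np.int64)
    return np.bincount(idx, minlength=2 ** (k + 1)).astype(np.int64)


def build_count_table(
    samples: Sequence[TransitionSample], target: int, inputs: Sequence[int]
) -> CountTable:
    """Tally the ``2**(k+1)`` joint patterns of ``inputs`` and ``target``."""
    inputs = tuple(int(g) for g in inputs)
    if len(set(inputs)) != len(inputs):
        raise ValueError(f"duplicate input genes in {inputs}")
    X, Y = stack_transitions(samples)
    if X.shape[0] == 0:
        counts = np.zeros(2 ** (len(inputs) + 1), dtype=np.int64)
        return CountTable(target, inputs, counts, 0)
    n = X.shape[1]
    for g in (*inputs, target):
        if not 1 <= g <= n:
            raise IndexError(f"gene index {g} outside 1..{n}")
    counts = _counts_from_arrays(X, Y, target, inputs)
    return CountTable(target, inputs, counts, X.shape[0])


def positivity_pattern(tab: CountTable) -> np.ndarray:
    """Bit mask marking which cells hold a positive count ("+" vs "0")."""
    return (tab.counts > 0).astype(np.int8)


def dump_tables_csv(
    samples: Sequence[TransitionSample], n: int, K: int, path
) -> None:
    """Audit dump: one CSV row per (target, input tuple) count table."""
    import pandas as pd

    from .simulate import canonical_tuples

    X, Y = stack_transitions(samples)
    rows = []
    for tup in canonical_tuples(n, K):
        for target in range(1, n + 1):
            counts = _counts_from_arrays(X, Y, target, tup)
            rows.append(
                {
                    "target": target,
                    "inputs": ",".join(map(str, tup)),
                    **{f"m_{cell:0{K + 1}b}": int(c) for cell, c in enumerate(counts)},
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
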