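"""File formats, expression binarization and run manifests.

Transitions travel as TSV with 2n columns (``v1..vn`` for the time-t
state, ``v1p..vnp`` for the time-t+1 state), one row per sample, header
line included; the reader/writer pair round-trips exactly.  Continuous
expression matrices (genes x time points, log-ratios) arrive as TSV with
the gene identifier in the first column and, optionally, a second header
row labelled ``experiment`` assigning each time-point column to an
experiment, so that transitions never span experiment boundaries.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .simulate import TransitionSample, stack_transitions

__all__ = [
    "ExpressionMatrix",
    "read_transitions_tsv",
    "write_transitions_tsv",
    "read_expression_tsv",
    "drop_incomplete_columns",
    "binarize_log_ratio",
    "binarize_trend",
    "transitions_from_binary",
    "write_run_manifest",
    "setup_logging",
]

logger = logging.getLogger(__name__)


# -------------------------------------------------------------- transitions


def write_transitions_tsv(samples: Sequence[TransitionSample], path) -> None:
    X, Y = stack_transitions(samples)
    if X.shape[0] == 0:
        raise ValueError("refusing to write an empty transition file")
    n = X.shape[1]
    cols = [f"v{i}" for i in range(1, n + 1)] + [f"v{i}p" for i in range(1, n + 1)]
    pd.DataFrame(np.hstack([X, Y]), columns=cols).to_csv(path, sep="\t", index=False)


def read_transitions_tsv(path) -> list[TransitionSample]:
    df = pd.read_csv(path, sep="\t")
    n = df.shape[1] // 2
    if df.shape[1] != 2 * n or n == 0:
        raise ValueError(f"expected 2n columns in {path}, got {df.shape[1]}")
    X = df.iloc[:, :n].to_numpy(dtype=np.int8)
    Y = df.iloc[:, n:].to_numpy(dtype=np.int8)
    if not np.isin(X, (0, 1)).all() or not np.isin(Y, (0, 1)).all():
        raise ValueError(f"non-binary entries in {path}")
    return [TransitionSample(X[i], Y[i]) for i in range(X.shape[0])]


# --------------------------------------------------------------- expression


@dataclass(frozen=True)
class ExpressionMatrix:
    """A genes x time-points real-valued matrix with experiment labels.

    ``data`` is indexed by gene identifier; ``experiments`` assigns each
    column to an experiment (consecutive columns of one experiment are
    consecutive time points).
    """

    data: pd.DataFrame
    experiments: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        exps = self.experiments or tuple(["expt1"] * self.data.shape[1])
        if len(exps) != self.data.shape[1]:
            raise ValueError("one experiment label per column required")
        object.__setattr__(self, "experiments", tuple(str(e) for e in exps))

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(str(g) for g in self.data.index)

    def experiment_slices(self) -> list[slice]:
        """Column slices of the consecutive runs of each experiment."""
        out, start = [], 0
        for j in range(1, len(self.experiments) + 1):
            if j == len(self.experiments) or self.experiments[j] != self.experiments[start]:
                out.append(slice(start, j))
                start = j
        return out


def read_expression_tsv(path, drop_incomplete: bool = False) -> ExpressionMatrix:
    """Read a gene x time TSV; first column gene IDs, optional second
    header row (first cell ``experiment``) giving experiment labels."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        second = fh.readline().rstrip("\n").split("\t")
        experiments: tuple[str, ...] = ()
        skiprows = 1
        if second and second[0].strip().lower() == "experiment":
            experiments = tuple(second[1:])
            skiprows = 2
    df = pd.read_csv(path, sep="\t", skiprows=skiprows, header=None, index_col=0)
    df.columns = header[1:]
    df.index.name = header[0]
    mat = ExpressionMatrix(df, experiments)
    if drop_incomplete:
        mat = drop_incomplete_columns(mat)
    return mat


def drop_incomplete_columns(mat: ExpressionMatrix) -> ExpressionMatrix:
    """Drop every time-point column containing a missing value."""
    keep = ~mat.data.isna().any(axis=0)
    dropped = [c for c, k in zip(mat.data.columns, keep) if not k]
    if dropped:
        logger.info("dropping %d columns with missing values: %s", len(dropped), dropped)
    exps = tuple(e for e, k in zip(mat.experiments, keep) if k)
    return ExpressionMatrix(mat.data.loc[:, keep], exps)


def _check_no_missing(mat: ExpressionMatrix) -> None:
    if mat.data.isna().any().any():
        bad = [
            (str(g), str(c))
            for g, row in mat.data.isna().iterrows()
            for c, isna in row.items()
            if isna
        ]
        raise ValueError(f"missing expression values at (gene, column): {bad}")


def binarize_log_ratio(
    mat: ExpressionMatrix, threshold: float | dict = 0.0
) -> pd.DataFrame:
    """On/off call per entry: 1 where the log-ratio exceeds the threshold,
    else 0 (a value exactly at the threshold counts as off).

    ``threshold`` defaults to 0 (expressed above reference) and may be a
    gene-id -> value mapping when biological background knowledge suggests
    per-gene cutoffs.
    """
    _check_no_missing(mat)
    if isinstance(threshold, dict):
        cut = pd.Series(
            [threshold.get(g, 0.0) for g in mat.data.index], index=mat.data.index
        )
        return mat.data.gt(cut, axis=0).astype(np.int8)
    return (mat.data > threshold).astype(np.int8)


def binarize_trend(mat: ExpressionMatrix) -> tuple[pd.DataFrame, tuple[str, ...]]:
    """On/off call per time step: 1 where the gene increases from t to t+1,
    0 where it decreases or stays exactly constant.

    Returns the (genes x steps) binary matrix together with the experiment
    label of each step column.  Steps never cross experiment boundaries;
    every experiment needs at least two time points.
    """
    _check_no_missing(mat)
    pieces, exps = [], []
    for sl in mat.experiment_slices():
        block = mat.data.iloc[:, sl]
        if block.shape[1] < 2:
            raise ValueError(
                f"experiment {mat.experiments[sl.start]!r} has a single time "
                "point; trends need at least two"
            )
        diff = block.to_numpy()[:, 1:] - block.to_numpy()[:, :-1]
        cols = [f"{a}->{b}" for a, b in zip(block.columns[:-1], block.columns[1:])]
        pieces.append(pd.DataFrame((diff > 0).astype(np.int8), index=mat.data.index, columns=cols))
        exps.extend([mat.experiments[sl.start]] * (block.shape[1] - 1))
    return pd.concat(pieces, axis=1), tuple(exps)


def transitions_from_binary(
    binary: pd.DataFrame, experiments: Sequence[str] | None = None
) -> list[TransitionSample]:
    """One sample per consecutive column pair within each experiment.

    ``binary`` is genes x time points (0/1); rows become the genes
    ``v1..vn`` in row order.  With experiment labels, pairs never span a
    boundary; without, all columns form one time course.
    """
    vals = binary.to_numpy(dtype=np.int8)
    T = vals.shape[1]
    if experiments is None:
        experiments = ["expt1"] * T
    if len(experiments) != T:
        raise ValueError("one experiment label per column required")
    samples = []
    for t in range(T - 1):
        if experiments[t] != experiments[t + 1]:
            continue
        samples.append(TransitionSample(vals[:, t].copy(), vals[:, t + 1].copy()))
    return samples


# ------------------------------------------------------------ run plumbing


def setup_logging(level: int = logging.INFO) -> None:
    """Route package logs to stderr (idempotent)."""
    root = logging.getLogger("tdbn")
    if not root.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        root.addHandler(handler)
    root.setLevel(level)


def write_run_manifest(path, **entries) -> None:
    """Machine-readable record of a run: seeds, K, thresholds, versions."""
    from . import __version__

    manifest = {"tdbn_version": __version__, **entries}
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
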