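"""Influence measures for discrete biomarker subsets.

A subset of discrete predictor variables partitions the samples into cells
(one cell per observed combination of category codes).  Two scalar *influence
measures* score how strongly that partition separates a binary outcome:

* the **I-score**, the sum over cells of the squared deviation of the
  observed case count from its expectation under no association,
  ``sum_j (n1(j) - n_j * pi1)**2``;

* the **multivariate gain ratio (MGR)**, the information gain of the joint
  partition divided by its split information,
  ``(Info(Y) - Info_S(Y)) / SplitInfo(S)``.  For a single variable this is
  Quinlan's classical gain ratio (GR).

Both operate on a :class:`DiscreteMatrix` (an ``n x p`` matrix of small
non-negative integer codes with a binary outcome) through a
:class:`PartitionTable`.  :class:`SubsetScorer` provides the fast array path
used by the search algorithms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import xlogy

__all__ = [
    "DiscreteMatrix",
    "PartitionTable",
    "as_subset",
    "build_partition",
    "i_score",
    "entropy_terms",
    "mgr",
    "gr_ranking",
    "score_subset",
    "SubsetScorer",
    "read_discrete_csv",
    "write_discrete_csv",
]


@dataclass(frozen=True)
class DiscreteMatrix:
    """An ``n x p`` design matrix of integer category codes with binary labels.

    Parameters
    ----------
    values
        Array of shape ``(n, p)`` of non-negative integer codes.
    variable_names
        ``p`` unique labels, one per column.
    labels
        Binary outcome per sample, coded 0/1 (1 = case / diseased).
    """

    values: np.ndarray
    variable_names: tuple
    labels: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values)
        if values.ndim != 2 or values.size == 0:
            raise ValueError("values must be a non-empty 2-D array")
        if not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.equal(np.mod(values, 1), 0)):
                raise ValueError("values must be integer category codes")
            values = values.astype(np.int64)
        if values.min() < 0:
            raise ValueError("category codes must be non-negative")
        labels = np.asarray(self.labels)
        if labels.shape != (values.shape[0],):
            raise ValueError("labels must have one entry per sample")
        if not np.isin(labels, (0, 1)).all():
            raise ValueError("labels must be coded 0/1")
        names = tuple(str(v) for v in self.variable_names)
        if len(names) != values.shape[1]:
            raise ValueError("variable_names must have one entry per column")
        if len(set(names)) != len(names):
            raise ValueError("variable_names must be unique")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", labels.astype(np.int8))
        object.__setattr__(self, "variable_names", names)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @property
    def pi1(self) -> float:
        """Fraction of samples with label 1."""
        return float(self.labels.sum()) / self.n

    def select(self, rows=None, cols=None) -> "DiscreteMatrix":
        """Return a sub-matrix restricted to the given row/column indices."""
        values = self.values
        labels = self.labels
        names = self.variable_names
        if rows is not None:
            rows = np.asarray(rows)
            values = values[rows]
            labels = labels[rows]
        if cols is not None:
            cols = list(cols)
            values = values[:, cols]
            names = tuple(names[c] for c in cols)
        return DiscreteMatrix(values, names, labels)


@dataclass(frozen=True)
class PartitionTable:
    """Occupied cells of the partition induced by a variable subset.

    ``cells`` maps each observed tuple of category codes to
    ``(n_j, n1_j)`` — the cell's sample count and its count of label-1
    samples.  Only occupied cells (``n_j >= 1``) are stored.
    """

    cells: dict
    n: int
    pi1: float

    def __post_init__(self):
        if not self.cells:
            raise ValueError("partition must have at least one occupied cell")
        total = sum(nj for nj, _ in self.cells.values())
        ones = sum(n1 for _, n1 in self.cells.values())
        if total != self.n:
            raise ValueError("cell totals must sum to n")
        if ones != round(self.n * self.pi1):
            raise ValueError("cell case counts must sum to n * pi1")
        for key, (nj, n1) in self.cells.items():
            if not (0 <= n1 <= nj) or nj < 1:
                raise ValueError(f"invalid counts for cell {key}")

    def counts(self):
        """Return ``(n_j, n1_j)`` arrays over occupied cells."""
        nj = np.array([c[0] for c in self.cells.values()], dtype=np.int64)
        n1 = np.array([c[1] for c in self.cells.values()], dtype=np.float64)
        return nj, n1


def as_subset(indices: Iterable[int], p: int) -> tuple:
    """Normalize and validate a variable subset against a matrix width ``p``."""
    idx = tuple(sorted(int(i) for i in indices))
    if not idx:
        raise ValueError("subset must be non-empty")
    if len(set(idx)) != len(idx):
        raise ValueError("subset indices must be distinct")
    if idx[0] < 0 or idx[-1] >= p:
        raise IndexError(f"subset index out of range for p={p}")
    return idx


def build_partition(matrix: DiscreteMatrix, subset: Sequence[int]) -> PartitionTable:
    """Group samples by their code tuple on ``subset`` and tally outcomes."""
    idx = as_subset(subset, matrix.p)
    sub = matrix.values[:, idx]
    keys, inverse = np.unique(sub, axis=0, return_inverse=True)
    nj = np.bincount(inverse)
    n1 = np.bincount(inverse, weights=matrix.labels.astype(float))
    cells = {
        tuple(int(v) for v in keys[j]): (int(nj[j]), int(round(n1[j])))
        for j in range(len(keys))
    }
    return PartitionTable(cells=cells, n=matrix.n, pi1=matrix.pi1)


# ---------------------------------------------------------------------------
# measures on count arrays (shared by the PartitionTable API and the fast path)

def _i_score_from_counts(nj, n1, pi1) -> float:
    return float(np.sum((n1 - nj * pi1) ** 2))


def _entropy_terms_from_counts(nj, n1, n, pi1, base=None):
    info_y = -(xlogy(pi1, pi1) + xlogy(1.0 - pi1, 1.0 - pi1))
    n0 = nj - n1
    # 0*log(0) := 0 throughout (xlogy convention)
    info_cond = -np.sum(xlogy(n1 / n, n1 / nj) + xlogy(n0 / n, n0 / nj))
    split_info = -np.sum(xlogy(nj / n, nj / n))
    scale = 1.0 if base is None else math.log(base)
    return (
        float(info_y) / scale,
        float(info_cond) / scale,
        float(split_info) / scale,
    )


def _mgr_from_counts(nj, n1, n, pi1) -> float:
    info_y, info_cond, split_info = _entropy_terms_from_counts(nj, n1, n, pi1)
    if split_info <= 0.0 or info_y <= 0.0:
        # a subset that does not split the sample, or single-class data,
        # carries no usable information
        return 0.0
    gain = max(info_y - info_cond, 0.0)
    return gain / split_info


def i_score(partition: PartitionTable) -> float:
    """Raw I-score of a partition: ``sum_j (n1(j) - n_j*pi1)**2``."""
    nj, n1 = partition.counts()
    return _i_score_from_counts(nj, n1, partition.pi1)


def entropy_terms(partition: PartitionTable, base=None):
    """Return ``(info_y, info_cond, split_info)`` for a partition.

    Natural logarithms by default; pass ``base=2`` for bits.  ``info_y`` is
    the outcome entropy, ``info_cond`` the outcome entropy conditional on the
    cell, and ``split_info`` the entropy of the cell occupancy itself.
    """
    nj, n1 = partition.counts()
    return _entropy_terms_from_counts(nj, n1, partition.n, partition.pi1, base=base)


def mgr(partition: PartitionTable) -> float:
    """Multivariate gain ratio of a partition.

    ``(info_y - info_cond) / split_info``, with the conventions that a
    partition with a single occupied cell (``split_info == 0``) or
    single-class data scores 0.  The ratio is invariant to the logarithm
    base.  For a one-variable subset this is the classical gain ratio.
    """
    nj, n1 = partition.counts()
    return _mgr_from_counts(nj, n1, partition.n, partition.pi1)


class SubsetScorer:
    """Fast influence-measure evaluation for many subsets of one matrix.

    Encodes each subset's code tuples into a mixed-radix integer and tallies
    cells with ``bincount``, avoiding Python-level grouping.  Used by the
    triple screen and the backward-dropping search, where millions of subset
    evaluations may be needed.
    """

    def __init__(self, matrix: DiscreteMatrix, measure: str = "mgr"):
        if measure not in ("i_score", "mgr"):
            raise ValueError(f"unknown measure {measure!r}")
        self.matrix = matrix
        self.measure = measure
        self._values = matrix.values.astype(np.int64)
        self._labels = matrix.labels.astype(np.float64)
        self._radix = self._values.max(axis=0) + 1
        self._n = matrix.n
        self._pi1 = matrix.pi1

    def cell_counts(self, subset):
        """Return ``(n_j, n1_j)`` arrays over occupied cells of ``subset``."""
        idx = list(subset)
        code = self._values[:, idx[0]]
        span = int(self._radix[idx[0]])
        for i in idx[1:]:
            code = code * self._radix[i] + self._values[:, i]
            span *= int(self._radix[i])
        if span <= max(4 * self._n, 4096):
            nj = np.bincount(code, minlength=span)
            n1 = np.bincount(code, weights=self._labels, minlength=span)
            mask = nj > 0
            return nj[mask], n1[mask]
        _, inverse = np.unique(code, return_inverse=True)
        nj = np.bincount(inverse)
        n1 = np.bincount(inverse, weights=self._labels)
        return nj, n1

    def __call__(self, subset) -> float:
        nj, n1 = self.cell_counts(subset)
        if self.measure == "i_score":
            return _i_score_from_counts(nj, n1, self._pi1)
        return _mgr_from_counts(nj, n1, self._n, self._pi1)


def score_subset(matrix: DiscreteMatrix, subset, measure: str = "mgr") -> float:
    """Influence measure of a single subset (convenience wrapper)."""
    return SubsetScorer(matrix, measure)(as_subset(subset, matrix.p))


def gr_ranking(matrix: DiscreteMatrix):
    """Gain ratio of every single variable, sorted descending.

    Returns a list of ``(variable_name, gr)`` pairs; ties are broken by
    ascending variable index.
    """
    scorer = SubsetScorer(matrix, "mgr")
    scored = [(matrix.variable_names[i], scorer((i,))) for i in range(matrix.p)]
    order = sorted(range(matrix.p), key=lambda i: (-scored[i][1], i))
    return [scored[i] for i in order]


# ---------------------------------------------------------------------------
# delimited-text I/O

def read_discrete_csv(path, label_col: str, sep: str = ",") -> DiscreteMatrix:
    """Read a samples-by-variables delimited table with a binary label column."""
    df = pd.read_csv(path, sep=sep)
    if label_col not in df.columns:
        raise ValueError(f"label column {label_col!r} not found")
    labels = df[label_col].to_numpy()
    uniq = set(np.unique(labels).tolist())
    if not uniq <= {0, 1}:
        raise ValueError("label column must be coded 0/1; run preprocessing first")
    data = df.drop(columns=[label_col])
    return DiscreteMatrix(data.to_numpy(), tuple(data.columns), labels)


def write_discrete_csv(matrix: DiscreteMatrix, path, label_col: str = "label",
                       sep: str = ",") -> None:
    df = pd.DataFrame(matrix.values, columns=list(matrix.variable_names))
    df[label_col] = matrix.labels
    df.to_csv(path, sep=sep, index=False)
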