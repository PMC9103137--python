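"""Backward-dropping search for influential variable subsets.

The backward-dropping algorithm (BDA) starts from a random subset of ``k``
variables and repeatedly removes the variable whose removal raises the
influence measure the most, recording the best subset seen along the way
(the *return set*).  Repeated over ``B`` random starts, this explores the
interaction space without enumerating it.  Two post-filters tidy the B
return sets: overlap filtering keeps only the best-scoring set among any
that share variables, and forward adding rebuilds each survivor variable by
variable to drop false-positive members.

Sizing helpers translate the sample size into a workable initial subset
size (partition cells must stay populated) and the coverage goal into a
repetition count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .measures import DiscreteMatrix, SubsetScorer, as_subset

__all__ = [
    "BDAConfig",
    "ReturnSet",
    "InitialSizeBounds",
    "initial_size_bounds",
    "repetitions",
    "backward_drop",
    "run_bda",
    "filter_overlaps",
    "forward_add",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BDAConfig:
    """Search parameters: initial size k, repetitions B, coverage order z."""

    k: int
    B: int
    z: int = 2
    measure: str = "mgr"
    seed: int = 0

    def __post_init__(self):
        if not (1 <= self.z <= self.k):
            raise ValueError("need 1 <= z <= k")
        if self.B < 1:
            raise ValueError("need B >= 1")
        if self.measure not in ("i_score", "mgr"):
            raise ValueError(f"unknown measure {self.measure!r}")


@dataclass(frozen=True)
class ReturnSet:
    """A subset surviving one backward-dropping run, with its score."""

    variables: tuple
    score: float
    origin: int = -1


@dataclass(frozen=True)
class InitialSizeBounds:
    """Workable initial-subset sizes for a given sample size.

    ``poisson_min_bound_k`` is the largest k for which a random (k-1)-variable
    partition is still expected to receive collisions (n^2 / (2 m_{k-1}) >= 1,
    Poisson approximation); ``adequacy_bound_k`` the largest k that keeps at
    least 4 observations per partition cell on average.  Any k in
    ``recommended_range`` (inclusive) is workable.
    """

    poisson_min_bound_k: int
    adequacy_bound_k: int

    @property
    def recommended_range(self):
        lo, hi = sorted((self.adequacy_bound_k, self.poisson_min_bound_k))
        return (lo, hi)


def initial_size_bounds(n: int, categories_per_variable: int = 2) -> InitialSizeBounds:
    """Compute both initial-size bounds for ``n`` samples (exact integer rule)."""
    c = int(categories_per_variable)
    if n < 1 or c < 2:
        raise ValueError("need n >= 1 and categories_per_variable >= 2")
    k_poisson = 0
    while n * n >= 2 * c ** k_poisson:          # c**(k-1) with k = k_poisson+1
        k_poisson += 1
    k_adequacy = 0
    while n >= 4 * c ** (k_adequacy + 1):
        k_adequacy += 1
    if k_poisson == 0 or k_adequacy == 0:
        log.warning("sample size n=%d too small for a meaningful initial size", n)
    return InitialSizeBounds(k_poisson, k_adequacy)


def repetitions(p: int, k: int, z: int):
    """Repetition count to cover all z-variable interactions in expectation.

    ``B_hat = ceil[(C(p,z)/C(k,z)) * ln C(p,z)]`` (at least 1); twice that is
    an upper bound that covers all key variables.  Returns ``(B_hat, 2*B_hat)``.
    """
    if not (1 <= z <= k <= p):
        raise ValueError("need 1 <= z <= k <= p")
    cpz = math.comb(p, z)
    ckz = math.comb(k, z)
    b_hat = max(1, math.ceil((cpz / ckz) * math.log(cpz)))
    return b_hat, 2 * b_hat


def backward_drop(matrix: DiscreteMatrix, initial_subset, measure: str = "mgr",
                  scorer: SubsetScorer | None = None, origin: int = -1) -> ReturnSet:
    """One backward-dropping run from a given initial subset.

    At each stage every variable is tentatively dropped and the drop giving
    the highest measure is committed (ties: drop the smallest index).  The
    retained pending combinations — the initial subset and every intermediate
    down to a single variable — are compared and the highest-scoring one is
    returned (ties resolved toward the smaller subset).
    """
    if scorer is None:
        scorer = SubsetScorer(matrix, measure)
    current = as_subset(initial_subset, matrix.p)
    pending = [(current, scorer(current))]
    while len(current) > 1:
        best_sub, best_score = None, -math.inf
        for v in current:  # ascending index; strict > keeps the smallest-v drop
            cand = tuple(u for u in current if u != v)
            s = scorer(cand)
            if s > best_score:
                best_sub, best_score = cand, s
        current = best_sub
        pending.append((current, best_score))
    # sizes shrink along `pending`; >= prefers the smaller subset on ties
    best_sub, best_score = pending[0]
    for sub, s in pending[1:]:
        if s >= best_score:
            best_sub, best_score = sub, s
    return ReturnSet(variables=best_sub, score=best_score, origin=origin)


def run_bda(matrix: DiscreteMatrix, config: BDAConfig):
    """B backward-dropping runs from uniform random k-subsets.

    Duplicate return sets (same variable set) are collapsed, keeping the
    highest score and earliest origin.  Fully reproducible under the seed.
    """
    if matrix.p < config.k:
        raise ValueError(f"p={matrix.p} < initial size k={config.k}")
    rng = np.random.default_rng(config.seed)
    scorer = SubsetScorer(matrix, config.measure)
    collapsed: dict[tuple, ReturnSet] = {}
    for b in range(config.B):
        start = tuple(sorted(rng.choice(matrix.p, config.k, replace=False).tolist()))
        rs = backward_drop(matrix, start, scorer=scorer, origin=b)
        prev = collapsed.get(rs.variables)
        if prev is None or rs.score > prev.score:
            if prev is not None:
                rs = ReturnSet(rs.variables, rs.score, prev.origin)
            collapsed[rs.variables] = rs
    log.info("BDA: %d repetitions -> %d distinct return sets",
             config.B, len(collapsed))
    return list(collapsed.values())


def filter_overlaps(return_sets):
    """Greedy overlap filter: keep a set only if disjoint from all better ones.

    Sets are visited in decreasing score order (ties: lexicographically
    smaller variable set first).
    """
    ordered = sorted(return_sets, key=lambda rs: (-rs.score, rs.variables))
    kept, used = [], set()
    for rs in ordered:
        if used.isdisjoint(rs.variables):
            kept.append(rs)
            used.update(rs.variables)
    return kept


def forward_add(matrix: DiscreteMatrix, return_sets, measure: str = "mgr",
                tol: float = 1e-9, scorer: SubsetScorer | None = None):
    """Rebuild each return set variable by variable to remove false positives.

    Starting from the set's best single variable, the remaining members are
    re-admitted greedily in order of marginal contribution; a variable stays
    only if it raises the measure by more than ``tol``.  The best single
    variable is always kept, so results are never empty.
    """
    if scorer is None:
        scorer = SubsetScorer(matrix, measure)
    rebuilt: dict[tuple, ReturnSet] = {}
    for rs in return_sets:
        members = list(rs.variables)
        best_v, best_s = None, -math.inf
        for v in members:  # ascending; strict > keeps the smallest index on ties
            s = scorer((v,))
            if s > best_s:
                best_v, best_s = v, s
        current = (best_v,)
        current_score = best_s
        remaining = [v for v in members if v != best_v]
        while remaining:
            cand_v, cand_s = None, -math.inf
            for v in remaining:
                s = scorer(tuple(sorted(current + (v,))))
                if s > cand_s:
                    cand_v, cand_s = v, s
            if cand_s > current_score + tol:
                current = tuple(sorted(current + (cand_v,)))
                current_score = cand_s
                remaining.remove(cand_v)
            else:
                break
        prev = rebuilt.get(current)
        if prev is None or current_score > prev.score:
            rebuilt[current] = ReturnSet(current, current_score, rs.origin)
    return list(rebuilt.values())
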