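"""Dimension reduction by 3-way interactions (triple screening).

When thousands of variables survive preprocessing, the subset search cannot
start from all of them.  This screen scores every triple of variables with
an influence measure, keeps the top triples up to an elbow in the strided
score sequence (second differences near zero), then keeps the variables that
occur most often in those triples up to an elbow in the retention-frequency
sequence (first differences near zero).
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .measures import DiscreteMatrix, SubsetScorer

__all__ = [
    "ScreenReport",
    "score_all_triples",
    "second_difference_cutoff",
    "first_difference_cutoff",
    "select_top_triples",
    "select_top_variables",
    "screen",
]

log = logging.getLogger(__name__)


@dataclass
class ScreenReport:
    """Everything the triple screen computed, for inspection and serialization."""

    triple_scores: list            # [(triple, score)] descending
    thousandth_scores: list        # strided score sequence
    second_diffs: list
    stride: int
    triple_cutoff: int             # number of retained triples
    retention_freq: list           # [(variable index, count)] descending
    first_diffs: list
    variable_cutoff: int
    retained_variables: list       # variable indices

    def to_dict(self, variable_names=None) -> dict:
        name = (lambda i: variable_names[i]) if variable_names else (lambda i: i)
        return {
            "stride": self.stride,
            "triple_cutoff": self.triple_cutoff,
            "thousandth_scores": list(map(float, self.thousandth_scores)),
            "second_diffs": list(map(float, self.second_diffs)),
            "retention_freq": [[name(v), int(c)] for v, c in self.retention_freq],
            "first_diffs": list(map(float, self.first_diffs)),
            "variable_cutoff": self.variable_cutoff,
            "retained_variables": [name(v) for v in self.retained_variables],
        }


def score_all_triples(matrix: DiscreteMatrix, measure: str = "mgr"):
    """Score all C(p,3) triples, sorted by descending score then index order."""
    if matrix.p < 3:
        raise ValueError("triple screening needs p >= 3")
    scorer = SubsetScorer(matrix, measure)
    scored = [(t, scorer(t)) for t in itertools.combinations(range(matrix.p), 3)]
    scored.sort(key=lambda ts: (-ts[1], ts[0]))
    return scored


def second_difference_cutoff(strided_scores, epsilon_frac: float = 0.01) -> int:
    """First 0-based index where |second difference| is near zero.

    "Near zero" is |d2| <= epsilon_frac * max|d2|.  If the sequence never
    qualifies, the last second-difference index is returned (keep through the
    last strided point, with a warning upstream).
    """
    t = np.asarray(strided_scores, dtype=float)
    d2 = t[:-2] - 2.0 * t[1:-1] + t[2:]
    if len(d2) == 0:
        return 0
    threshold = epsilon_frac * np.abs(d2).max()
    hits = np.flatnonzero(np.abs(d2) <= threshold)
    return int(hits[0]) if len(hits) else int(len(d2) - 1)


def first_difference_cutoff(frequencies, epsilon_frac: float = 0.01):
    """Number of leading entries to keep before the first-difference elbow.

    Returns ``(cutoff, first_diffs)`` where ``cutoff`` is the first 0-based
    index whose |first difference| falls to <= epsilon_frac * max|diff|.
    A cutoff of 0 (flat start) or an all-zero difference sequence means no
    elbow exists; the caller keeps everything.
    """
    f = np.asarray(frequencies, dtype=float)
    d1 = np.diff(f)
    if len(d1) == 0 or np.abs(d1).max() == 0:
        return 0, d1
    threshold = epsilon_frac * np.abs(d1).max()
    hits = np.flatnonzero(np.abs(d1) <= threshold)
    cutoff = int(hits[0]) if len(hits) else 0
    return cutoff, d1


def select_top_triples(scored_triples, stride: int = 1000,
                       epsilon_frac: float = 0.01):
    """Keep the top triples up to the second-difference elbow.

    Scores are sampled at ranks ``stride, 2*stride, ...``; the cutoff is the
    first strided index whose second difference is near zero, and the top
    ``(index + 1) * stride`` triples are retained.  When fewer than three
    strided points exist the stride shrinks to ``max(1, n_triples // 10)``;
    if that still leaves fewer than three points, all triples are kept.

    Returns ``(retained_triples, diagnostics)``.
    """
    m = len(scored_triples)
    scores = np.array([s for _, s in scored_triples], dtype=float)
    if m // stride < 3:
        new_stride = max(1, m // 10)
        if new_stride != stride:
            log.info("stride shrunk from %d to %d for %d triples",
                     stride, new_stride, m)
        stride = new_stride
    strided = scores[stride - 1::stride]
    if len(strided) < 3:
        log.warning("fewer than 3 strided points; keeping all %d triples", m)
        return list(scored_triples), {
            "stride": stride, "thousandth_scores": strided.tolist(),
            "second_diffs": [], "triple_cutoff": m,
        }
    cut_idx = second_difference_cutoff(strided, epsilon_frac)
    n_keep = min((cut_idx + 1) * stride, m)
    d2 = strided[:-2] - 2.0 * strided[1:-1] + strided[2:]
    diag = {
        "stride": stride,
        "thousandth_scores": strided.tolist(),
        "second_diffs": d2.tolist(),
        "triple_cutoff": n_keep,
    }
    return list(scored_triples[:n_keep]), diag


def select_top_variables(retained_triples, epsilon_frac: float = 0.01):
    """Keep high-retention-frequency variables up to the first-difference elbow.

    Variables are ranked by how often they occur in the retained triples;
    the keep count is the first index where the frequency drop flattens.
    Degenerate sequences (all frequencies equal, or a flat start) keep every
    occurring variable, with a warning.

    Returns ``(retained_variable_indices, diagnostics)``.
    """
    if not retained_triples:
        raise ValueError("no retained triples")
    counts = Counter()
    for entry in retained_triples:
        triple = entry[0] if isinstance(entry, tuple) and len(entry) == 2 else entry
        counts.update(triple)
    ranked = sorted(counts.items(), key=lambda vc: (-vc[1], vc[0]))
    freqs = [c for _, c in ranked]
    cutoff, d1 = first_difference_cutoff(freqs, epsilon_frac)
    if cutoff < 1:
        log.warning("no elbow in retention frequencies; keeping all %d variables",
                    len(ranked))
        cutoff = len(ranked)
    kept = [v for v, _ in ranked[:cutoff]]
    diag = {
        "retention_freq": ranked,
        "first_diffs": d1.tolist(),
        "variable_cutoff": cutoff,
    }
    return kept, diag


def screen(matrix: DiscreteMatrix, measure: str = "mgr", stride: int = 1000,
           epsilon_frac: float = 0.01) -> ScreenReport:
    """Run the full triple screen and assemble a :class:`ScreenReport`."""
    scored = score_all_triples(matrix, measure)
    retained, tdiag = select_top_triples(scored, stride, epsilon_frac)
    kept_vars, vdiag = select_top_variables(retained, epsilon_frac)
    log.info("triple screen: %d triples -> %d retained -> %d variables",
             len(scored), len(retained), len(kept_vars))
    return ScreenReport(
        triple_scores=scored,
        thousandth_scores=tdiag["thousandth_scores"],
        second_diffs=tdiag["second_diffs"],
        stride=tdiag["stride"],
        triple_cutoff=tdiag["triple_cutoff"],
        retention_freq=vdiag["retention_freq"],
        first_diffs=vdiag["first_diffs"],
        variable_cutoff=vdiag["variable_cutoff"],
        retained_variables=kept_vars,
    )
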