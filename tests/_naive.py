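"""Independent naive oracles: direct double-loop evaluation of the measure
formulas, kept deliberately separate from the package's array implementation."""

import math


def naive_cells(values, labels, subset):
    """Group samples by their code tuple on the subset, pure Python."""
    cells = {}
    for i in range(len(values)):
        key = tuple(int(values[i][j]) for j in subset)
        nj, n1 = cells.get(key, (0, 0))
        cells[key] = (nj + 1, n1 + int(labels[i]))
    return cells


def naive_i_score(values, labels, subset):
    n = len(values)
    pi1 = sum(int(v) for v in labels) / n
    total = 0.0
    for nj, n1 in naive_cells(values, labels, subset).values():
        total += (n1 - nj * pi1) ** 2
    return total


def naive_mgr(values, labels, subset):
    n = len(values)
    pi1 = sum(int(v) for v in labels) / n

    def plogp(p):
        return p * math.log(p) if p > 0 else 0.0

    info_y = -(plogp(pi1) + plogp(1 - pi1))
    info_cond = 0.0
    split_info = 0.0
    for nj, n1 in naive_cells(values, labels, subset).values():
        n0 = nj - n1
        if n1 > 0:
            info_cond -= (n1 / n) * math.log(n1 / nj)
        if n0 > 0:
            info_cond -= (n0 / n) * math.log(n0 / nj)
        split_info -= plogp(nj / n)
    if split_info <= 0 or info_y <= 0:
        return 0.0
    return (info_y - info_cond) / split_info
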