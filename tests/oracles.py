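"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's dynamic programs: DTW and Fréchet
are evaluated by exhaustive enumeration of all monotone paths/couplings,
and MIC by direct enumeration of every admissible grid with mutual
information computed straight from the contingency counts.
"""

import itertools
import math

import numpy as np


def monotone_paths(n: int, m: int):
    """All monotone paths from (0, 0) to (n-1, m-1) with unit steps
    right / down / diagonal."""
    def extend(path):
        i, j = path[-1]
        if i == n - 1 and j == m - 1:
            yield path
            return
        for di, dj in ((1, 0), (0, 1), (1, 1)):
            ii, jj = i + di, j + dj
            if ii < n and jj < m:
                yield from extend(path + [(ii, jj)])
    yield from extend([(0, 0)])


def dtw_brute(a, b) -> float:
    best = math.inf
    for path in monotone_paths(len(a), len(b)):
        cost = sum(abs(a[i] - b[j]) for i, j in path)
        best = min(best, cost)
    return best


def frechet_brute(a, b) -> float:
    best = math.inf
    for path in monotone_paths(len(a), len(b)):
        leash = max(abs(a[i] - b[j]) for i, j in path)
        best = min(best, leash)
    return best


def dtw_and_frechet_brute(a, b) -> tuple[float, float]:
    """Both distances from a single path enumeration."""
    best_sum = math.inf
    best_max = math.inf
    for path in monotone_paths(len(a), len(b)):
        costs = [abs(a[i] - b[j]) for i, j in path]
        best_sum = min(best_sum, sum(costs))
        best_max = min(best_max, max(costs))
    return best_sum, best_max


def _grid_mi(row_block, col_block, r, c) -> float:
    cnt = np.zeros((r, c))
    np.add.at(cnt, (row_block, col_block), 1)
    n = cnt.sum()
    p = cnt / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (px * py))
    return float(np.nansum(terms))


def mic_brute(x, y, alpha: float = 0.6) -> float:
    """MIC by exhaustive search over all grids with rows*cols < n**alpha."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    B = n ** alpha
    xr = np.argsort(np.argsort(x, kind="stable"), kind="stable")
    yr = np.argsort(np.argsort(y, kind="stable"), kind="stable")
    best = 0.0
    r = 2
    while r * 2 < B:
        c = 2
        while r * c < B:
            for row_cuts in itertools.combinations(range(1, n), r - 1):
                rbl = np.digitize(yr, row_cuts)
                for col_cuts in itertools.combinations(range(1, n), c - 1):
                    cbl = np.digitize(xr, col_cuts)
                    val = _grid_mi(rbl, cbl, r, c) / math.log2(min(r, c))
                    if val > best:
                        best = val
            c += 1
        r += 1
    return best
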