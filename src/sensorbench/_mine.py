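"""Maximal Information Coefficient via the MINE characteristic matrix.

The MIC of a sample is the maximum, over axis-aligned grids with
``rows * cols < B(n) = n**alpha``, of the grid's mutual information
normalised by ``log2(min(rows, cols))``.  For a fixed assignment of points
to rows, the optimal column partition can be found exactly by dynamic
programming over *clump* boundaries (maximal runs of x-consecutive points
sharing a row; an optimal partition never cuts inside a clump).  What
remains is the choice of row partition:

* small samples (``n <= exact_n``): every row partition is enumerated, so
  the returned value is exactly the defined MIC;
* larger samples: the classic approximation — rows are mass-equipartitioned
  and clumps are capped at ``c * cols`` superclumps — run in both
  orientations, taking the element-wise maximum of the two characteristic
  matrices.

The DP maximises ``sum_j phi_j`` with ``phi(col) = -m log m + sum_q m_q log
m_q`` (``m`` points in the column, ``m_q`` of them in row ``q``), which
equals ``n * (H(cols) - H(cols, rows))``; adding ``H(rows)`` gives the
mutual information of the grid.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from numba import njit

LN2 = math.log(2.0)


@njit(cache=False)
def _equipartition(y_sorted: np.ndarray, k: int) -> np.ndarray:
    """Assign each position of a y-sorted sample to one of k rows.

    Greedy mass equipartition that never splits runs of tied y values.
    """
    n = y_sorted.shape[0]
    rows = np.zeros(n, dtype=np.int64)
    cur = 0
    share = 0.0
    desired = n / k
    i = 0
    while i < n:
        j = i
        while j < n and y_sorted[j] == y_sorted[i]:
            j += 1
        run = float(j - i)
        if share > 0.0 and abs(share + run - desired) >= abs(share - desired) and cur < k - 1:
            cur += 1
            share = 0.0
            remaining_rows = k - cur
            desired = (n - i) / remaining_rows
        for p in range(i, j):
            rows[p] = cur
        share += run
        i = j
    return rows


@njit(cache=False)
def _clump_bounds(xs: np.ndarray, rx: np.ndarray) -> tuple[np.ndarray, int]:
    """Clump boundaries over the x-sorted sample.

    Runs of identical x form indivisible groups; adjacent groups merge into
    one clump while all their points lie in one common row.
    """
    n = xs.shape[0]
    bounds = np.empty(n + 1, dtype=np.int64)
    bounds[0] = 0
    m = 0
    i = 0
    prev_uniform_row = -2  # row of previous clump if uniform, else -1
    while i < n:
        j = i
        uniform = True
        row0 = rx[i]
        while j < n and xs[j] == xs[i]:
            if rx[j] != row0:
                uniform = False
            j += 1
        if i > 0:
            if not (uniform and prev_uniform_row == row0):
                m += 1
                bounds[m] = i
        prev_uniform_row = row0 if uniform else -1
        i = j
    m += 1
    bounds[m] = n
    return bounds[: m + 1], m


@njit(cache=False)
def _superclumps(bounds: np.ndarray, m: int, k_hat: int) -> tuple[np.ndarray, int]:
    """Coalesce clumps down to at most k_hat superclumps (mass-balanced)."""
    n = bounds[m]
    out = np.empty(k_hat + 1, dtype=np.int64)
    out[0] = 0
    cur = 0
    share = 0.0
    desired = n / k_hat
    for c in range(m):
        run = float(bounds[c + 1] - bounds[c])
        if share > 0.0 and abs(share + run - desired) >= abs(share - desired) and cur < k_hat - 1:
            cur += 1
            out[cur] = bounds[c]
            share = 0.0
            desired = (n - bounds[c]) / (k_hat - cur)
        share += run
    out[cur + 1] = n
    return out[: cur + 2], cur + 1


@njit(cache=False)
def _cum_counts(rx: np.ndarray, bounds: np.ndarray, m: int, r: int) -> np.ndarray:
    cum = np.zeros((m + 1, r), dtype=np.float64)
    for c in range(m):
        for q in range(r):
            cum[c + 1, q] = cum[c, q]
        for p in range(bounds[c], bounds[c + 1]):
            cum[c + 1, rx[p]] += 1.0
    return cum


@njit(cache=False)
def _dp_best_phi(bounds: np.ndarray, cum: np.ndarray, m: int, max_cols: int) -> np.ndarray:
    """Max of sum_j phi_j over partitions into at most l columns, l=1..max_cols."""
    r = cum.shape[1]
    # phi(s, t) for 0 <= s < t <= m
    PH = np.full((m + 1, m + 1), -np.inf)
    for s in range(m + 1):
        for t in range(s + 1, m + 1):
            mass = float(bounds[t] - bounds[s])
            val = -mass * math.log(mass)
            for q in range(r):
                mq = cum[t, q] - cum[s, q]
                if mq > 0.0:
                    val += mq * math.log(mq)
            PH[s, t] = val
    L = min(max_cols, m)
    F = np.full((m + 1, L + 1), -np.inf)
    for t in range(1, m + 1):
        F[t, 1] = PH[0, t]
    for l in range(2, L + 1):
        for t in range(l, m + 1):
            best = -np.inf
            for s in range(l - 1, t):
                cand = F[s, l - 1] + PH[s, t]
                if cand > best:
                    best = cand
            F[t, l] = best
    out = np.full(max_cols + 1, -np.inf)
    best_so_far = -np.inf
    for l in range(1, max_cols + 1):
        if l <= L and F[m, l] > best_so_far:
            best_so_far = F[m, l]
        out[l] = best_so_far  # "at most l columns" is monotone in l
    return out


def _entropy_rows(cum_last: np.ndarray, n: int) -> float:
    h = 0.0
    for q in cum_last:
        if q > 0:
            h -= (q / n) * math.log(q / n)
    return h


def _mi_for_rows(x_order_rows: np.ndarray, xs: np.ndarray, max_cols: int,
                 k_hat: int | None) -> tuple[np.ndarray, float]:
    """Best mutual information (nats) for each column count, given row labels
    of the x-sorted sample."""
    n = xs.shape[0]
    r = int(x_order_rows.max()) + 1
    bounds, m = _clump_bounds(xs, x_order_rows)
    if k_hat is not None and m > k_hat:
        bounds, m = _superclumps(bounds, m, k_hat)
    cum = _cum_counts(x_order_rows, bounds, m, r)
    best_phi = _dp_best_phi(bounds, cum, m, max_cols)
    hq = _entropy_rows(cum[m], n)
    return best_phi, hq


def _char_matrix_half(x: np.ndarray, y: np.ndarray, alpha: float, c: float) -> dict:
    """Approximate characteristic matrix: rows equipartitioned on y, columns
    optimised on x.  Keys are (rows, cols); values mutual information in bits."""
    n = x.shape[0]
    B = n ** alpha
    xo = np.argsort(x, kind="stable")
    yo = np.argsort(y, kind="stable")
    xs = x[xo]
    M: dict[tuple[int, int], float] = {}
    r = 2
    while r * 2 < B:
        max_cols = int((B - 1e-9) // r)
        rows = np.empty(n, dtype=np.int64)
        rows[yo] = _equipartition(y[yo], r)
        rx = rows[xo]
        k_hat = max(2, int(c * max_cols))
        best_phi, hq = _mi_for_rows(rx, xs, max_cols, k_hat)
        for l in range(2, max_cols + 1):
            if best_phi[l] > -np.inf:
                M[(r, l)] = (hq + best_phi[l] / n) / LN2
        r += 1
    return M


def _char_matrix_exact(x: np.ndarray, y: np.ndarray, alpha: float) -> dict:
    """Exact characteristic matrix by enumerating every row partition."""
    n = x.shape[0]
    B = n ** alpha
    xo = np.argsort(x, kind="stable")
    yo = np.argsort(y, kind="stable")
    xs = x[xo]
    y_sorted = y[yo]
    # admissible cut positions: between distinct consecutive y values
    cut_pos = [p for p in range(1, n) if y_sorted[p] != y_sorted[p - 1]]
    pos_of_point = np.empty(n, dtype=np.int64)
    pos_of_point[yo] = np.arange(n)
    M: dict[tuple[int, int], float] = {}
    r = 2
    while r * 2 < B:
        max_cols = int((B - 1e-9) // r)
        for comb in itertools.combinations(cut_pos, r - 1):
            rows = np.digitize(pos_of_point, np.asarray(comb)).astype(np.int64)
            rx = rows[xo]
            best_phi, hq = _mi_for_rows(rx, xs, max_cols, None)
            for l in range(2, max_cols + 1):
                if best_phi[l] > -np.inf:
                    mi = (hq + best_phi[l] / n) / LN2
                    key = (r, l)
                    if mi > M.get(key, -np.inf):
                        M[key] = mi
        r += 1
    return M


def mic_score(x: np.ndarray, y: np.ndarray, alpha: float = 0.6, c: float = 15.0,
              exact_n: int = 40) -> float:
    """MIC of a paired sample (symmetric in x and y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    if n != y.shape[0]:
        raise ValueError("x and y must have equal length")
    if n ** alpha <= 4:
        raise ValueError("sample too small for any admissible 2x2 grid")
    if n <= exact_n:
        M = _char_matrix_exact(x, y, alpha)
        best = 0.0
        for (r, l), mi in M.items():
            best = max(best, mi / math.log2(min(r, l)))
        return float(min(max(best, 0.0), 1.0))
    M1 = _char_matrix_half(x, y, alpha, c)
    M2 = _char_matrix_half(y, x, alpha, c)
    best = 0.0
    for key in set(M1) | set(M2):
        r, l = key
        mi = max(M1.get((r, l), 0.0), M2.get((l, r), 0.0))
        best = max(best, mi / math.log2(min(r, l)))
    return float(min(max(best, 0.0), 1.0))
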