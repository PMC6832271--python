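"""Similarity battery: DTW distance, global discrete Fréchet distance and a
moving-window local Fréchet profile.

Both measures operate on the rescaled-to-[0, 1] series and use the absolute
value difference as the point cost, so they share a cost scale:

* DTW accumulates the summed cost along the cheapest monotone warping path
  (steps down, right, diagonal; endpoints anchored) — identical series have
  distance zero, and the value grows with series length since no path-length
  normalisation is applied.
* The discrete Fréchet distance is the min over monotone couplings of the
  maximum point cost (the shortest leash that lets two walkers traverse both
  curves without backing up).

Both dynamic programs are evaluated along anti-diagonals so the inner loops
are vectorised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .signal_prep import ParameterSeries

logger = logging.getLogger(__name__)


class SimilarityError(ValueError):
    pass


@dataclass
class SimilarityResult:
    """Full similarity battery for one channel pair."""

    dtw: float
    frechet_global: float
    frechet_local_starts: np.ndarray  # window start times, s
    frechet_local: np.ndarray  # distance per window
    window: float  # s


def _values(x) -> np.ndarray:
    v = np.asarray(x.v if isinstance(x, ParameterSeries) else x, dtype=float)
    if isinstance(x, ParameterSeries) and x.scale != "rescaled01":
        logger.debug("similarity metric on non-rescaled series %s", x.name.render())
    if v.size == 0:
        raise SimilarityError("empty series")
    if not np.all(np.isfinite(v)):
        raise SimilarityError("series must be gap-free")
    return v


def _wavefront(a: np.ndarray, b: np.ndarray, kind: str) -> float:
    """Anti-diagonal sweep of the DTW ('sum') or Fréchet ('max') recurrence."""
    n, m = a.size, b.size
    inf = np.inf
    # padded diagonals indexed by i (position in a); entry [i+1] holds D[i, d-i]
    prev2 = np.full(n + 1, inf)
    prev1 = np.full(n + 1, inf)
    for d in range(n + m - 1):
        i_lo = max(0, d - m + 1)
        i_hi = min(n - 1, d)
        idx = np.arange(i_lo, i_hi + 1)
        cost = np.abs(a[idx] - b[d - idx])
        cur = np.full(n + 1, inf)
        if d == 0:
            cur[1] = cost[0]
        else:
            m1 = prev1[idx + 1]  # (i, j-1)
            m2 = prev1[idx]      # (i-1, j)
            m3 = prev2[idx]      # (i-1, j-1)
            best = np.minimum(np.minimum(m1, m2), m3)
            if kind == "sum":
                vals = cost + best
            else:
                vals = np.maximum(cost, best)
            if i_lo == 0:  # (0, d) has only the (0, d-1) predecessor
                if kind == "sum":
                    vals[0] = cost[0] + prev1[1]
                else:
                    vals[0] = max(cost[0], prev1[1])
            cur[idx + 1] = vals
        prev2, prev1 = prev1, cur
    return float(prev1[n])


def dtw_distance(x, y) -> float:
    """DTW distance with |a - b| local cost and no warping-band constraint."""
    a, b = _values(x), _values(y)
    if a.size < 2 or b.size < 2:
        raise SimilarityError("DTW needs series of length >= 2")
    return _wavefront(a, b, "sum")


def frechet_global(x, y) -> float:
    """Discrete Fréchet distance (coupling DP) on the value sequences.

    The series share a grid, so the leash length is measured on the values
    alone (|a - b|); the time coordinate adds nothing at coupled indices of
    a common normalised time axis.
    """
    a, b = _values(x), _values(y)
    if a.size < 2 or b.size < 2:
        raise SimilarityError("Fréchet needs series of length >= 2")
    return _wavefront(a, b, "max")


def frechet_local(x, y, window: float = 60.0, step: float = 10.0) -> tuple[np.ndarray, np.ndarray]:
    """Global Fréchet distance on each aligned moving sub-window.

    ``window`` and ``step`` are in seconds; output is indexed by window start
    time.  Requires two ParameterSeries on the same grid spanning at least
    one window.
    """
    if not (isinstance(x, ParameterSeries) and isinstance(y, ParameterSeries)):
        raise SimilarityError("frechet_local needs ParameterSeries inputs")
    if x.t.size != y.t.size or not np.array_equal(x.t, y.t):
        raise SimilarityError("series must share the grid")
    res_s = x.resolution_ms / 1000.0
    span = (x.t[-1] - x.t[0]) / 1000.0
    if window > span:
        raise SimilarityError(f"window {window}s exceeds series span {span:.1f}s")
    w = int(round(window / res_s))
    s = max(1, int(round(step / res_s)))
    starts = []
    dists = []
    for i0 in range(0, x.t.size - w + 1, s):
        starts.append((x.t[i0] - x.t[0]) / 1000.0)
        dists.append(_wavefront(x.v[i0:i0 + w], y.v[i0:i0 + w], "max"))
    return np.asarray(starts), np.asarray(dists)


def similarity_battery(x: ParameterSeries, y: ParameterSeries,
                       window: float = 60.0, step: float = 10.0) -> SimilarityResult:
    """DTW + global and local Fréchet for one rescaled channel pair."""
    starts, local = frechet_local(x, y, window=window, step=step)
    return SimilarityResult(
        dtw=dtw_distance(x, y),
        frechet_global=frechet_global(x, y),
        frechet_local_starts=starts,
        frechet_local=local,
        window=window,
    )
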