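"""Gap interpolation, smoothing, rescaling and band filtering of channels.

A :class:`ParameterSeries` is one named channel on a regular grid.  Channel
names follow the study's grammar: direct measurements render as
``"<parameter>: <platform> [filt.] [(mv. avg.)]"`` (e.g. ``"GSR: VP (mv.
avg.)"``) and ECG-derived ones as ``"<parameter>: from ECG <platform> [(mv.
avg.)]"`` (e.g. ``"IBI: from ECG BH"``).

Four transforms are provided:

* :func:`spline_fill` — natural cubic spline through the observed samples to
  fill interior gaps left by grid alignment (splines keep oscillation low
  compared to polynomial fits through the same support).
* :func:`moving_average` — +/- 5 s moving mean to suppress high local
  variation; the window is time-defined and truncated at the series edges.
* :func:`minmax_rescale` — map min..max to 0..1 for the similarity battery
  (the correlation battery always consumes the original scale).
* :func:`butterworth_bandfilter` — first-order 0.05 Hz high-pass plus
  first-order 0.5 Hz low-pass, applied zero-phase.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

logger = logging.getLogger(__name__)

DIRECT_PARAMETERS = ("HR", "IBI", "ECG", "GSR")
DERIVED_PARAMETERS = ("HR", "IBI", "GSR", "VLF", "LF", "HF")
ALL_PARAMETERS = ("HR", "IBI", "ECG", "GSR", "VLF", "LF", "HF")


class PrepError(ValueError):
    """Raised when a series does not meet a transform's preconditions."""


@dataclass(frozen=True)
class ChannelName:
    """Structured channel name under the study's naming grammar."""

    parameter: str
    platform: str
    derived_from: str = "none"  # "none" or "ECG"
    filtered: bool = False
    mvavg: bool = False

    def __post_init__(self) -> None:
        if self.parameter not in ALL_PARAMETERS:
            raise ValueError(f"unknown parameter {self.parameter!r}")
        if self.platform not in ("VP", "BH", "E4"):
            raise ValueError(f"unknown platform {self.platform!r}")
        if self.derived_from not in ("none", "ECG"):
            raise ValueError(f"derived_from must be 'none' or 'ECG'")
        if self.parameter in ("VLF", "LF", "HF") and self.derived_from == "none":
            raise ValueError(f"{self.parameter} exists only as an ECG-derived channel")

    def render(self) -> str:
        if self.derived_from == "ECG":
            s = f"{self.parameter}: from ECG {self.platform}"
        else:
            s = f"{self.parameter}: {self.platform}"
        if self.filtered:
            s += " filt."
        if self.mvavg:
            s += " (mv. avg.)"
        return s

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()

    @classmethod
    def parse(cls, text: str) -> "ChannelName":
        """Parse a rendered name; the colon after the parameter is optional."""
        pat = (
            r"^\s*(?P<param>[A-Z]+):?\s+(?:from\s+(?P<src>ECG)\s+)?"
            r"(?P<plat>VP|BH|E4)(?P<filt>\s+filt\.)?(?P<mv>\s+\(mv\.\s*avg\.?\))?\s*$"
        )
        m = re.match(pat, text)
        if not m:
            raise ValueError(f"cannot parse channel name {text!r}")
        return cls(
            parameter=m.group("param"),
            platform=m.group("plat"),
            derived_from=m.group("src") or "none",
            filtered=bool(m.group("filt")),
            mvavg=bool(m.group("mv")),
        )


@dataclass
class ParameterSeries:
    """One named channel on a regular millisecond grid.

    Missing cells are NaN; ``scale`` records whether the values are in the
    parameter's original unit or rescaled to [0, 1]; ``provenance`` lists the
    transforms applied, in order.
    """

    name: ChannelName
    t: np.ndarray  # ms, regular
    v: np.ndarray
    scale: str = "original"  # "original" | "rescaled01"
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.size != self.v.size:
            raise ValueError("t and v must have equal length")
        if self.t.size >= 2:
            steps = np.diff(self.t)
            if not np.allclose(steps, steps[0]):
                raise ValueError("grid must be regular")
        if self.scale not in ("original", "rescaled01"):
            raise ValueError(f"unknown scale {self.scale!r}")

    @property
    def resolution_ms(self) -> float:
        if self.t.size < 2:
            raise ValueError("resolution undefined for series of length < 2")
        return float(self.t[1] - self.t[0])

    @property
    def rate_hz(self) -> float:
        return 1000.0 / self.resolution_ms

    def __len__(self) -> int:
        return int(self.t.size)

    def copy(self) -> "ParameterSeries":
        return ParameterSeries(self.name, self.t.copy(), self.v.copy(),
                               self.scale, list(self.provenance))


def spline_fill(s: ParameterSeries) -> ParameterSeries:
    """Fill interior missing cells with a natural cubic spline.

    Observed samples are kept bit-identical; leading/trailing missing cells
    are dropped so the series is trimmed to its observed span.
    """
    mask = np.isfinite(s.v)
    n_obs = int(mask.sum())
    if n_obs == 0:
        raise PrepError(f"{s.name.render()}: all-missing channel")
    if n_obs < 4:
        raise PrepError(f"{s.name.render()}: spline_fill needs >= 4 support points, got {n_obs}")
    first, last = np.flatnonzero(mask)[[0, -1]]
    t = s.t[first:last + 1]
    v = s.v[first:last + 1].copy()
    inner = np.isfinite(v)
    if not inner.all():
        cs = CubicSpline(t[inner], v[inner], bc_type="natural")
        v[~inner] = cs(t[~inner])
    return ParameterSeries(s.name, t, v, s.scale, s.provenance + ["spline_fill"])


def moving_average(s: ParameterSeries, half_window: float = 5.0) -> ParameterSeries:
    """Moving mean over ``[t - half_window, t + half_window]`` seconds.

    Only full windows are emitted, so the output is trimmed by one half
    window on each side.  (Truncated edge windows would average half the
    data and bias the boundary level; max-type similarity statistics are
    dominated by exactly those boundary cells.)  Requires a gap-free series.
    """
    if half_window <= 0:
        raise PrepError("half_window must be > 0")
    if not np.all(np.isfinite(s.v)):
        raise PrepError(f"{s.name.render()}: moving_average requires a gap-free series")
    w = int(round(half_window * 1000.0 / s.resolution_ms))
    n = len(s)
    if n < 2 * w + 1:
        raise PrepError(f"{s.name.render()}: series shorter than the averaging window")
    csum = np.concatenate([[0.0], np.cumsum(s.v)])
    idx = np.arange(w, n - w)
    v = (csum[idx + w + 1] - csum[idx - w]) / (2 * w + 1)
    name = replace(s.name, mvavg=True)
    return ParameterSeries(name, s.t[idx].copy(), v, s.scale,
                           s.provenance + [f"moving_average(+/-{half_window}s)"])


def minmax_rescale(s: ParameterSeries) -> ParameterSeries:
    """Rescale min..max to 0..1; constant series map to all-zero (warned)."""
    if not np.all(np.isfinite(s.v)):
        raise PrepError(f"{s.name.render()}: minmax_rescale requires a gap-free series")
    lo, hi = float(np.min(s.v)), float(np.max(s.v))
    if hi == lo:
        logger.warning("%s: constant series rescaled to all-zero", s.name.render())
        v = np.zeros_like(s.v)
    else:
        v = (s.v - lo) / (hi - lo)
    return ParameterSeries(s.name, s.t.copy(), v, "rescaled01",
                           s.provenance + ["minmax_rescale"])


def butterworth_bandfilter(
    s: ParameterSeries, hp: float = 0.05, lp: float = 0.5, order: int = 1
) -> ParameterSeries:
    """First-order high-pass (0.05 Hz) then low-pass (0.5 Hz) Butterworth.

    Applied forward-backward (zero-phase) so the filtered channel is not
    artificially lagged before cross-correlation; this is recorded in the
    provenance.
    """
    if lp <= hp:
        raise PrepError(f"low-pass cutoff {lp} Hz must exceed high-pass {hp} Hz")
    fs = s.rate_hz
    if fs <= 2 * lp:
        raise PrepError(f"sampling rate {fs} Hz too low for low-pass at {lp} Hz")
    if not np.all(np.isfinite(s.v)):
        raise PrepError(f"{s.name.render()}: filtering requires a gap-free series")
    sos_hp = sps.butter(order, hp, btype="highpass", fs=fs, output="sos")
    sos_lp = sps.butter(order, lp, btype="lowpass", fs=fs, output="sos")
    v = sps.sosfiltfilt(sos_lp, sps.sosfiltfilt(sos_hp, s.v))
    name = replace(s.name, filtered=True)
    return ParameterSeries(name, s.t.copy(), v, s.scale,
                           s.provenance + [f"butterworth(hp={hp},lp={lp},order={order},zero_phase)"])


def from_frame(frame, channel: str) -> ParameterSeries:
    """Lift one AlignedFrame column into a ParameterSeries (original scale)."""
    if channel not in frame.channels:
        raise KeyError(f"channel {channel!r} not in frame")
    return ParameterSeries(ChannelName.parse(channel), frame.grid.copy(),
                           frame.channels[channel].copy(), "original",
                           [f"aligned@{frame.resolution}ms"])
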