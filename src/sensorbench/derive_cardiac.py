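"""Cardiac derivations: R-peak detection, IBI extraction, HR<->IBI conversion
and complex-demodulation heart-rate-variability band amplitudes.

The inter-beat interval (IBI, ms) is the time between successive R-peaks of
the ECG.  HRV is summarised as the time-varying amplitude of IBI oscillation
in three bands: VLF (0.025-0.07 Hz), LF (0.07-0.14 Hz) and HF (0.14-0.5 Hz),
estimated by complex demodulation: multiply the evenly resampled IBI series
by a complex carrier at the band centre, low-pass the product at half the
band width, and read off twice the magnitude as the amplitude envelope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .signal_prep import ChannelName, ParameterSeries, PrepError, spline_fill

logger = logging.getLogger(__name__)

#: Physiological bounds on a plausible inter-beat interval (200-40 bpm).
IBI_BOUNDS_MS = (250.0, 3000.0)

REFRACTORY_MS = 250.0


class CardiacError(ValueError):
    pass


@dataclass(frozen=True)
class HRVBand:
    name: str  # VLF | LF | HF
    f_lo: float  # Hz
    f_hi: float  # Hz

    def __post_init__(self) -> None:
        if not self.f_lo < self.f_hi:
            raise ValueError("f_lo must be < f_hi")

    @property
    def carrier(self) -> float:
        return 0.5 * (self.f_lo + self.f_hi)

    @property
    def half_width(self) -> float:
        return 0.5 * (self.f_hi - self.f_lo)


HRV_BANDS: dict[str, HRVBand] = {
    "VLF": HRVBand("VLF", 0.025, 0.07),
    "LF": HRVBand("LF", 0.07, 0.14),
    "HF": HRVBand("HF", 0.14, 0.5),
}


@dataclass
class RPeakTrain:
    """Strictly increasing R-peak times (ms) plus the source ECG channel."""

    peak_times: np.ndarray  # ms
    source: ChannelName

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        if self.peak_times.size and not np.all(np.diff(self.peak_times) > 0):
            raise CardiacError("peak times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.peak_times.size)


def detect_r_peaks(ecg: ParameterSeries) -> RPeakTrain:
    """Detect R-peaks with a derivative-square-integrate scheme.

    The ECG is band-passed (5-15 Hz), differentiated, squared and integrated
    over a 150 ms moving window; local maxima of the integrated energy above
    an adaptive signal/noise threshold, separated by a 250 ms refractory
    period, are accepted.  Peak times are refined to the local raw-signal
    maximum with parabolic (sub-sample) interpolation, so a clean pulse train
    is located to well under one sample.
    """
    if ecg.name.parameter != "ECG":
        raise CardiacError(f"expected an ECG channel, got {ecg.name.render()}")
    fs = ecg.rate_hz
    if fs < 100.0:
        raise CardiacError(f"ECG rate {fs:g} Hz < 100 Hz")
    v = ecg.v
    if not np.all(np.isfinite(v)):
        raise CardiacError("ECG must be gap-free (spline_fill first)")
    if v.size < int(fs) or float(np.std(v)) < 1e-12:
        logger.warning("%s: flat or too-short ECG, no peaks", ecg.name.render())
        return RPeakTrain(np.empty(0), ecg.name)

    hi = min(15.0, 0.45 * fs)
    sos = sps.butter(2, [5.0, hi], btype="bandpass", fs=fs, output="sos")
    band = sps.sosfiltfilt(sos, v)
    energy = np.gradient(band) ** 2
    win = max(1, int(round(0.150 * fs)))
    kernel = np.ones(win) / win
    integ = np.convolve(energy, kernel, mode="same")

    refractory = int(round(REFRACTORY_MS / 1000.0 * fs))
    cand, _ = sps.find_peaks(integ, distance=max(1, refractory))
    if cand.size == 0:
        logger.warning("%s: no candidate peaks", ecg.name.render())
        return RPeakTrain(np.empty(0), ecg.name)

    # Adaptive signal/noise levels (Pan-Tompkins style running estimates).
    spk = float(np.max(integ[cand[: min(len(cand), 20)]]))
    npk = float(np.median(integ))
    accepted: list[int] = []
    for c in cand:
        thr = npk + 0.25 * (spk - npk)
        if integ[c] >= thr:
            accepted.append(c)
            spk = 0.125 * integ[c] + 0.875 * spk
        else:
            npk = 0.125 * integ[c] + 0.875 * npk

    # Refine each accepted peak to the raw-signal maximum nearby.
    half = max(1, int(round(0.100 * fs)))
    times: list[float] = []
    for c in accepted:
        lo = max(0, c - half)
        hi_i = min(v.size, c + half + 1)
        k = lo + int(np.argmax(v[lo:hi_i]))
        t = ecg.t[k]
        if 0 < k < v.size - 1:
            y0, y1, y2 = v[k - 1], v[k], v[k + 1]
            denom = y0 - 2 * y1 + y2
            if abs(denom) > 1e-12:
                delta = 0.5 * (y0 - y2) / denom
                t = t + np.clip(delta, -1, 1) * ecg.resolution_ms
        times.append(float(t))

    times_arr = np.array(sorted(set(times)))
    if times_arr.size > 1:  # enforce refractory period on refined times
        keep = [0]
        for i in range(1, times_arr.size):
            if times_arr[i] - times_arr[keep[-1]] >= REFRACTORY_MS:
                keep.append(i)
        times_arr = times_arr[keep]
    return RPeakTrain(times_arr, ecg.name)


def ibi_intervals(p: RPeakTrain) -> tuple[np.ndarray, np.ndarray]:
    """Raw (stamp, interval) pairs: ``IBI(t_i) = t_i - t_{i-1}`` stamped at
    ``t_i``, with intervals outside the physiological bounds dropped."""
    if len(p) < 2:
        raise CardiacError("need >= 2 peaks to form an IBI")
    ibis = np.diff(p.peak_times)
    stamps = p.peak_times[1:]
    ok = (ibis >= IBI_BOUNDS_MS[0]) & (ibis <= IBI_BOUNDS_MS[1])
    if not ok.all():
        logger.info("%s: dropped %d non-physiological IBI sample(s)",
                    p.source.render(), int((~ok).sum()))
    return stamps[ok], ibis[ok]


def ibi_from_peaks(p: RPeakTrain, resolution_ms: float = 100.0) -> ParameterSeries:
    """IBI series from an R-peak train, resampled onto a regular grid.

    ``IBI(t_i) = t_i - t_{i-1}``, stamped at ``t_i``.  Intervals outside the
    physiological bounds [250, 3000] ms are dropped (artifact filter, logged),
    and the remaining samples are spline-interpolated onto the analysis grid.
    """
    stamps, ibis = ibi_intervals(p)
    if ibis.size < 4:
        raise CardiacError("fewer than 4 physiological IBIs")

    t0 = stamps[0] - (stamps[0] % resolution_ms)
    grid = np.arange(t0, stamps[-1] + resolution_ms, resolution_ms)
    idx = ((stamps - grid[0]) // resolution_ms).astype(int)
    sums = np.bincount(idx, weights=ibis, minlength=grid.size)
    counts = np.bincount(idx, minlength=grid.size)
    v = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)

    name = ChannelName("IBI", p.source.platform, derived_from="ECG")
    raw = ParameterSeries(name, grid, v, "original",
                          [f"ibi_from_peaks@{resolution_ms:g}ms"])
    return spline_fill(raw)


def hr_ibi_convert(v):
    """Convert HR [bpm] to IBI [ms] or back: ``IBI_ms = 60000 / HR_bpm``.

    A strict involution on positive values; accepts scalars or arrays.
    """
    arr = np.asarray(v, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("hr_ibi_convert requires positive values")
    out = 60000.0 / arr
    return float(out) if np.isscalar(v) or arr.ndim == 0 else out


def complex_demodulation(
    ibi: ParameterSeries, band: HRVBand, demod_rate_hz: float = 4.0
) -> ParameterSeries:
    """Amplitude envelope of the IBI oscillation inside one HRV band.

    The evenly resampled IBI series is multiplied by ``exp(-i 2 pi f_c t)``
    with the carrier at the band centre; the product is low-passed at half
    the band width (8th-order Butterworth, zero-phase) and the envelope is
    ``2 * |filtered product|``.  Output is interpolated back onto the input
    grid and named ``"<band>: from ECG <platform>"``.
    """
    if not np.all(np.isfinite(ibi.v)):
        raise CardiacError("complex_demodulation requires a gap-free IBI series")
    duration_s = (ibi.t[-1] - ibi.t[0]) / 1000.0
    min_dur = 2.0 / band.f_lo
    if duration_s < min_dur:
        raise CardiacError(
            f"series of {duration_s:.1f}s shorter than 2 carrier periods ({min_dur:.1f}s)"
        )
    # resample to the demodulation rate
    dt = 1.0 / demod_rate_hz
    t_s = np.arange(ibi.t[0] / 1000.0, ibi.t[-1] / 1000.0 + 0.5 * dt, dt)
    x = np.interp(t_s, ibi.t / 1000.0, ibi.v)
    x = x - float(np.mean(x))
    carrier = np.exp(-1j * 2.0 * np.pi * band.carrier * t_s)
    prod = x * carrier
    # steep skirt: a tone just outside the band sits barely beyond the
    # half-width cutoff, so a shallow filter would leak it into the envelope
    sos = sps.butter(8, band.half_width, btype="lowpass", fs=demod_rate_hz, output="sos")
    filt = sps.sosfiltfilt(sos, prod.real) + 1j * sps.sosfiltfilt(sos, prod.imag)
    amp = 2.0 * np.abs(filt)
    # back onto the input grid
    v = np.interp(ibi.t / 1000.0, t_s, amp)
    name = ChannelName(band.name, ibi.name.platform, derived_from="ECG",
                       mvavg=ibi.name.mvavg)
    return ParameterSeries(name, ibi.t.copy(), v, "original",
                           ibi.provenance + [f"complex_demodulation({band.name})"])
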