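"""Seeded synthetic cohort emulating the ergometer benchmarking protocol.

A session lasts 1200 s: 5 min seated rest, 10 min cycling with the load
stepped through 35/65/100/133/165 W every 2 min, and 5 min cool-down.  Per
participant a latent physiological truth is simulated:

* heart rate follows a first-order exponential approach to a load-dependent
  target (rest baseline ~65-75 bpm, target affine in watts; onset time
  constant 30 s, recovery 60 s);
* the inter-beat interval is 60000/HR plus sinusoidal LF- and HF-band
  modulation of known amplitude, so heart-rate-variability demodulation has
  a ground truth to recover; R-peaks are placed so successive gaps equal the
  instantaneous IBI (with small Gaussian jitter);
* skin conductance is a slow load-driven tonic level plus phasic
  exponential-decay responses at random event times.

Each platform then observes this truth through its own error model: platform
sampling rate, a constant reporting lag, a range-dependent offset ``a/v + b``
(maximal in the low range, vanishing in the high range), Gaussian noise,
sample dropout, and — for skin conductance — a platform-specific phasic gain
(the wrist-worn device responds more strongly to sweating than the gel
electrodes of the reference).  One deliberately degraded participant (heavy
dropout, weak electrode contact) is included to mirror the anomalous
participant of the original study.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ingest_align import CAPABILITIES, SensorStream

logger = logging.getLogger(__name__)

SESSION_S = 1200.0
TRUTH_RATE_HZ = 4.0
ECG_SIGMA_MS = 8.0
HR_BOUNDS_BPM = (45.0, 200.0)
LOAD_STEPS_W = (35.0, 65.0, 100.0, 133.0, 165.0)


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class ProtocolPhase:
    name: str
    start: float  # s
    duration: float  # s
    load: float  # W


def default_protocol() -> list[ProtocolPhase]:
    """Rest (5 min), five 2-min load steps, cool-down (5 min)."""
    phases = [ProtocolPhase("rest", 0.0, 300.0, 0.0)]
    for i, w in enumerate(LOAD_STEPS_W, start=1):
        phases.append(ProtocolPhase(f"step{i}", 300.0 + 120.0 * (i - 1), 120.0, w))
    phases.append(ProtocolPhase("cooldown", 900.0, 300.0, 0.0))
    return phases


def _validate_phases(phases: list[ProtocolPhase]) -> None:
    t = 0.0
    for ph in phases:
        if abs(ph.start - t) > 1e-9 or ph.duration <= 0:
            raise SimulationError(f"phases must tile the session; bad phase {ph}")
        t = ph.start + ph.duration


def load_profile(t_s: np.ndarray, phases: list[ProtocolPhase]) -> np.ndarray:
    load = np.zeros_like(t_s, dtype=float)
    for ph in phases:
        load[(t_s >= ph.start) & (t_s < ph.start + ph.duration)] = ph.load
    return load


@dataclass
class TruthParams:
    """Latent per-participant physiology; defaults are population means."""

    hr_baseline_bpm: float = 70.0
    hr_gain_bpm_per_w: float = 0.5
    tau_on_s: float = 30.0
    tau_off_s: float = 60.0
    lf_amplitude_ms: float = 50.0
    lf_freq_hz: float = 0.105
    hf_amplitude_ms: float = 25.0
    hf_freq_hz: float = 0.32
    ibi_jitter_ms: float = 2.0
    gsr_baseline_us: float = 5.0
    gsr_drift_gain_us: float = 2.0  # tonic rise at peak load
    gsr_tau_s: float = 60.0
    scr_rate_rest_hz: float = 0.05
    scr_rate_active_hz: float = 0.15
    scr_amplitude_us: float = 0.3


@dataclass
class TruthTrajectories:
    seed: int
    params: TruthParams
    phases: list[ProtocolPhase]
    t: np.ndarray  # s, regular TRUTH_RATE_HZ grid
    hr: np.ndarray  # bpm
    ibi: np.ndarray  # ms, == 60000 / hr exactly
    gsr_tonic: np.ndarray  # uS
    gsr_phasic: np.ndarray  # uS (unit phasic gain)
    r_peak_times_ms: np.ndarray

    @property
    def gsr(self) -> np.ndarray:
        return self.gsr_tonic + self.gsr_phasic


def simulate_truth(seed: int, phases: list[ProtocolPhase] | None = None,
                   params: TruthParams | None = None) -> TruthTrajectories:
    """Simulate one participant's latent trajectories (seeded)."""
    phases = phases if phases is not None else default_protocol()
    params = params if params is not None else TruthParams()
    _validate_phases(phases)
    if params.hr_baseline_bpm <= 0 or params.hr_gain_bpm_per_w < 0:
        raise SimulationError("invalid HR parameters")
    if params.tau_on_s <= 0 or params.tau_off_s <= 0 or params.gsr_tau_s <= 0:
        raise SimulationError("time constants must be positive")
    if params.gsr_baseline_us <= 0:
        raise SimulationError("GSR baseline must be positive")
    rng = np.random.default_rng(seed)
    duration = phases[-1].start + phases[-1].duration
    dt = 1.0 / TRUTH_RATE_HZ
    t = np.arange(0.0, duration, dt)
    load = load_profile(t, phases)

    # heart rate: first-order approach to a load-affine target
    target = params.hr_baseline_bpm + params.hr_gain_bpm_per_w * load
    hr_base = np.empty_like(t)
    hr_base[0] = target[0]
    for i in range(1, t.size):
        tau = params.tau_on_s if target[i] > hr_base[i - 1] else params.tau_off_s
        hr_base[i] = hr_base[i - 1] + dt * (target[i] - hr_base[i - 1]) / tau

    # IBI = 60000/HR plus band-limited sinusoidal modulation (HRV truth)
    phi_lf, phi_hf = rng.uniform(0.0, 2.0 * np.pi, size=2)
    ibi = 60000.0 / hr_base
    ibi = ibi + params.lf_amplitude_ms * np.sin(2 * np.pi * params.lf_freq_hz * t + phi_lf)
    ibi = ibi + params.hf_amplitude_ms * np.sin(2 * np.pi * params.hf_freq_hz * t + phi_hf)
    ibi = np.clip(ibi, 60000.0 / HR_BOUNDS_BPM[1], 60000.0 / HR_BOUNDS_BPM[0])
    hr = 60000.0 / ibi  # exact HR/IBI duality

    # skin conductance: tonic first-order drift + phasic responses
    tonic = np.empty_like(t)
    tonic[0] = params.gsr_baseline_us
    peak_w = max(ph.load for ph in phases) or 1.0
    for i in range(1, t.size):
        tgt = params.gsr_baseline_us + params.gsr_drift_gain_us * load[i] / peak_w
        tonic[i] = tonic[i - 1] + dt * (tgt - tonic[i - 1]) / params.gsr_tau_s
    rate = np.where(load > 0, params.scr_rate_active_hz, params.scr_rate_rest_hz)
    events = rng.random(t.size) < rate * dt
    impulses = np.where(events, rng.exponential(params.scr_amplitude_us, size=t.size), 0.0)
    tau_r, tau_d = 0.75, 4.0
    k_t = np.arange(0.0, 6.0 * tau_d, dt)
    kernel = np.exp(-k_t / tau_d) - np.exp(-k_t / tau_r)
    kernel /= kernel.max()
    phasic = np.convolve(impulses, kernel)[: t.size]

    # R-peaks: successive gaps equal the instantaneous IBI (+ jitter)
    peaks = []
    tp = float(rng.uniform(0.0, 0.5))
    while tp < duration:
        peaks.append(tp * 1000.0)
        gap_ms = float(np.interp(tp, t, ibi)) + rng.normal(0.0, params.ibi_jitter_ms)
        tp += max(gap_ms, 250.0) / 1000.0

    return TruthTrajectories(seed=seed, params=params, phases=list(phases), t=t,
                             hr=hr, ibi=ibi, gsr_tonic=tonic, gsr_phasic=phasic,
                             r_peak_times_ms=np.asarray(peaks))


@dataclass
class SensorErrorModel:
    """Observation model of one (platform, parameter) channel."""

    platform: str
    rate_hz: float
    lag_s: float = 0.0
    offset_a: float = 0.0  # reciprocal component: error a/v, largest at low values
    offset_b: float = 0.0
    noise_sd: float = 0.0
    dropout_p: float = 0.0
    phasic_gain: float = 1.0  # GSR responsiveness
    ecg_amplitude_mv: float = 1.0

    def __post_init__(self) -> None:
        if self.rate_hz <= 0:
            raise SimulationError("rate must be > 0")
        if self.lag_s < 0:
            raise SimulationError("lag must be >= 0")
        if not 0.0 <= self.dropout_p <= 0.2:
            raise SimulationError("dropout_p must lie in [0, 0.2]")


def apply_sensor_model(truth: TruthTrajectories, model: SensorErrorModel,
                       parameter: str, rng: np.random.Generator | None = None,
                       participant_id: str = "") -> SensorStream:
    """Observe one truth trajectory through a platform's error model."""
    if parameter not in CAPABILITIES.get(model.platform, ()):
        raise SimulationError(f"platform {model.platform} does not record {parameter}")
    rng = rng if rng is not None else np.random.default_rng(truth.seed)
    duration = truth.t[-1] + 1.0 / TRUTH_RATE_HZ

    if parameter == "ECG":
        step = 1000.0 / model.rate_hz
        t_ms = np.arange(0.0, duration * 1000.0, step)
        peaks = truth.r_peak_times_ms + model.lag_s * 1000.0
        v = np.zeros_like(t_ms)
        half = 5.0 * ECG_SIGMA_MS
        for pk in peaks:
            lo = np.searchsorted(t_ms, pk - half)
            hi = np.searchsorted(t_ms, pk + half)
            v[lo:hi] += model.ecg_amplitude_mv * np.exp(
                -0.5 * ((t_ms[lo:hi] - pk) / ECG_SIGMA_MS) ** 2)
        if model.noise_sd > 0:
            v = v + rng.normal(0.0, model.noise_sd, size=v.size)
    else:
        t_s = np.arange(0.0, duration, 1.0 / model.rate_hz)
        src = np.maximum(t_s - model.lag_s, 0.0)
        if parameter == "HR":
            v = np.interp(src, truth.t, truth.hr)
        elif parameter == "IBI":
            v = np.interp(src, truth.t, truth.ibi)
        elif parameter == "GSR":
            v = (np.interp(src, truth.t, truth.gsr_tonic)
                 + model.phasic_gain * np.interp(src, truth.t, truth.gsr_phasic))
        else:  # pragma: no cover
            raise SimulationError(f"unknown parameter {parameter}")
        if model.offset_a or model.offset_b:
            v = v + model.offset_a / v + model.offset_b
        if model.noise_sd > 0:
            v = v + rng.normal(0.0, model.noise_sd, size=v.size)
        if parameter == "GSR":
            v = np.maximum(v, 0.01)
        t_ms = t_s * 1000.0

    if model.dropout_p > 0:
        keep = rng.random(t_ms.size) >= model.dropout_p
        keep[:4] = True  # keep a usable stream even under heavy dropout
        t_ms, v = t_ms[keep], v[keep]

    return SensorStream(participant_id=participant_id, platform=model.platform,
                        parameter=parameter, nominal_rate=model.rate_hz,
                        t=t_ms, v=v)


def default_error_models() -> dict[tuple[str, str], SensorErrorModel]:
    """Study-condition error models per (platform, parameter).

    VP is the wired reference (no lag, negligible offset).  BH reports 1 s
    late with a reciprocal low-range HR offset; E4 reports 2 s late and is
    more responsive to sweating (higher phasic gain).  Sampling rates follow
    the devices: VP GSR 25 Hz, E4 GSR 4 Hz, E4 IBI 64 Hz, ECG 250 Hz; BH
    summary channels at 1 Hz.
    """
    return {
        ("VP", "HR"): SensorErrorModel("VP", 25.0, noise_sd=0.3, dropout_p=0.01),
        ("VP", "IBI"): SensorErrorModel("VP", 25.0, noise_sd=3.0, dropout_p=0.01),
        ("VP", "ECG"): SensorErrorModel("VP", 250.0, noise_sd=0.02, dropout_p=0.01),
        ("VP", "GSR"): SensorErrorModel("VP", 25.0, noise_sd=0.02, dropout_p=0.01),
        ("BH", "HR"): SensorErrorModel("BH", 1.0, lag_s=1.0, offset_a=700.0,
                                       noise_sd=0.8, dropout_p=0.01),
        ("BH", "IBI"): SensorErrorModel("BH", 1.0, lag_s=1.0, offset_b=5.0,
                                        noise_sd=8.0, dropout_p=0.01),
        ("BH", "ECG"): SensorErrorModel("BH", 250.0, lag_s=1.0, noise_sd=0.02,
                                        ecg_amplitude_mv=0.9, dropout_p=0.01),
        ("E4", "IBI"): SensorErrorModel("E4", 64.0, lag_s=2.0, noise_sd=10.0,
                                        dropout_p=0.02),
        ("E4", "GSR"): SensorErrorModel("E4", 4.0, lag_s=2.0, noise_sd=0.05,
                                        phasic_gain=1.8, dropout_p=0.01),
    }


def _degrade(models: dict[tuple[str, str], SensorErrorModel]) -> dict[tuple[str, str], SensorErrorModel]:
    """Weak-contact analog: heavy dropout, 10x noise, feeble ECG and GSR."""
    out = {}
    for key, m in models.items():
        out[key] = dataclasses.replace(
            m, dropout_p=0.2, noise_sd=m.noise_sd * 10.0,
            ecg_amplitude_mv=m.ecg_amplitude_mv * 0.15,
            phasic_gain=m.phasic_gain * 0.3,
        )
    return out


def _sample_params(rng: np.random.Generator) -> TruthParams:
    return TruthParams(
        hr_baseline_bpm=float(rng.uniform(65.0, 75.0)),
        hr_gain_bpm_per_w=float(np.clip(rng.normal(0.5, 0.04), 0.35, 0.6)),
        gsr_baseline_us=float(rng.uniform(2.0, 10.0)),
        gsr_drift_gain_us=float(rng.uniform(1.0, 3.0)),
    )


def generate_cohort(outdir: str | Path, n: int = 18, master_seed: int = 0,
                    degraded_index: int | None = 1,
                    error_models: dict[tuple[str, str], SensorErrorModel] | None = None,
                    ) -> dict:
    """Write an n-participant cohort in the raw delimited-file layout.

    Each participant gets one CSV per (platform, parameter) capability plus a
    ground-truth manifest (seeds, latent parameters, configured lags) used by
    recovery tests.  All randomness flows from ``master_seed``.  Participant
    ``degraded_index`` (default the second, set None to disable) uses the
    weak-contact error models.
    """
    if n < 1:
        raise SimulationError("n must be >= 1")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    base_models = error_models if error_models is not None else default_error_models()
    seeds = np.random.SeedSequence(master_seed).generate_state(2 * n) % (2 ** 31)
    manifest: dict = {"master_seed": int(master_seed), "n": int(n), "participants": []}
    if degraded_index is not None and degraded_index >= n:
        degraded_index = None

    for i in range(n):
        pid = f"RP_{i + 1:02d}"
        pdir = outdir / pid
        pdir.mkdir(exist_ok=True)
        truth_seed = int(seeds[2 * i])
        sensor_seed = int(seeds[2 * i + 1])
        prng = np.random.default_rng(truth_seed)
        params = _sample_params(prng)
        truth = simulate_truth(truth_seed, params=params)
        degraded = degraded_index is not None and i == degraded_index
        models = _degrade(base_models) if degraded else base_models
        srng = np.random.default_rng(sensor_seed)
        files = {}
        for (platform, parameter), model in sorted(models.items()):
            stream = apply_sensor_model(truth, model, parameter, rng=srng,
                                        participant_id=pid)
            fname = f"{platform}_{parameter}.csv"
            pd.DataFrame({"t_ms": stream.t, "value": stream.v}).to_csv(
                pdir / fname, index=False, float_format="%.4f")
            files[f"{platform}/{parameter}"] = fname
        manifest["participants"].append({
            "id": pid,
            "truth_seed": truth_seed,
            "sensor_seed": sensor_seed,
            "degraded": bool(degraded),
            "params": dataclasses.asdict(params),
            "lags_s": {f"{p}/{q}": m.lag_s for (p, q), m in sorted(models.items())},
            "files": files,
        })

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
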