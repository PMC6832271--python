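"""Orchestration: channel preparation, pair enumeration, the per-participant
metric battery, and assembly of sorted participant x pair benchmark matrices.

The default roster holds the study's 15 analysis parameters: 7 directly
measured channels (HR from VP and BH; IBI from VP, BH and E4; GSR from VP and
E4) plus 8 ECG-derived ones (IBI, VLF, LF and HF from the VP and BH ECGs).
Same-parameter pairs (every cross-source combination within a parameter,
raw and moving-averaged variants paired separately) receive the full
correlation + similarity battery; cross-parameter pairs (moving-averaged
variants) receive the correlation battery.  Correlation metrics consume the
original scale, similarity metrics min-max rescaled copies.

Matrices follow the study's sorting convention: within each parameter group
rows are ordered by cross-participant average (best first), columns by the
participant's average over all pairs (best first); "best" is the highest
value for correlation statistics and the smallest distance for similarity
statistics.  Row averages are appended as a last column and per-group column
averages as a group's last row; missing cells stay missing and are excluded
from every average.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import correlation_metrics as cm
from . import derive_cardiac as dc
from . import ingest_align as ia
from . import signal_prep as sp
from . import similarity_metrics as sm

logger = logging.getLogger(__name__)

PARAMETER_ORDER = ("HR", "IBI", "GSR", "VLF", "LF", "HF")
#: the laboratory reference first, so it acts as the independent series in
#: cross-correlation (a positive best lag = the wearable lags behind VP)
PLATFORM_ORDER = ("VP", "BH", "E4")
CORRELATION_BATTERY = ("r2", "ccf", "mic", "association")
SIMILARITY_BATTERY = ("dtw", "frechet_global", "frechet_local")
FULL_BATTERY = CORRELATION_BATTERY + SIMILARITY_BATTERY
#: statistics where smaller means more similar (sorted ascending)
DISTANCE_STATISTICS = ("dtw", "frechet_global")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Run configuration; every metric parameter is overridable from YAML."""

    resolution_ms: int = 100  # alignment grid for all channels but ECG
    ecg_resolution_ms: int = 10  # finer grid so R-peak timing survives
    metric_resolution_ms: int = 1000  # battery grid (integer-second lags)
    half_window_s: float = 5.0  # moving-average half window
    max_lag_s: float = 15.0
    epsilon: float = 0.1  # MIC - R^2 tolerance for "~ 0"
    mic_alpha: float = 0.6
    mic_c: float = 15.0
    mic_exact_n: int = 40
    frechet_window_s: float = 60.0
    frechet_step_s: float = 10.0
    demod_rate_hz: float = 4.0
    gsr_filter: bool = True  # produce filt. / filt. (mv. avg.) GSR variants
    difference_ccf: bool = True
    seed: int = 0

    @property
    def mic_config(self) -> cm.MICConfig:
        return cm.MICConfig(alpha=self.mic_alpha, c=self.mic_c, exact_n=self.mic_exact_n)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class PairSpec:
    """One channel pair and the battery it receives."""

    a: sp.ChannelName
    b: sp.ChannelName
    pair_type: str  # same_parameter | cross_parameter
    battery: tuple[str, ...]

    @property
    def key(self) -> str:
        return f"{self.a.render()} vs {self.b.render()}"

    @property
    def group(self) -> str:
        """Parameter group for matrix row grouping (same-type pairs)."""
        return self.a.parameter if self.pair_type == "same_parameter" else "cross"


@dataclass
class PairMetrics:
    """Metric battery outcome for one pair; unfilled members stay None."""

    pair: PairSpec
    r2: float | None = None
    ccf: cm.CrossCorrelation | None = None
    mic: float | None = None
    association: cm.AssociationClass | None = None
    dtw: float | None = None
    frechet_global: float | None = None
    frechet_local: tuple[np.ndarray, np.ndarray] | None = None

    def statistic(self, name: str) -> float:
        """Scalar cell value for matrix assembly (NaN when unavailable)."""
        if name == "r2":
            return float("nan") if self.r2 is None else self.r2
        if name == "mic":
            return float("nan") if self.mic is None else self.mic
        if name == "nonlinearity":
            return float("nan") if self.association is None else self.association.score
        if name == "ccf_peak":
            return float("nan") if self.ccf is None else self.ccf.peak
        if name == "best_lag":
            return float("nan") if self.ccf is None else self.ccf.best_lag
        if name == "dtw":
            return float("nan") if self.dtw is None else self.dtw
        if name == "frechet_global":
            return float("nan") if self.frechet_global is None else self.frechet_global
        raise KeyError(f"unknown statistic {name!r}")


def default_roster() -> list[sp.ChannelName]:
    """The 15 analysis parameters (base variants, unfiltered, not averaged)."""
    roster = [
        sp.ChannelName("HR", "VP"), sp.ChannelName("HR", "BH"),
        sp.ChannelName("IBI", "VP"), sp.ChannelName("IBI", "BH"), sp.ChannelName("IBI", "E4"),
        sp.ChannelName("GSR", "VP"), sp.ChannelName("GSR", "E4"),
    ]
    for plat in ("VP", "BH"):
        for param in ("IBI", "VLF", "LF", "HF"):
            roster.append(sp.ChannelName(param, plat, derived_from="ECG"))
    return roster


def _validate_roster(roster: Sequence[sp.ChannelName]) -> None:
    for ch in roster:
        if ch.derived_from == "ECG":
            if "ECG" not in ia.CAPABILITIES[ch.platform]:
                raise PipelineError(f"{ch.render()}: platform has no ECG to derive from")
        elif ch.parameter in ("VLF", "LF", "HF"):
            raise PipelineError(f"{ch.render()}: HRV bands exist only as derived channels")
        elif ch.parameter not in ia.CAPABILITIES[ch.platform]:
            raise PipelineError(f"{ch.render()}: violates the platform capability table")


def _sort_key(ch: sp.ChannelName) -> tuple:
    return (PARAMETER_ORDER.index(ch.parameter), ch.filtered, ch.mvavg,
            ch.derived_from, PLATFORM_ORDER.index(ch.platform))


def enumerate_pairs(roster: Sequence[sp.ChannelName],
                    policy: Mapping | None = None) -> list[PairSpec]:
    """Enumerate same-parameter and cross-parameter pairs from a roster.

    ``roster`` lists base channels (no variant flags); variants are expanded
    here: same-parameter pairs are formed per variant (raw and mv-avg
    separately, plus filtered GSR when enabled), cross-parameter pairs use
    the moving-averaged variants.  Order is deterministic: parameter group,
    then variant, then platform.
    """
    policy = dict(policy or {})
    gsr_filter = bool(policy.get("gsr_filter", True))
    cross_variant_mvavg = bool(policy.get("cross_variant_mvavg", True))
    _validate_roster(roster)

    variants: list[sp.ChannelName] = []
    for ch in roster:
        variants.append(ch)
        variants.append(dataclasses.replace(ch, mvavg=True))
        if gsr_filter and ch.parameter == "GSR":
            variants.append(dataclasses.replace(ch, filtered=True))
            variants.append(dataclasses.replace(ch, filtered=True, mvavg=True))
    variants.sort(key=_sort_key)

    pairs: list[PairSpec] = []
    # same-parameter: identical (parameter, filtered, mvavg), different source
    by_group: dict[tuple, list[sp.ChannelName]] = {}
    for ch in variants:
        by_group.setdefault((ch.parameter, ch.filtered, ch.mvavg), []).append(ch)
    for key in sorted(by_group, key=lambda k: (PARAMETER_ORDER.index(k[0]), k[1], k[2])):
        group = by_group[key]
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                a, b = group[i], group[j]
                if (a.platform, a.derived_from) == (b.platform, b.derived_from):
                    continue
                pairs.append(PairSpec(a, b, "same_parameter", FULL_BATTERY))

    # cross-parameter: different parameter, configured variant policy
    cross_roster = [ch for ch in variants
                    if ch.mvavg == cross_variant_mvavg]
    for i in range(len(cross_roster)):
        for j in range(i + 1, len(cross_roster)):
            a, b = cross_roster[i], cross_roster[j]
            if a.parameter == b.parameter:
                continue
            pairs.append(PairSpec(a, b, "cross_parameter", CORRELATION_BATTERY))
    logger.info("enumerated %d same-parameter and %d cross-parameter pairs",
                sum(p.pair_type == "same_parameter" for p in pairs),
                sum(p.pair_type == "cross_parameter" for p in pairs))
    return pairs


# ---------------------------------------------------------------------------
# channel preparation


def _downsample(s: sp.ParameterSeries, resolution_ms: float) -> sp.ParameterSeries:
    """Block-mean onto a coarser grid (blocks anchored at t=0 multiples)."""
    if resolution_ms <= s.resolution_ms:
        return s
    factor = resolution_ms / s.resolution_ms
    if abs(factor - round(factor)) > 1e-9:
        raise PipelineError("metric resolution must be a multiple of the grid step")
    t0 = np.ceil(s.t[0] / resolution_ms) * resolution_ms
    start = int(round((t0 - s.t[0]) / s.resolution_ms))
    f = int(round(factor))
    nblocks = (len(s) - start) // f
    if nblocks < 2:
        raise PipelineError("series too short for the metric grid")
    v = s.v[start:start + nblocks * f].reshape(nblocks, f).mean(axis=1)
    t = t0 + resolution_ms * np.arange(nblocks)
    return sp.ParameterSeries(s.name, t, v, s.scale,
                              s.provenance + [f"downsample@{resolution_ms:g}ms"])


def read_participant_streams(pdir: str | Path) -> list[ia.SensorStream]:
    """Read every ``<platform>_<parameter>.csv`` in a participant directory."""
    pdir = Path(pdir)
    streams = []
    for path in sorted(pdir.glob("*_*.csv")):
        platform, parameter = path.stem.split("_", 1)
        if platform not in ia.PLATFORMS or parameter not in ia.PARAMETERS:
            continue
        streams.append(ia.read_stream(path, participant_id=pdir.name,
                                      platform=platform, parameter=parameter))
    if not streams:
        raise PipelineError(f"{pdir}: no stream files found")
    return streams


def prepare_channels(pdir: str | Path, cfg: PipelineConfig | None = None,
                     ) -> dict[str, sp.ParameterSeries]:
    """Full preparation of one participant: align, fill, derive, variants.

    Returns every analysis channel (direct + ECG-derived, raw / mv-avg /
    filtered variants) on the metric grid, keyed by rendered channel name.
    A channel that fails preparation is skipped with a log entry, never
    aborting the participant.
    """
    cfg = cfg or PipelineConfig()
    streams = read_participant_streams(pdir)
    ecg_streams = [s for s in streams if s.parameter == "ECG"]
    other_streams = [s for s in streams if s.parameter != "ECG"]

    base: dict[str, sp.ParameterSeries] = {}
    if other_streams:
        frame = ia.transpose_align(other_streams, cfg.resolution_ms)
        for name in frame.channels:
            try:
                base[name] = sp.spline_fill(sp.from_frame(frame, name))
            except sp.PrepError as exc:
                logger.warning("%s: %s: channel skipped", Path(pdir).name, exc)

    for s in ecg_streams:
        try:
            eframe = ia.transpose_align([s], cfg.ecg_resolution_ms)
            ecg = sp.spline_fill(sp.from_frame(eframe, f"ECG: {s.platform}"))
            peaks = dc.detect_r_peaks(ecg)
            ibi = dc.ibi_from_peaks(peaks, resolution_ms=cfg.resolution_ms)
            base[ibi.name.render()] = ibi
            for band in dc.HRV_BANDS.values():
                env = dc.complex_demodulation(ibi, band, demod_rate_hz=cfg.demod_rate_hz)
                base[env.name.render()] = env
        except (dc.CardiacError, sp.PrepError) as exc:
            logger.warning("%s: ECG %s: derivation failed: %s",
                           Path(pdir).name, s.platform, exc)

    channels: dict[str, sp.ParameterSeries] = {}
    for name, series in base.items():
        variants = [series, sp.moving_average(series, cfg.half_window_s)]
        if cfg.gsr_filter and series.name.parameter == "GSR":
            try:
                filt = sp.butterworth_bandfilter(series)
                variants += [filt, sp.moving_average(filt, cfg.half_window_s)]
            except sp.PrepError as exc:
                logger.warning("%s: %s", Path(pdir).name, exc)
        for var in variants:
            try:
                channels[var.name.render()] = _downsample(var, cfg.metric_resolution_ms)
            except PipelineError as exc:
                logger.warning("%s: %s: %s", Path(pdir).name, var.name.render(), exc)
    return channels


# ---------------------------------------------------------------------------
# metric battery


def _common_span(x: sp.ParameterSeries, y: sp.ParameterSeries,
                 ) -> tuple[sp.ParameterSeries, sp.ParameterSeries]:
    """Trim two same-resolution series to their overlapping span."""
    if abs(x.resolution_ms - y.resolution_ms) > 1e-9:
        raise PipelineError("series resolutions differ")
    t0 = max(x.t[0], y.t[0])
    t1 = min(x.t[-1], y.t[-1])
    if t1 <= t0:
        raise PipelineError("series do not overlap")

    def cut(s: sp.ParameterSeries) -> sp.ParameterSeries:
        i0 = int(round((t0 - s.t[0]) / s.resolution_ms))
        i1 = int(round((t1 - s.t[0]) / s.resolution_ms)) + 1
        return sp.ParameterSeries(s.name, s.t[i0:i1], s.v[i0:i1], s.scale,
                                  list(s.provenance))

    return cut(x), cut(y)


def compute_pair_metrics(x: sp.ParameterSeries, y: sp.ParameterSeries,
                         pair: PairSpec, cfg: PipelineConfig) -> PairMetrics:
    """Run the pair's battery: correlations on the original scale,
    similarities on min-max rescaled copies."""
    x, y = _common_span(x, y)
    out = PairMetrics(pair=pair)
    if "r2" in pair.battery:
        out.r2 = cm.linear_r2(x, y)
    if "ccf" in pair.battery:
        out.ccf = cm.cross_correlation(x, y, max_lag=cfg.max_lag_s,
                                       difference=cfg.difference_ccf)
    if "mic" in pair.battery:
        out.mic = cm.mic(x, y, cfg.mic_config)
    if "association" in pair.battery and out.mic is not None and out.r2 is not None:
        if np.isfinite(out.r2):
            out.association = cm.classify_association(out.mic, out.r2, cfg.epsilon)
    needs_sim = set(pair.battery) & set(SIMILARITY_BATTERY)
    if needs_sim:
        xr, yr = sp.minmax_rescale(x), sp.minmax_rescale(y)
        if "dtw" in pair.battery:
            out.dtw = sm.dtw_distance(xr, yr)
        if "frechet_global" in pair.battery:
            out.frechet_global = sm.frechet_global(xr, yr)
        if "frechet_local" in pair.battery:
            out.frechet_local = sm.frechet_local(xr, yr, cfg.frechet_window_s,
                                                 cfg.frechet_step_s)
    return out


def run_participant(channels: Mapping[str, sp.ParameterSeries],
                    pairs: Sequence[PairSpec],
                    cfg: PipelineConfig | None = None,
                    ) -> dict[str, PairMetrics | None]:
    """Compute the battery for every pair; failures become missing cells."""
    cfg = cfg or PipelineConfig()
    results: dict[str, PairMetrics | None] = {}
    errors: dict[str, str] = {}
    for pair in pairs:
        a, b = pair.a.render(), pair.b.render()
        if a not in channels or b not in channels:
            results[pair.key] = None
            errors[pair.key] = "missing channel"
            continue
        try:
            results[pair.key] = compute_pair_metrics(channels[a], channels[b], pair, cfg)
        except (PipelineError, ValueError) as exc:
            logger.warning("pair %s failed: %s", pair.key, exc)
            results[pair.key] = None
            errors[pair.key] = str(exc)
    if results and all(v is None for v in results.values()):
        raise PipelineError(f"all pairs failed: {errors}")
    return results


# ---------------------------------------------------------------------------
# matrix assembly


@dataclass
class BenchmarkMatrix:
    """Sorted participants x pairs grid of one statistic, with averages."""

    statistic: str
    data: pd.DataFrame  # rows: pair keys (sorted), cols: participants (sorted)
    groups: pd.Series  # parameter group per pair key
    ascending: bool  # True for distance statistics
    row_avgs: pd.Series = field(default=None)  # type: ignore[assignment]
    col_avgs: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.row_avgs is None:
            self.row_avgs = self.data.mean(axis=1, skipna=True)
        if self.col_avgs is None:
            self.col_avgs = self.data.groupby(self.groups, sort=False).mean()

    def to_display_frame(self) -> pd.DataFrame:
        """Wide table with the per-pair average as last column and each
        group's participant average appended as the group's last row."""
        blocks = []
        for grp in self.groups.unique():
            rows = self.data.loc[self.groups == grp].copy()
            rows["avg"] = self.row_avgs.loc[rows.index]
            avg_row = self.col_avgs.loc[grp].copy()
            avg_row["avg"] = float(rows["avg"].mean(skipna=True))
            avg_row.name = f"[{grp}] participant avg"
            blocks.append(pd.concat([rows, avg_row.to_frame().T]))
        return pd.concat(blocks)

    def to_csv(self, path: str | Path) -> None:
        self.to_display_frame().to_csv(path, index_label="pair", float_format="%.10g")


def assemble_matrix(results: Mapping[str, Mapping[str, PairMetrics | None]],
                    statistic: str,
                    pairs: Sequence[PairSpec] | None = None) -> BenchmarkMatrix:
    """Assemble the sorted benchmark matrix of one statistic.

    ``results`` maps participant -> pair key -> PairMetrics (or None for a
    missing cell).  Rows are sorted within their parameter group by
    cross-participant mean, columns by cross-pair mean; both sorts are
    stable, descending for correlation statistics and ascending for
    distances.  Missing cells are excluded from averages, never imputed.
    """
    if not results:
        raise PipelineError("no participants")
    participants = sorted(results)  # processing-order independent tie-break
    pair_keys: list[str] = []
    group_of: dict[str, str] = {}
    if pairs is not None:
        for p in pairs:
            pair_keys.append(p.key)
            group_of[p.key] = p.group
    else:
        for per in results.values():
            for key, pm in per.items():
                if key not in group_of:
                    pair_keys.append(key)
                    group_of[key] = pm.pair.group if pm is not None else "cross"

    cells = pd.DataFrame(
        {q: {k: (np.nan if results[q].get(k) is None
                 else results[q][k].statistic(statistic))
             for k in pair_keys} for q in participants},
        index=pd.Index(pair_keys, name="pair"), columns=participants,
    )
    ascending = statistic in DISTANCE_STATISTICS
    groups = pd.Series({k: group_of[k] for k in pair_keys}, index=cells.index)

    col_means = cells.mean(axis=0, skipna=True)
    col_order = col_means.sort_values(ascending=ascending, kind="stable",
                                      na_position="last").index
    cells = cells[col_order]

    row_means = cells.mean(axis=1, skipna=True)
    ordered_rows: list[str] = []
    seen: list[str] = []
    for key in pair_keys:  # preserve group appearance order
        g = groups[key]
        if g not in seen:
            seen.append(g)
    for g in seen:
        keys = [k for k in pair_keys if groups[k] == g]
        sorted_keys = row_means.loc[keys].sort_values(
            ascending=ascending, kind="stable", na_position="last").index
        ordered_rows.extend(sorted_keys)
    cells = cells.loc[ordered_rows]
    groups = groups.loc[ordered_rows]
    return BenchmarkMatrix(statistic=statistic, data=cells, groups=groups,
                           ascending=ascending)


# ---------------------------------------------------------------------------
# cohort driver and tidy output


def results_to_tidy(results: Mapping[str, Mapping[str, PairMetrics | None]],
                    ) -> pd.DataFrame:
    """Long-format table: participant, pair, pair_type, metric, lag, value."""
    rows = []
    for participant, per in results.items():
        for key, pm in per.items():
            if pm is None:
                rows.append((participant, key, "", "missing", np.nan, np.nan))
                continue
            ptype = pm.pair.pair_type
            for stat in ("r2", "mic", "nonlinearity", "ccf_peak", "best_lag",
                         "dtw", "frechet_global"):
                try:
                    val = pm.statistic(stat)
                except KeyError:  # pragma: no cover
                    continue
                if np.isfinite(val):
                    rows.append((participant, key, ptype, stat, np.nan, val))
            if pm.association is not None:
                rows.append((participant, key, ptype,
                             f"class:{pm.association.value}", np.nan,
                             pm.association.score))
            if pm.ccf is not None:
                for lag, r in zip(pm.ccf.lags, pm.ccf.coefficients):
                    if np.isfinite(r):
                        rows.append((participant, key, ptype, "ccf", lag, r))
    return pd.DataFrame(rows, columns=["participant", "pair", "pair_type",
                                       "metric", "lag", "value"])


def local_frechet_to_tidy(results: Mapping[str, Mapping[str, PairMetrics | None]],
                          ) -> pd.DataFrame:
    rows = []
    for participant, per in results.items():
        for key, pm in per.items():
            if pm is None or pm.frechet_local is None:
                continue
            starts, dists = pm.frechet_local
            for t0, d in zip(starts, dists):
                rows.append((participant, key, t0, d))
    return pd.DataFrame(rows, columns=["participant", "pair", "window_start_s",
                                       "distance"])


def run_cohort(input_dir: str | Path, cfg: PipelineConfig | None = None,
               outdir: str | Path | None = None,
               roster: Sequence[sp.ChannelName] | None = None,
               pairs: Sequence[PairSpec] | None = None,
               participants: Sequence[str] | None = None,
               ) -> dict[str, dict[str, PairMetrics | None]]:
    """Run the full benchmark over a cohort directory.

    ``input_dir`` holds one sub-directory per participant (raw stream CSVs).
    When ``outdir`` is given, tidy metric tables, the benchmark matrices and
    a run manifest are written there.  Cell values depend only on each
    participant's own data, so processing order is irrelevant.
    """
    cfg = cfg or PipelineConfig()
    input_dir = Path(input_dir)
    if pairs is None:
        pairs = enumerate_pairs(roster if roster is not None else default_roster(),
                                {"gsr_filter": cfg.gsr_filter})
    pdirs = sorted(d for d in input_dir.iterdir() if d.is_dir())
    if participants is not None:
        pdirs = [d for d in pdirs if d.name in set(participants)]
    if not pdirs:
        raise PipelineError(f"no participant directories under {input_dir}")

    results: dict[str, dict[str, PairMetrics | None]] = {}
    for pdir in pdirs:
        logger.info("processing %s", pdir.name)
        channels = prepare_channels(pdir, cfg)
        results[pdir.name] = run_participant(channels, pairs, cfg)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tidy = results_to_tidy(results)
        tidy.to_csv(outdir / "metrics.csv", index=False, float_format="%.10g")
        local_frechet_to_tidy(results).to_csv(
            outdir / "frechet_local.csv", index=False, float_format="%.10g")
        for stat in ("r2", "ccf_peak", "mic", "nonlinearity", "dtw", "frechet_global"):
            matrix = assemble_matrix(results, stat, pairs=pairs)
            matrix.to_csv(outdir / f"matrix_{stat}.csv")
        manifest = {
            "config": cfg.to_dict(),
            "participants": [d.name for d in pdirs],
            "n_pairs": {
                "same_parameter": sum(p.pair_type == "same_parameter" for p in pairs),
                "cross_parameter": sum(p.pair_type == "cross_parameter" for p in pairs),
            },
        }
        with open(outdir / "run_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
    return results
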