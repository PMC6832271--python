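"""Reading raw sensor streams and aligning them onto a regular millisecond grid.

Raw recordings arrive as one delimited text file per (participant, platform,
parameter), either in a plain dialect (columns ``t_ms, value``) or in a packed
dialect (columns ``t_s, payload, rate_hz``) where every row carries one second
worth of sub-second samples in a single delimiter-separated string.  Streams
are unpacked, validated, and transposed from the vertical one-sample-per-row
layout onto a common regular grid (10 or 100 ms cells), averaging samples that
fall into the same cell and leaving empty cells missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PLATFORMS = ("VP", "BH", "E4")
PARAMETERS = ("HR", "IBI", "ECG", "GSR")

#: Platform capability matrix: which parameter each platform records directly.
#: VP is the wired laboratory reference; BH is a chest strap (no GSR); E4 is a
#: wrist band (no ECG electrodes, optical IBI only).
CAPABILITIES: dict[str, tuple[str, ...]] = {
    "VP": ("HR", "IBI", "ECG", "GSR"),
    "BH": ("HR", "IBI", "ECG"),
    "E4": ("IBI", "GSR"),
}

VALID_RESOLUTIONS = (10, 100)


class StreamError(ValueError):
    """Raised for malformed or inconsistent raw stream files."""


@dataclass
class PackedRow:
    """One second of samples packed into a delimited payload string."""

    t0: float  # ms since session start, second resolution
    payload: str  # k delimiter-separated decimal values
    k: int  # samples encoded in the payload


@dataclass
class SensorStream:
    """One raw (platform, parameter) sample sequence for one participant.

    ``t`` is in milliseconds since session start, ``v`` in the parameter's
    native unit (HR bpm, IBI ms, ECG mV, GSR uS).
    """

    participant_id: str
    platform: str
    parameter: str
    nominal_rate: float  # samples / second
    t: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.platform not in PLATFORMS:
            raise StreamError(f"unknown platform {self.platform!r}")
        if self.parameter not in PARAMETERS:
            raise StreamError(f"unknown parameter {self.parameter!r}")
        if self.parameter not in CAPABILITIES[self.platform]:
            raise StreamError(
                f"platform {self.platform} does not record {self.parameter}"
            )
        if self.nominal_rate <= 0:
            raise StreamError("nominal_rate must be > 0")
        if self.t.size != self.v.size:
            raise StreamError("t and v must have equal length")
        if self.t.size and not np.all(np.diff(self.t) > 0):
            raise StreamError("timestamps must be strictly increasing")
        if self.v.size and not np.all(np.isfinite(self.v)):
            raise StreamError("all sample values must be finite")

    def __len__(self) -> int:
        return int(self.t.size)


@dataclass
class AlignedFrame:
    """Multichannel regular-grid table with missing cells encoded as NaN."""

    resolution: int  # grid step, ms
    grid: np.ndarray  # regular timestamps, ms
    channels: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.resolution not in VALID_RESOLUTIONS:
            raise ValueError(f"resolution must be one of {VALID_RESOLUTIONS}")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"t_ms": self.grid, **self.channels})

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.6f")


def unpack_packed_row(row: PackedRow, rate: float, delimiter: str = ";") -> list[tuple[float, float]]:
    """Expand one packed row into ``(t_ms, value)`` samples.

    Sample ``i`` of ``k`` receives timestamp ``t0 + i * 1000 / rate`` so that
    every single measurement carries its own sub-second timestamp.
    """
    parts = [p for p in row.payload.split(delimiter) if p.strip() != ""]
    try:
        values = [float(p) for p in parts]
    except ValueError as exc:
        excerpt = row.payload[:40]
        raise StreamError(f"cannot decode packed payload {excerpt!r}: {exc}") from exc
    if len(values) != row.k:
        raise StreamError(
            f"packed row at t0={row.t0} declares k={row.k} but payload has {len(values)} values"
        )
    step = 1000.0 / rate
    return [(row.t0 + i * step, v) for i, v in enumerate(values)]


def _infer_rate(t_ms: np.ndarray) -> float:
    if t_ms.size < 2:
        return 1.0
    dt = float(np.median(np.diff(t_ms)))
    return 1000.0 / dt if dt > 0 else 1.0


def read_stream(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    *,
    participant_id: str = "",
    platform: str = "VP",
    parameter: str = "HR",
    nominal_rate: float | None = None,
    delimiter: str = ",",
) -> SensorStream:
    """Read one raw stream file (plain or packed dialect) into a SensorStream.

    ``schema`` optionally remaps the expected column names, e.g.
    ``{"t_ms": "time", "value": "gsr"}``.  Rows are sorted by timestamp;
    duplicate timestamps are rejected naming the offending line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    schema = dict(schema or {})
    try:
        df = pd.read_csv(path, sep=delimiter)
    except Exception as exc:  # pandas raises several parser error types
        raise StreamError(f"{path.name}: cannot parse file: {exc}") from exc
    if df.empty:
        raise StreamError(f"{path.name}: empty stream file")

    cols = {c.strip(): c for c in df.columns}
    t_col = schema.get("t_ms", "t_ms")
    v_col = schema.get("value", "value")
    packed_cols = (schema.get("t_s", "t_s"), schema.get("payload", "payload"),
                   schema.get("rate_hz", "rate_hz"))

    if all(c in cols for c in packed_cols):
        samples: list[tuple[float, float]] = []
        rows = zip(df[cols[packed_cols[0]]], df[cols[packed_cols[1]]], df[cols[packed_cols[2]]])
        for line_no, (t_s, payload, rate) in enumerate(rows, start=2):
            try:
                payload = str(payload)
                k = len([p for p in payload.split(";") if p.strip() != ""])
                samples.extend(
                    unpack_packed_row(PackedRow(float(t_s) * 1000.0, payload, k), float(rate))
                )
            except (StreamError, ValueError) as exc:
                raise StreamError(f"{path.name}: line {line_no}: {exc}") from exc
        t = np.array([s[0] for s in samples])
        v = np.array([s[1] for s in samples])
        rate = nominal_rate if nominal_rate is not None else float(df[cols[packed_cols[2]]].iloc[0])
    else:
        if t_col not in cols or v_col not in cols:
            raise StreamError(
                f"{path.name}: columns not resolvable; expected ({t_col!r}, {v_col!r}) "
                f"or packed dialect {packed_cols}, found {list(df.columns)}"
            )
        t_raw = pd.to_numeric(df[cols[t_col]], errors="coerce")
        v_raw = pd.to_numeric(df[cols[v_col]], errors="coerce")
        bad = t_raw.isna() | v_raw.isna()
        if bad.any():
            # +2: header line plus 1-based numbering
            line_no = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise StreamError(f"{path.name}: line {line_no}: malformed row")
        t = t_raw.to_numpy(dtype=float)
        v = v_raw.to_numpy(dtype=float)
        rate = nominal_rate if nominal_rate is not None else _infer_rate(np.sort(t))

    order = np.argsort(t, kind="stable")
    t, v = t[order], v[order]
    dup = np.flatnonzero(np.diff(t) == 0)
    if dup.size:
        # report the file line of the duplicated timestamp (post-sort index
        # maps back through `order`; +2 for header and 1-based lines)
        line_no = int(order[dup[0] + 1]) + 2
        raise StreamError(
            f"{path.name}: line {line_no}: duplicate timestamp {t[dup[0]]:g} ms"
        )

    return SensorStream(
        participant_id=participant_id,
        platform=platform,
        parameter=parameter,
        nominal_rate=float(rate),
        t=t,
        v=v,
    )


def transpose_align(streams: Sequence[SensorStream], resolution: int) -> AlignedFrame:
    """Transpose vertical streams into a horizontal multichannel grid.

    Each sample is assigned to the half-open cell ``[t, t + resolution)``
    anchored at the session start (the earliest timestamp over all streams);
    cells holding more than one sample store the arithmetic mean, cells with
    no sample are missing (NaN).  The grid covers the union of stream spans.
    """
    if resolution not in VALID_RESOLUTIONS:
        raise ValueError(f"resolution must be one of {VALID_RESOLUTIONS}")
    if not streams:
        raise ValueError("no streams to align")
    participants = {s.participant_id for s in streams}
    if len(participants) > 1:
        raise StreamError(f"streams from multiple participants: {sorted(participants)}")

    t_start = min(float(s.t[0]) for s in streams if len(s))
    t_end = max(float(s.t[-1]) for s in streams if len(s))
    # cells are anchored at t=0 so grids of different resolutions stay in phase
    t0 = np.floor(t_start / resolution) * resolution
    n_cells = int((t_end - t0) // resolution) + 1
    grid = t0 + resolution * np.arange(n_cells, dtype=float)

    spans = [(float(s.t[0]), float(s.t[-1])) for s in streams if len(s)]
    if len(spans) > 1:
        latest_start = max(a for a, _ in spans)
        earliest_end = min(b for _, b in spans)
        if latest_start > earliest_end:
            logger.warning(
                "streams have disjoint, non-overlapping spans; frame produced anyway"
            )

    frame = AlignedFrame(resolution=resolution, grid=grid)
    for s in streams:
        name = f"{s.parameter}: {s.platform}"
        idx = ((s.t - t0) // resolution).astype(int)
        sums = np.bincount(idx, weights=s.v, minlength=n_cells)
        counts = np.bincount(idx, minlength=n_cells)
        with np.errstate(invalid="ignore"):
            vals = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        frame.channels[name] = vals
    return frame
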