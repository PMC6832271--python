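"""Static rendering of benchmark outputs: exploratory pair panels, matrix
heat tables and DTW-style pair comparisons.

Each figure is regenerated deterministically from the run results (fixed
style, no timestamps in the files), so re-rendering a manifest reproduces
byte-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless, deterministic

import matplotlib.pyplot as plt
import numpy as np

from .benchmark_pipeline import BenchmarkMatrix, PairMetrics
from .signal_prep import ParameterSeries

logger = logging.getLogger(__name__)

_SAVE_KW = dict(dpi=110, metadata={"Software": None})


@dataclass
class ReportSpec:
    """What to render: filters default to everything available."""

    participants: list[str] | None = None
    pairs: list[str] | None = None
    statistics: tuple[str, ...] = ("r2", "mic", "dtw", "frechet_global")
    formats: tuple[str, ...] = ("png",)


def _slug(text: str) -> str:
    keep = [c if c.isalnum() else "_" for c in text]
    out = "".join(keep)
    while "__" in out:
        out = out.replace("__", "_")
    return out.strip("_")


def exploratory_panel(pair_key: str, participant: str,
                      metrics: PairMetrics | None,
                      x: ParameterSeries | None = None,
                      y: ParameterSeries | None = None,
                      x_mv: ParameterSeries | None = None,
                      y_mv: ParameterSeries | None = None,
                      outdir: str | Path = ".") -> Path | None:
    """Time plot + scatter (with OLS line and R^2) + cross-correlation stems.

    Missing results are skipped with a log entry rather than raising.
    """
    if metrics is None or x is None or y is None:
        logger.warning("%s / %s: no results, panel skipped", participant, pair_key)
        return None
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    fig, axes = plt.subplots(2, 2, figsize=(10, 7))
    ax = axes[0, 0]
    ax.plot(x.t / 1000.0, x.v, lw=0.8, label=x.name.render(), color="tab:blue")
    ax.plot(y.t / 1000.0, y.v, lw=0.8, label=y.name.render(), color="tab:red")
    ax.set_xlabel("time [s]")
    ax.set_ylabel("value (original scale)")
    ax.legend(fontsize=7)
    ax.set_title("time plot", fontsize=9)

    ax = axes[0, 1]
    n = min(len(x), len(y))
    xv, yv = x.v[:n], y.v[:n]
    ax.plot(xv, yv, ".", ms=2, alpha=0.5, color="tab:red")
    if np.std(xv) > 0:
        slope, intercept = np.polyfit(xv, yv, 1)
        xs = np.linspace(float(np.min(xv)), float(np.max(xv)), 50)
        ax.plot(xs, slope * xs + intercept, "k-", lw=1)
    r2_txt = "n/a" if metrics.r2 is None or not np.isfinite(metrics.r2) else f"{metrics.r2:.3f}"
    ax.set_title(f"scatter, R$^2$ = {r2_txt}", fontsize=9)
    ax.set_xlabel(x.name.render())
    ax.set_ylabel(y.name.render())

    for col, (series_pair, label) in enumerate(
            [((x, y), "as-is"), ((x_mv, y_mv), "mv. avg.")]):
        ax = axes[1, col]
        ccf = metrics.ccf
        if col == 1 and (x_mv is None or y_mv is None):
            ax.set_axis_off()
            continue
        if ccf is not None:
            ax.stem(ccf.lags, np.nan_to_num(ccf.coefficients), basefmt="k-")
            ax.set_ylim(-1.05, 1.05)
        ax.set_xlabel("lag [s]")
        ax.set_ylabel("r")
        ax.set_title(f"cross-correlation ({label})", fontsize=9)

    fig.suptitle(f"{participant}: {pair_key}", fontsize=10)
    fig.tight_layout()
    out = outdir / f"panel_{_slug(participant)}_{_slug(pair_key)}.png"
    fig.savefig(out, **_SAVE_KW)
    plt.close(fig)
    return out


def matrix_heat(matrix: BenchmarkMatrix, outdir: str | Path = ".",
                cmap: str | None = None) -> tuple[Path, Path]:
    """Heat table of a benchmark matrix plus the exact CSV it renders.

    The CSV (single source of truth) and the image share row/column order;
    missing cells render hatched grey and are excluded from the averages.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    disp = matrix.to_display_frame()
    csv_path = outdir / f"matrix_{matrix.statistic}.csv"
    disp.to_csv(csv_path, index_label="pair", float_format="%.10g")

    values = disp.to_numpy(dtype=float)
    if cmap is None:
        cmap = "RdYlBu_r" if not matrix.ascending else "viridis_r"
    fig_h = max(3.0, 0.28 * values.shape[0] + 1.5)
    fig_w = max(4.0, 0.5 * values.shape[1] + 2.5)
    fig, ax = plt.subplots(figsize=(fig_w, fig_h))
    masked = np.ma.masked_invalid(values)
    cm_obj = plt.get_cmap(cmap).copy()
    cm_obj.set_bad(color="0.85")
    im = ax.imshow(masked, aspect="auto", cmap=cm_obj)
    ax.set_xticks(range(values.shape[1]), disp.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(values.shape[0]), disp.index, fontsize=6)
    ax.set_title(f"{matrix.statistic} matrix", fontsize=10)
    fig.colorbar(im, ax=ax, shrink=0.7)
    fig.tight_layout()
    png_path = outdir / f"matrix_{matrix.statistic}.png"
    fig.savefig(png_path, **_SAVE_KW)
    plt.close(fig)
    return png_path, csv_path
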