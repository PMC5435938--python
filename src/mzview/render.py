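"""Figure output: stick spectrum plots with a summary block and top-N peak
labels, optionally stacked with a chromatogram panel and precursor panels.

Interactive hover labels are replaced by static annotations plus a JSON
sidecar (``<figure>.labels.json``) listing exactly which peaks were labeled,
so label placement is machine-checkable. Output format (PNG/SVG) follows the
file extension.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.backends.backend_svg import FigureCanvasSVG
from matplotlib.figure import Figure

from .model import Chromatogram, Spectrum

__all__ = ["plot_spectrum", "plot_with_context", "top_n_peaks", "sidecar_path"]


def top_n_peaks(spec: Spectrum, n: int) -> list[tuple[float, float]]:
    """The n most intense (m/z, intensity) pairs; ties go to lower m/z."""
    if n <= 0 or len(spec.peaks) == 0:
        return []
    pairs = sorted(
        zip(spec.peaks.mz.tolist(), spec.peaks.intensity.tolist()),
        key=lambda p: (-p[1], p[0]),
    )
    return pairs[:n]


def sidecar_path(out: Path | str) -> Path:
    return Path(str(out) + ".labels.json")


def _format_rt(rt_s: float) -> str:
    return f"{rt_s / 60.0:.4g} min ({rt_s:.6g} s)"


def _summary(spec: Spectrum) -> str:
    h = spec.header
    bp = spec.base_peak
    bp_text = f"{bp[0]:.4f} m/z @ {bp[1]:.4g}" if bp else "n/a"
    tic = f"{h.total_ion_current:.4g}" if h.total_ion_current is not None else "n/a"
    return (
        f"scan {h.scan_id}  |  MS{h.ms_level}  |  RT {_format_rt(h.retention_time_s)}\n"
        f"base peak {bp_text}  |  TIC {tic}"
    )


def _draw_spectrum(ax, spec: Spectrum, labels: Sequence[tuple[float, float]],
                   profile: bool = False) -> None:
    mz = spec.peaks.mz
    inten = spec.peaks.intensity
    if len(spec.peaks) == 0:
        ax.text(0.5, 0.5, "empty spectrum", ha="center", va="center",
                transform=ax.transAxes, fontsize=11, color="0.4")
        ax.set_xlim(0, 1)
        ax.set_ylim(0, 1)
    else:
        if profile:
            ax.plot(mz, inten, lw=0.8, color="tab:blue")
        else:
            ax.vlines(mz, 0.0, inten, lw=0.8, color="tab:blue")
        span = float(mz.max() - mz.min()) or 1.0
        ax.set_xlim(float(mz.min()) - 0.02 * span, float(mz.max()) + 0.02 * span)
        ax.set_ylim(bottom=0)
        for lmz, lint in labels:
            ax.annotate(
                f"({lmz:.4f}, {lint:.4g})",
                xy=(lmz, lint),
                xytext=(0, 4),
                textcoords="offset points",
                ha="center",
                fontsize=7,
            )
    ax.set_xlabel("m/z")
    ax.set_ylabel("intensity")


def _save(fig: Figure, out: Path) -> Path:
    out.parent.mkdir(parents=True, exist_ok=True)
    canvas = FigureCanvasSVG(fig) if out.suffix.lower() == ".svg" else FigureCanvasAgg(fig)
    fig.savefig(out)
    return out


def plot_spectrum(
    spec: Spectrum,
    label_top_n: int = 0,
    out: Path | str = "spectrum.png",
    profile: bool = False,
) -> Path:
    """Stick plot of one spectrum with its summary block.

    Labels the ``label_top_n`` most intense peaks with "(m/z, intensity)"
    and writes the label sidecar next to the figure.
    """
    out = Path(out)
    labels = top_n_peaks(spec, label_top_n)
    fig = Figure(figsize=(9, 4.5), dpi=110)
    ax = fig.add_subplot(111)
    _draw_spectrum(ax, spec, labels, profile=profile)
    ax.set_title(_summary(spec), fontsize=9, loc="left", family="monospace")
    fig.tight_layout()
    _save(fig, out)
    _write_sidecar(out, [{"mz": m, "intensity": i, "panel": 0} for m, i in labels],
                   panels=1)
    return out


def plot_with_context(
    spec: Spectrum,
    chrom: Optional[Chromatogram] = None,
    precursors: Sequence[Spectrum] = (),
    out: Path | str = "spectrum.png",
    label_top_n: int = 0,
    profile: bool = False,
) -> Path:
    """Multi-panel figure: optional chromatogram on top (with a marker at
    the shown scan's RT), the selected spectrum, then one panel per
    precursor ordered toward MS1."""
    out = Path(out)
    n_panels = 1 + (1 if chrom is not None else 0) + len(precursors)
    fig = Figure(figsize=(9, 2.8 * n_panels), dpi=110)
    axes = fig.subplots(n_panels, 1, squeeze=False)[:, 0]
    sidecar: list[dict] = []
    panel = 0
    if chrom is not None:
        ax = axes[panel]
        ax.plot(chrom.time_s, chrom.intensity, lw=1.0, color="tab:green")
        ax.axvline(spec.header.retention_time_s, color="tab:red", lw=0.9, ls="--")
        ax.set_xlabel("retention time (s)")
        ax.set_ylabel("intensity")
        ax.set_title(f"chromatogram: {chrom.chrom_id}", fontsize=9, loc="left")
        panel += 1
    labels = top_n_peaks(spec, label_top_n)
    _draw_spectrum(axes[panel], spec, labels, profile=profile)
    axes[panel].set_title(_summary(spec), fontsize=9, loc="left", family="monospace")
    sidecar.extend({"mz": m, "intensity": i, "panel": panel} for m, i in labels)
    panel += 1
    for prec in precursors:
        plabels = top_n_peaks(prec, label_top_n)
        _draw_spectrum(axes[panel], prec, plabels, profile=profile)
        axes[panel].set_title("precursor " + _summary(prec), fontsize=9,
                              loc="left", family="monospace")
        sidecar.extend({"mz": m, "intensity": i, "panel": panel}
                       for m, i in plabels)
        panel += 1
    fig.tight_layout()
    _save(fig, out)
    _write_sidecar(out, sidecar, panels=n_panels)
    return out


def _write_sidecar(out: Path, labels: list[dict], panels: int) -> None:
    sidecar_path(out).write_text(
        json.dumps({"panels": panels, "labels": labels}), encoding="utf-8"
    )
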