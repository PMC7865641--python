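"""Plotting helpers: QC overlays and concentration-series figures.

Matplotlib with the Agg backend; every function writes a PNG/SVG path and
returns the figure for further tweaking.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .array_qc import QCReport, STATUS_OK
from .chip_io import ChipImageSet
from .conc_opt import ConcentrationSeries

_STATUS_COLORS = {
    "missing": "red",
    "low_density": "orange",
    "saturated": "magenta",
    "irregular": "yellow",
}


def qc_overlay(image_set: ChipImageSet, report: QCReport, path=None):
    """Annotated chip image: flagged spots circled by status color."""
    fig, ax = plt.subplots(figsize=(8, 5))
    img = image_set.images.astype(float).mean(axis=0)
    ax.imshow(img, cmap="gray", interpolation="nearest")
    r = image_set.layout.spot_radius_px
    for _, row in report.spots.iterrows():
        if row.blank or row.status == STATUS_OK:
            continue
        circ = plt.Circle(
            (row.centroid_x_px, row.centroid_y_px), 1.4 * r,
            fill=False, color=_STATUS_COLORS.get(row.status, "cyan"), lw=1.5,
        )
        ax.add_patch(circ)
        ax.annotate(row.status, (row.centroid_x_px, row.centroid_y_px - 1.6 * r),
                    color=_STATUS_COLORS.get(row.status, "cyan"), fontsize=6,
                    ha="center")
    ax.set_title(f"chip QC: {report.verdict}")
    ax.set_axis_off()
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def mass_vs_concentration(series_list: list[ConcentrationSeries], path=None):
    """Immobilized mass vs spotting concentration, one line per probe."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for s in series_list:
        err = s.mass_sd if s.mass_sd is not None else None
        ax.errorbar(s.concentrations_um, s.mass_ng_mm2, yerr=err,
                    marker="o", capsize=3, label=f"{s.probe} ({s.chemistry})")
    ax.set_xlabel("spotting concentration (uM)")
    ax.set_ylabel("immobilized mass (ng/mm$^2$)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def signal_vs_concentration(series_list: list[ConcentrationSeries], path=None):
    """End-of-association binding signal vs spotting concentration."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for s in series_list:
        if s.binding_signal is None:
            continue
        err = s.binding_sd if s.binding_sd is not None else None
        ax.errorbar(s.concentrations_um, s.binding_signal, yerr=err,
                    marker="s", capsize=3, label=s.probe)
    ax.set_xlabel("spotting concentration (uM)")
    ax.set_ylabel("binding signal (ng/mm$^2$)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def binding_curves(curves: dict, schedule=None, path=None):
    """Sensorgram panel: replicate-averaged mass vs time per probe."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for probe, c in sorted(curves.items()):
        ax.plot(c.times_s / 60.0, c.mass_mean, label=probe, lw=1.2)
    if schedule is not None:
        for ph in schedule.injections:
            ax.axvspan(ph.start_s / 60.0, ph.end_s / 60.0, alpha=0.08, color="tab:blue")
    ax.set_xlabel("time (min)")
    ax.set_ylabel("bound mass (ng/mm$^2$)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
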