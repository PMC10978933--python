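"""Static QC figures: plate grids, fluctuation lines, heatmaps and
control charts, faceted the way the downloadable report bundles them
(per-plate grids over antigens; per-antigen grids over controls)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import ListedColormap

from mbaqc.bead_qc import BeadQCConfig, classify_counts, fluctuation_series
from mbaqc.control import ControlTrackingResult
from mbaqc.io import WELL_ROWS, PlateData
from mbaqc.mfi_qc import MfiQCConfig, flag_mfi, heatmap_matrix

_FLAG_COLORS = {"pass": "#d9ead3", "warn": "#ffe599", "fail": "#ea9999",
                "none": "#d9ead3", "yellow": "#ffe599", "red": "#ea9999"}


def _plate_axes(ax, title: str) -> None:
    ax.set_xlim(0.5, 12.5)
    ax.set_ylim(8.5, 0.5)
    ax.set_xticks(range(1, 13))
    ax.set_yticks(range(1, 9))
    ax.set_yticklabels(list(WELL_ROWS), fontsize=6)
    ax.tick_params(labelsize=6)
    ax.set_title(title, fontsize=8)


def _draw_plate(ax, sub, flag_col: str, label_col: str, title: str) -> None:
    _plate_axes(ax, title)
    for _, rec in sub.iterrows():
        r = WELL_ROWS.index(rec["well_row"]) + 1
        c = int(rec["well_col"])
        color = _FLAG_COLORS.get(rec[flag_col], "#ffffff")
        ax.add_patch(plt.Rectangle((c - 0.5, r - 0.5), 1, 1, facecolor=color,
                                   edgecolor="gray", linewidth=0.3))
        val = rec[label_col]
        label = f"{val:.0f}" if isinstance(val, float) else str(val)
        ax.text(c, r, label, ha="center", va="center", fontsize=4)


def bead_plate_figure(plate: PlateData, cfg: BeadQCConfig | None = None):
    """96-well bead-count plate plot, faceted by antigen; red below the
    lower threshold, yellow below the upper."""
    cfg = cfg or BeadQCConfig()
    antigens = plate.antigens
    fig, axes = plt.subplots(1, len(antigens), figsize=(4.2 * len(antigens), 3.2),
                             squeeze=False)
    for ax, antigen in zip(axes[0], antigens):
        sub = plate.records[plate.records["antigen"] == antigen].copy()
        sub["bead_flag"] = classify_counts(sub["bead_count"], cfg).to_numpy()
        _draw_plate(ax, sub, "bead_flag", "bead_count",
                    f"{plate.metadata.batch_name} — {antigen}")
    fig.tight_layout()
    return fig


def fluctuation_figure(plate: PlateData, cfg: BeadQCConfig | None = None):
    """Bead counts by instrument read order with threshold and mean lines."""
    cfg = cfg or BeadQCConfig()
    antigens = plate.antigens
    fig, axes = plt.subplots(len(antigens), 1, figsize=(6, 2.0 * len(antigens)),
                             squeeze=False, sharex=True)
    for ax, antigen in zip(axes[:, 0], antigens):
        series = fluctuation_series(plate, antigen, cfg)
        pts = series.points
        ax.plot(pts["read_order"], pts["bead_count"], "-", color="0.5", lw=0.7)
        fails = pts[pts["bead_flag"] == "fail"]
        ax.plot(pts["read_order"], pts["bead_count"], ".", color="0.3", ms=3)
        ax.plot(fails["read_order"], fails["bead_count"], "o", color="red", ms=4)
        ax.axhline(series.thresholds[1], color="green", lw=0.8)
        ax.axhline(series.thresholds[0], color="red", lw=0.8)
        ax.axhline(series.mean_count, color="blue", lw=0.8)
        ax.set_ylabel("beads/well", fontsize=7)
        ax.set_title(f"{plate.metadata.batch_name} — {antigen}", fontsize=8)
        ax.tick_params(labelsize=6)
    axes[-1, 0].set_xlabel("read order", fontsize=7)
    fig.tight_layout()
    return fig


def mfi_plate_figure(plate: PlateData, cfg: MfiQCConfig | None = None):
    """96-well net-MFI plate plot faceted by antigen: red at/below plate
    background, yellow at/below the warning level."""
    cfg = cfg or MfiQCConfig()
    antigens = plate.antigens
    fig, axes = plt.subplots(1, len(antigens), figsize=(4.2 * len(antigens), 3.2),
                             squeeze=False)
    for ax, antigen in zip(axes[0], antigens):
        flags = flag_mfi(plate, antigen, cfg)
        _draw_plate(ax, flags, "mfi_flag", "net_mfi",
                    f"{plate.metadata.batch_name} — {antigen}")
    fig.tight_layout()
    return fig


def heatmap_figure(plate: PlateData):
    """Log10 raw-MFI heatmaps faceted by antigen; absent cells gray "NA"."""
    antigens = plate.antigens
    fig, axes = plt.subplots(1, len(antigens), figsize=(4.4 * len(antigens), 3.2),
                             squeeze=False)
    for ax, antigen in zip(axes[0], antigens):
        hm = heatmap_matrix(plate, antigen)
        masked = np.ma.masked_invalid(hm.grid)
        cmap = plt.get_cmap("viridis").copy()
        cmap.set_bad("#bbbbbb")
        im = ax.imshow(masked, cmap=cmap, aspect="auto",
                       extent=(0.5, 12.5, 8.5, 0.5))
        _plate_axes(ax, f"{plate.metadata.batch_name} — {antigen}")
        for r in range(8):
            for c in range(12):
                raw = hm.annotations[r, c]
                label = "NA" if np.isnan(raw) else f"{raw:.0f}"
                ax.text(c + 1, r + 1, label, ha="center", va="center",
                        fontsize=4, color="white")
        fig.colorbar(im, ax=ax, label="log10 MFI")
    fig.tight_layout()
    return fig


def control_tracking_figure(results: list[ControlTrackingResult], antigen: str):
    """Control charts for one antigen, faceted by control: individual values
    against the center line and 1/2/3-sigma limits, plus the MR chart when
    the method is I-MR."""
    results = [r for r in results if r.series.antigen == antigen]
    if not results:
        raise ValueError(f"no tracked controls for antigen {antigen!r}")
    with_mr = any(r.mr_chart is not None for r in results)
    ncols = 2 if with_mr else 1
    fig, axes = plt.subplots(len(results), ncols,
                             figsize=(5.5 * ncols, 2.2 * len(results)),
                             squeeze=False)
    for i, res in enumerate(results):
        ax = axes[i, 0]
        pts = res.verdicts
        ax.plot(pts["observation"], pts["value"], "-", color="0.6", lw=0.7)
        colors = pts["status"].map(
            {"in_control": "0.2", "cl2_warning": "orange", "out_of_control": "red"}
        )
        ax.scatter(pts["observation"], pts["value"], c=colors, s=12, zorder=3)
        lim = res.limits
        ax.axhline(lim.center, color="blue", lw=0.8)
        for k, style in ((1, ":"), (2, "--"), (3, "-")):
            for bound in (lim.upper(k), lim.lower(k)):
                ax.axhline(bound, color="0.4", lw=0.6, linestyle=style)
        ax.set_title(f"{res.series.control} — {antigen} ({res.spec.method})",
                     fontsize=8)
        ax.tick_params(labelsize=6)
        ax.set_ylabel("control MFI-bkg", fontsize=7)
        if with_mr:
            axm = axes[i, 1]
            if res.mr_chart is not None:
                mr = res.mr_chart
                axm.plot(mr.points["observation"], mr.points["mr"], ".-",
                         color="0.4", lw=0.7, ms=3)
                flagged = mr.points[mr.points["out_of_control"]]
                axm.plot(flagged["observation"], flagged["mr"], "o", color="red", ms=4)
                axm.axhline(mr.mean_mr, color="blue", lw=0.8)
                axm.axhline(mr.ucl, color="red", lw=0.8)
                axm.set_title("moving range", fontsize=8)
                axm.tick_params(labelsize=6)
            else:
                axm.axis("off")
    axes[-1, 0].set_xlabel("observation", fontsize=7)
    fig.tight_layout()
    return fig
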