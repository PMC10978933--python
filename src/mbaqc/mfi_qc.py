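"""MFI quality control relative to the plate background.

Each plate carries dedicated background wells (buffer only).  A well is
flagged **red** when its raw MFI is at or below the plate background for
that antigen — with multiple background wells the highest background MFI
sets the threshold — and **yellow** when it is above background but its
background-subtracted MFI is at or below a user "warning" level (default
100 MFI).  Red takes precedence, so no well is both.

Column- or row-wise blocks of red wells across antigens typically indicate
pipetting errors (e.g. a missed detection-reagent column).  There is no
MFI-based plate pass/fail verdict; the flags support visual review only.

Heatmaps use the raw MFI (no background subtraction) on a log10 scale so
that negative net values cannot produce undefined cells; non-positive or
missing MFI renders as an absent (NA) cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from mbaqc.errors import NoBackgroundWellError, UnknownAntigenError
from mbaqc.io import WELL_ROWS, PlateData


@dataclass(frozen=True)
class MfiQCConfig:
    """MFI flagging parameters (arbitrary fluorescence units)."""

    warning_mfi: float = 100.0

    def __post_init__(self) -> None:
        if self.warning_mfi < 0:
            raise ValueError("warning_mfi must be non-negative")


def _antigen_records(plate: PlateData, antigen: str) -> pd.DataFrame:
    sub = plate.records[plate.records["antigen"] == antigen]
    if sub.empty:
        raise UnknownAntigenError(
            f"antigen {antigen!r} not on plate {plate.metadata.batch_name!r}; "
            f"available: {', '.join(plate.antigens)}"
        )
    return sub


def plate_background(plate: PlateData, antigen: str) -> float:
    """Background MFI threshold for one plate/antigen.

    With multiple background wells the well with the highest MFI sets the
    threshold.  Raises :class:`NoBackgroundWellError` when the plate has no
    background-role well, in which case MFI flagging must be skipped or a
    background supplied.
    """
    sub = _antigen_records(plate, antigen)
    bg = sub[sub["role"] == "background"]
    if bg.empty:
        raise NoBackgroundWellError(
            f"plate {plate.metadata.batch_name!r} has no background well; "
            "label a background well or skip MFI flagging"
        )
    return float(bg["mfi"].max())


def flag_mfi(
    plate: PlateData, antigen: str, cfg: MfiQCConfig | None = None
) -> pd.DataFrame:
    """Per-well MFI flags (red / yellow / none) for one plate/antigen.

    Red: raw MFI at or below the plate background (inclusive); background
    wells themselves are red by definition.  Yellow: above background but
    background-subtracted MFI at or below ``warning_mfi`` (inclusive).
    The returned frame carries ``mfi``, the background-based ``net_mfi``
    shown on plate plots, and ``mfi_flag``.
    """
    cfg = cfg or MfiQCConfig()
    sub = _antigen_records(plate, antigen).copy()
    bg = plate_background(plate, antigen)
    net = sub["mfi"] - bg
    flags = np.where(
        sub["mfi"] <= bg, "red", np.where(net <= cfg.warning_mfi, "yellow", "none")
    )
    out = sub[["well", "well_row", "well_col", "sample_id", "role", "mfi"]].copy()
    out["net_mfi"] = net
    out["background_mfi"] = bg
    out["mfi_flag"] = flags
    return out.reset_index(drop=True)


@dataclass
class HeatmapMatrix:
    """8x12 grid of log10(raw MFI); NaN marks absent/non-positive cells."""

    batch_name: str
    antigen: str
    grid: np.ndarray  # shape (8, 12), log10 MFI
    annotations: np.ndarray  # shape (8, 12), raw MFI (NaN where absent)


def heatmap_matrix(plate: PlateData, antigen: str) -> HeatmapMatrix:
    """Log-scale plate heatmap for one antigen.

    Cells hold log10 of the raw MFI (no background subtraction); wells with
    no data or non-positive MFI are absent (NaN, rendered as gray "NA").
    The annotation grid carries the raw MFI for numeric labelling.
    """
    sub = _antigen_records(plate, antigen)
    grid = np.full((8, 12), np.nan)
    raw = np.full((8, 12), np.nan)
    for _, rec in sub.iterrows():
        r = WELL_ROWS.index(rec["well_row"])
        c = int(rec["well_col"]) - 1
        mfi = rec["mfi"]
        if pd.notna(mfi):
            raw[r, c] = mfi
            if mfi > 0:
                grid[r, c] = np.log10(mfi)
    return HeatmapMatrix(
        batch_name=plate.metadata.batch_name, antigen=antigen, grid=grid,
        annotations=raw,
    )
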