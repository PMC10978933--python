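"""Bead-count quality control.

Low bead counts per well reduce the statistical reliability of the median
fluorescence estimate; they arise from pipetting errors, bead aggregation
or instrument clogging.  Wells are flagged against two thresholds:

* ``fail`` (red)  — count strictly below the lower threshold (default 20);
* ``warn`` (yellow) — count at/above the lower but strictly below the
  upper threshold (default 35, the vendor-recommended minimum);
* ``pass`` — count at or above the upper threshold.

A plate fails for an antigen when the fraction of failed wells reaches the
plate-failure fraction (default 0.30, inclusive).  Flags are computed per
antigen and never pooled across antigens; the per-plate summary then lists
the antigens that failed on each plate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from mbaqc.errors import EmptyDatasetError, UnknownAntigenError
from mbaqc.io import PlateData


@dataclass(frozen=True)
class BeadQCConfig:
    """Thresholds for bead-count flagging (beads/well)."""

    lower_threshold: int = 20
    upper_threshold: int = 35
    plate_fail_fraction: float = 0.30
    #: when False, only control/unknown wells enter the plate-failure
    #: denominator; standards and backgrounds are still flagged per well
    include_all_roles: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.lower_threshold <= self.upper_threshold):
            raise ValueError("need 0 <= lower_threshold <= upper_threshold")
        if not (0.0 <= self.plate_fail_fraction <= 1.0):
            raise ValueError("plate_fail_fraction must be within [0, 1]")


def classify_counts(counts: pd.Series | np.ndarray, cfg: BeadQCConfig) -> pd.Series:
    """Vectorised pass/warn/fail partition of bead counts."""
    counts = pd.Series(np.asarray(counts))
    flags = pd.Series("pass", index=counts.index, dtype=object)
    flags[counts < cfg.upper_threshold] = "warn"
    flags[counts < cfg.lower_threshold] = "fail"
    return flags


def flag_bead_counts(ds: pd.DataFrame, cfg: BeadQCConfig | None = None) -> pd.DataFrame:
    """Attach a ``bead_flag`` column (pass/warn/fail) to every record."""
    if ds is None or len(ds) == 0:
        raise EmptyDatasetError("cannot flag an empty dataset")
    cfg = cfg or BeadQCConfig()
    out = ds.copy()
    out["bead_flag"] = classify_counts(out["bead_count"], cfg).to_numpy()
    return out


def summarize_bead_qc(
    flagged: pd.DataFrame, cfg: BeadQCConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The two plate-level bead summaries.

    Returns ``(per_antigen, per_plate)``:

    * ``per_antigen`` — one row per (batch, antigen): number of wells with
      data, number and fraction failed, and the plate-failure call
      (fraction_failed >= plate_fail_fraction, inclusive).  Wells with no
      data for an antigen are excluded from the denominator.
    * ``per_plate`` — one row per batch: the list and count of antigens
      that failed on that plate.
    """
    cfg = cfg or BeadQCConfig()
    df = flagged
    if not cfg.include_all_roles:
        df = df[df["role"].isin(["control", "unknown"])]
    df = df[df["bead_count"].notna()]

    grouped = df.groupby(["batch_name", "antigen"], sort=True)
    per_antigen = grouped.agg(
        n_wells=("bead_flag", "size"),
        n_failed=("bead_flag", lambda s: int((s == "fail").sum())),
        n_warn=("bead_flag", lambda s: int((s == "warn").sum())),
    ).reset_index()
    per_antigen["fraction_failed"] = per_antigen["n_failed"] / per_antigen["n_wells"]
    per_antigen["plate_failed"] = per_antigen["fraction_failed"] >= cfg.plate_fail_fraction

    rows = []
    for batch, sub in per_antigen.groupby("batch_name", sort=True):
        failed = sorted(sub.loc[sub["plate_failed"], "antigen"])
        rows.append(
            {
                "batch_name": batch,
                "failed_antigens": ";".join(failed),
                "n_failed_antigens": len(failed),
            }
        )
    per_plate = pd.DataFrame(rows)
    return per_antigen, per_plate


@dataclass
class FluctuationSeries:
    """Bead counts of one plate/antigen in instrument read order."""

    batch_name: str
    antigen: str
    points: pd.DataFrame  # read_order, well, bead_count, bead_flag
    mean_count: float
    thresholds: tuple[int, int]  # (lower, upper)


def fluctuation_series(
    plate: PlateData, antigen: str, cfg: BeadQCConfig | None = None
) -> FluctuationSeries:
    """Per-well bead counts ordered by instrument read order, with the
    reference values (thresholds, mean count) drawn on the fluctuation plot."""
    cfg = cfg or BeadQCConfig()
    sub = plate.records[plate.records["antigen"] == antigen]
    if sub.empty:
        raise UnknownAntigenError(
            f"antigen {antigen!r} not on plate {plate.metadata.batch_name!r}; "
            f"available: {', '.join(plate.antigens)}"
        )
    pts = sub[["read_order", "well", "bead_count"]].sort_values("read_order")
    pts = pts.reset_index(drop=True)
    pts["bead_flag"] = classify_counts(pts["bead_count"], cfg).to_numpy()
    return FluctuationSeries(
        batch_name=plate.metadata.batch_name,
        antigen=antigen,
        points=pts,
        mean_count=float(pts["bead_count"].mean()),
        thresholds=(cfg.lower_threshold, cfg.upper_threshold),
    )
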