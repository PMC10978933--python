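"""Synthetic multi-plate study generator with injectable anomalies.

Emulates a multi-antigen serosurveillance study run on 96-well plates: a
10-step threefold standard curve in singlet, four named assay controls,
background wells and 38 study samples, with controls, background and
samples in duplicate (10 + 2 x 43 = 96 occupied wells).  Baseline MFI is
lognormal per well role and antigen; bead counts are negative-binomial.

Anomalies mirror the failure modes a QC pipeline must catch:

* ``low_bead_bias`` — bead counts on whole plates biased low (clogging);
* ``row_artifact`` / ``column_artifact`` — a full plate row/column forced
  to MFI at or below the plate background across antigens (pipetting
  error);
* ``control_shift`` — one control's MFI multiplied on selected plates,
  biasing the control-tracking charts toward flagging those points.

Every injected anomaly is recorded in ground-truth tables together with
the flag it should receive from the corresponding QC module at default
configuration.  Generation is deterministic: identical (spec, anomalies,
seed) produce byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from mbaqc.io import (
    RECORD_COLUMNS,
    WELL_ROWS,
    PlateData,
    PlateMetadata,
    RoleConfig,
    parse_xponent,
    write_xponent,
)

_KIND_CODES = {
    "low_bead_bias": 1,
    "row_artifact": 2,
    "column_artifact": 3,
    "control_shift": 4,
}


@dataclass(frozen=True)
class SyntheticStudySpec:
    """Recipe for one synthetic study.

    ``antigen_presence`` maps antigen name to the 1-based plate numbers
    carrying it (``None`` = all plates).  The default three-antigen panel
    places antigen-1 on plates 1-29, antigen-2 on plates 14-32 and
    antigen-3 on every plate, reproducing an unequal 29/19/32 coverage.
    """

    n_plates: int = 32
    antigens: tuple[str, ...] = ("antigen-1", "antigen-2", "antigen-3")
    antigen_presence: dict | None = None
    n_standards: int = 10
    standard_top_mfi: float = 30000.0
    standard_dilution: float = 3.0
    control_names: tuple[str, ...] = ("neg", "pos800", "pos2400", "pos7200")
    control_mfi: dict = field(
        default_factory=lambda: {
            "neg": 60.0,
            "pos800": 9000.0,
            "pos2400": 3500.0,
            "pos7200": 1200.0,
        }
    )
    n_samples: int = 38
    sample_log10_mean: float = 2.7
    sample_log10_sd: float = 0.6
    background_mfi: float = 30.0
    noise_sd: float = 0.05  # lognormal sigma of multiplicative well noise
    bead_mean: float = 80.0
    bead_shape: float = 50.0  # negative-binomial size parameter
    duplicate_background: bool = True
    start: datetime = datetime(2023, 1, 5, 9, 30)
    interval_hours: float = 24.0
    instrument_serial: str = "LX200-12345"
    seed: int = 1

    def presence(self, antigen: str) -> tuple[int, ...]:
        if self.antigen_presence and antigen in self.antigen_presence:
            return tuple(self.antigen_presence[antigen])
        defaults = {
            "antigen-1": tuple(range(1, min(29, self.n_plates) + 1)),
            "antigen-2": tuple(range(max(1, self.n_plates - 18), self.n_plates + 1)),
        }
        if self.antigens == ("antigen-1", "antigen-2", "antigen-3") and antigen in defaults:
            return defaults[antigen]
        return tuple(range(1, self.n_plates + 1))

    def plate_antigens(self, plate_no: int) -> list[str]:
        return [a for a in self.antigens if plate_no in self.presence(a)]


@dataclass(frozen=True)
class AnomalySpec:
    """One injected anomaly and its magnitude parameters.

    ``control=None`` for ``control_shift`` rotates the shifted control over
    the spec's control names, one per target plate.
    """

    kind: str
    target_plates: tuple[int, ...]
    bead_factor: float = 0.18  # low_bead_bias count multiplier
    rows: tuple[str, ...] = ("D",)  # row_artifact
    columns: tuple[int, ...] = (5,)  # column_artifact
    control: str | None = None  # control_shift
    shift_factor: float = 6.0  # control_shift MFI multiplier

    def __post_init__(self) -> None:
        if self.kind not in _KIND_CODES:
            raise ValueError(f"unknown anomaly kind {self.kind!r}")


def default_anomalies() -> list[AnomalySpec]:
    """The demonstration anomaly set for a 32-plate study: two low-bead
    plates (10, 25), a row artifact on plate 1, a column artifact on plate
    2 and shifted controls on plates 7, 11, 14 and 29."""
    return [
        AnomalySpec(kind="low_bead_bias", target_plates=(10, 25)),
        AnomalySpec(kind="row_artifact", target_plates=(1,), rows=("D",)),
        AnomalySpec(kind="column_artifact", target_plates=(2,), columns=(5,)),
        AnomalySpec(kind="control_shift", target_plates=(7, 11, 14, 29)),
    ]


def _plate_layout(spec: SyntheticStudySpec) -> list[str]:
    """Sample IDs in read order (row-major A1..H12)."""
    ids = [f"Standard{i}" for i in range(1, spec.n_standards + 1)]
    for name in spec.control_names:
        ids += [name, name]
    ids += ["Background1"] * (2 if spec.duplicate_background else 1)
    for i in range(1, spec.n_samples + 1):
        ids += [f"Unk{i:02d}", f"Unk{i:02d}"]
    if len(ids) > 96:
        raise ValueError(f"layout needs {len(ids)} wells; a plate has 96")
    return ids


def _well_of(position: int) -> tuple[str, int]:
    """1-based read-order position -> (row letter, column) row-major."""
    return WELL_ROWS[(position - 1) // 12], (position - 1) % 12 + 1


def _generate_plate(spec: SyntheticStudySpec, plate_no: int) -> pd.DataFrame:
    rng = np.random.default_rng([spec.seed, plate_no])
    roles = RoleConfig(control_names=spec.control_names)
    ids = _plate_layout(spec)
    antigens = spec.plate_antigens(plate_no)
    rows = []
    # per-sample latent level shared by duplicates, per antigen
    for antigen in antigens:
        levels: dict[str, float] = {}
        for i in range(1, spec.n_standards + 1):
            levels[f"Standard{i}"] = spec.standard_top_mfi / spec.standard_dilution ** (i - 1)
        for name in spec.control_names:
            levels[name] = float(spec.control_mfi[name])
        levels["Background1"] = spec.background_mfi
        for i in range(1, spec.n_samples + 1):
            levels[f"Unk{i:02d}"] = 10.0 ** rng.normal(spec.sample_log10_mean, spec.sample_log10_sd)
        for position, sid in enumerate(ids, start=1):
            well_row, well_col = _well_of(position)
            mfi = levels[sid] * rng.lognormal(0.0, spec.noise_sd)
            p = spec.bead_shape / (spec.bead_shape + spec.bead_mean)
            count = int(rng.negative_binomial(spec.bead_shape, p))
            rows.append(
                {
                    "well": f"{well_row}{well_col}",
                    "well_row": well_row,
                    "well_col": well_col,
                    "sample_id": sid,
                    "role": roles.role_of(sid),
                    "antigen": antigen,
                    "mfi": round(mfi, 1),
                    "bead_count": count,
                    "read_order": position,
                }
            )
    return pd.DataFrame(rows)


def _recompute_net(records: pd.DataFrame) -> pd.DataFrame:
    """net MFI = raw MFI minus the highest background-well MFI per antigen."""
    out = records.copy()
    bg = (
        out[out["role"] == "background"]
        .groupby("antigen")["mfi"]
        .max()
    )
    out["net_mfi"] = (out["mfi"] - out["antigen"].map(bg)).round(1)
    return out


_BEAD_TRUTH_COLS = ["batch_name", "well", "antigen", "bead_count", "expected_flag"]
_MFI_TRUTH_COLS = ["batch_name", "well", "antigen", "expected_flag"]
_CONTROL_TRUTH_COLS = ["batch_name", "control", "antigen", "shift_factor", "expected_flag"]


def _apply_anomaly(
    records: pd.DataFrame,
    a: AnomalySpec,
    spec: SyntheticStudySpec,
    plate_no: int,
    batch_name: str,
) -> tuple[pd.DataFrame, dict[str, list[dict]]]:
    """Apply one anomaly in place (on a copy); return records + truth rows."""
    rng = np.random.default_rng([spec.seed, plate_no, _KIND_CODES[a.kind]])
    truth: dict[str, list[dict]] = {"bead": [], "mfi": [], "control": []}
    rec = records.copy()

    if a.kind == "low_bead_bias":
        rec["bead_count"] = np.floor(rec["bead_count"] * a.bead_factor).astype(int)
        for _, r in rec.iterrows():
            flag = (
                "fail" if r["bead_count"] < 20 else
                "warn" if r["bead_count"] < 35 else "pass"
            )
            truth["bead"].append(
                {
                    "batch_name": batch_name,
                    "well": r["well"],
                    "antigen": r["antigen"],
                    "bead_count": int(r["bead_count"]),
                    "expected_flag": flag,
                }
            )

    elif a.kind in ("row_artifact", "column_artifact"):
        if a.kind == "row_artifact":
            target = rec["well_row"].isin(a.rows)
        else:
            target = rec["well_col"].isin(a.columns)
        target &= rec["role"] != "background"  # keep the background threshold intact
        bg = rec[rec["role"] == "background"].groupby("antigen")["mfi"].max()
        for antigen, bg_mfi in bg.items():
            mask = target & (rec["antigen"] == antigen)
            u = rng.uniform(0.2, 0.95, size=int(mask.sum()))
            rec.loc[mask, "mfi"] = np.floor(bg_mfi * u * 10) / 10  # floor: stay <= bg
            for well in rec.loc[mask, "well"]:
                truth["mfi"].append(
                    {
                        "batch_name": batch_name,
                        "well": well,
                        "antigen": antigen,
                        "expected_flag": "red",
                    }
                )

    elif a.kind == "control_shift":
        plates = sorted(a.target_plates)
        if a.control is not None:
            control = a.control
        else:  # rotate over the named controls, one per target plate
            pos = plates.index(plate_no) if plate_no in plates else 0
            control = spec.control_names[pos % len(spec.control_names)]
        mask = rec["sample_id"].str.lower() == control.lower()
        rec.loc[mask, "mfi"] = (rec.loc[mask, "mfi"] * a.shift_factor).round(1)
        for antigen in rec.loc[mask, "antigen"].unique():
            truth["control"].append(
                {
                    "batch_name": batch_name,
                    "control": control,
                    "antigen": antigen,
                    "shift_factor": a.shift_factor,
                    "expected_flag": "out_of_control",
                }
            )

    return rec, truth


def generate_study(
    spec: SyntheticStudySpec,
    anomalies: list[AnomalySpec] | None = None,
    out_dir: str | Path = ".",
) -> tuple[list[Path], dict[str, pd.DataFrame]]:
    """Generate one study: one xPONENT-dialect CSV per plate (monotone run
    date-times) plus ground-truth tables for every injected anomaly.

    Returns ``(paths, ground_truth)`` with ground-truth keys ``"bead"``,
    ``"mfi"`` and ``"control"``; the tables are also written as CSVs next
    to the plate files.  Anomalies targeting nonexistent plates raise
    ``ValueError``.
    """
    anomalies = anomalies or []
    for a in anomalies:
        bad = [p for p in a.target_plates if not (1 <= p <= spec.n_plates)]
        if bad:
            raise ValueError(
                f"anomaly {a.kind!r} targets nonexistent plate(s) {bad}; "
                f"the study has {spec.n_plates} plates"
            )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    truth: dict[str, list[dict]] = {"bead": [], "mfi": [], "control": []}
    for plate_no in range(1, spec.n_plates + 1):
        batch_name = f"plate {plate_no}"
        records = _generate_plate(spec, plate_no)
        for a in anomalies:
            if plate_no in a.target_plates:
                records, t = _apply_anomaly(records, a, spec, plate_no, batch_name)
                for key in truth:
                    truth[key].extend(t[key])
        records = _recompute_net(records)
        metadata = PlateMetadata(
            batch_name=batch_name,
            batch_datetime=spec.start + timedelta(hours=spec.interval_hours * (plate_no - 1)),
            instrument_serial=spec.instrument_serial,
            source_file=f"plate_{plate_no:02d}.csv",
            plate_format=96,
        )
        plate = PlateData(metadata=metadata, records=records[RECORD_COLUMNS])
        paths.append(write_xponent(plate, out_dir / metadata.source_file))

    ground_truth = {
        "bead": pd.DataFrame(truth["bead"], columns=_BEAD_TRUTH_COLS),
        "mfi": pd.DataFrame(truth["mfi"], columns=_MFI_TRUTH_COLS),
        "control": pd.DataFrame(truth["control"], columns=_CONTROL_TRUTH_COLS),
    }
    for key, frame in ground_truth.items():
        frame.to_csv(out_dir / f"ground_truth_{key}.csv", index=False)
    return paths, ground_truth


def inject_anomaly(
    path: str | Path,
    anomalies: list[AnomalySpec],
    spec: SyntheticStudySpec | None = None,
    plate_no: int = 1,
    out_path: str | Path | None = None,
) -> tuple[Path, dict[str, pd.DataFrame]]:
    """Apply anomalies to an existing plate file (parse, modify, rewrite).

    With an empty anomaly list the file is rewritten unchanged (byte-for-
    byte, since the dialect serializer is stable).  Returns the output path
    and the ground-truth rows of the modifications.
    """
    spec = spec or SyntheticStudySpec()
    path = Path(path)
    out_path = Path(out_path) if out_path else path
    plate = parse_xponent(path, RoleConfig(control_names=spec.control_names))
    records = plate.records
    truth: dict[str, list[dict]] = {"bead": [], "mfi": [], "control": []}
    for a in anomalies:
        records, t = _apply_anomaly(records, a, spec, plate_no, plate.metadata.batch_name)
        for key in truth:
            truth[key].extend(t[key])
    if anomalies:
        records = _recompute_net(records)
    plate = PlateData(metadata=plate.metadata, records=records[RECORD_COLUMNS])
    write_xponent(plate, out_path)
    ground_truth = {
        "bead": pd.DataFrame(truth["bead"], columns=_BEAD_TRUTH_COLS),
        "mfi": pd.DataFrame(truth["mfi"], columns=_MFI_TRUTH_COLS),
        "control": pd.DataFrame(truth["control"], columns=_CONTROL_TRUTH_COLS),
    }
    return out_path, ground_truth
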