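"""Read, validate, merge and export Luminex-style plate data.

Two single-plate input dialects are supported, both restricted to 96-well
runs:

* **xPONENT-style CSV** — a small metadata header (``Batch``, ``Date``,
  ``SN``, ``PlateFormat``) followed by three labelled blocks, each
  introduced by a ``DataType:`` marker line: ``Median`` (MFI), ``Net MFI``
  and ``Count``.  Each block has one row per well with a well-location
  column, a sample-ID column and one column per antigen.  The exact
  dialect is documented in ``docs/formats.md``; the parser additionally
  tolerates quoted fields, a UTF-8 byte-order mark and trailing empty
  lines.
* **Bio-Plex-Manager-style workbook** — an ``.xlsx`` file in the
  multiple-analyte layout with the sheets ``FI``, ``FI—Bkgd`` and
  ``Bead Count`` (dash variants accepted).

Parsed plates are merged into the canonical long-format dataset: a pandas
``DataFrame`` with one row per (batch, well, antigen) carrying the
measurement columns (``mfi``, ``net_mfi``, ``bead_count``), the well
annotations (``sample_id``, ``role``, ``read_order``) and the plate
metadata (batch name, run date-time, instrument serial number).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from mbaqc.errors import (
    DuplicateBatchError,
    EmptyDatasetError,
    MissingBlockError,
    MissingSheetError,
    ParseError,
    UnsupportedPlateLayoutError,
)

WELL_ROWS = "ABCDEFGH"
WELL_COLS = tuple(range(1, 13))

#: long-format measurement/annotation columns of one plate
RECORD_COLUMNS = [
    "well",
    "well_row",
    "well_col",
    "sample_id",
    "role",
    "antigen",
    "mfi",
    "net_mfi",
    "bead_count",
    "read_order",
]

#: plate metadata columns replicated onto every record after merging
META_COLUMNS = [
    "batch_name",
    "batch_datetime",
    "instrument_serial",
    "source_file",
    "plate_format",
]

MERGED_COLUMNS = META_COLUMNS + RECORD_COLUMNS

_WELL_RE = re.compile(r"^([A-Za-z]{1,2})(\d{1,2})$")

# xPONENT block label -> measurement column
_BLOCK_MAP = {"Median": "mfi", "Net MFI": "net_mfi", "Count": "bead_count"}


def parse_well(label: str) -> tuple[str, int]:
    """Split a well label like ``"A1"`` into (row letter, column number).

    Raises :class:`UnsupportedPlateLayoutError` for addresses outside the
    96-well A1..H12 grid (e.g. 384-well rows I..P or columns 13..24).
    """
    m = _WELL_RE.match(label.strip())
    if not m:
        raise ParseError(f"invalid well location {label!r}")
    row, col = m.group(1).upper(), int(m.group(2))
    if row not in WELL_ROWS or col not in WELL_COLS:
        raise UnsupportedPlateLayoutError(
            f"well {label!r} is outside the 96-well A1..H12 grid; "
            "only single 96-well plate runs are accepted"
        )
    return row, col


def parse_datetime(text: str) -> datetime:
    """Parse a batch run date-time: ISO-8601, or US-style MM/DD/YYYY HH:MM."""
    text = text.strip()
    try:
        return datetime.fromisoformat(text)
    except ValueError:
        pass
    try:
        return datetime.strptime(text, "%m/%d/%Y %H:%M")
    except ValueError:
        raise ParseError(f"unparseable batch date-time {text!r}") from None


@dataclass(frozen=True)
class RoleConfig:
    """How sample IDs map onto well roles.

    Controls are matched by exact, case-insensitive name.  Standards and
    backgrounds are matched by prefix; a single-letter prefix ("S", "B")
    only matches when followed entirely by digits, so sample IDs such as
    "Serum12" are not swallowed.  Everything else is an unknown (a study
    sample).
    """

    control_names: tuple[str, ...] = ("neg", "pos800", "pos2400", "pos7200")
    standard_prefixes: tuple[str, ...] = ("Standard", "S")
    background_prefixes: tuple[str, ...] = ("Background", "B")

    def role_of(self, sample_id: str) -> str:
        sid = sample_id.strip()
        low = sid.lower()
        if low in {c.lower() for c in self.control_names}:
            return "control"
        for prefix in self.background_prefixes:
            if self._prefix_match(sid, prefix):
                return "background"
        for prefix in self.standard_prefixes:
            if self._prefix_match(sid, prefix):
                return "standard"
        return "unknown"

    @staticmethod
    def _prefix_match(sid: str, prefix: str) -> bool:
        if len(prefix) == 1:
            return bool(re.fullmatch(re.escape(prefix) + r"\d+", sid, re.IGNORECASE))
        return sid.lower().startswith(prefix.lower())


@dataclass(frozen=True)
class PlateMetadata:
    batch_name: str
    batch_datetime: datetime
    instrument_serial: str
    source_file: str
    plate_format: int = 96

    def __post_init__(self) -> None:
        if self.plate_format != 96:
            raise UnsupportedPlateLayoutError(
                f"plate format {self.plate_format} is not supported; "
                "only single 96-well plate runs are accepted"
            )


@dataclass
class PlateData:
    """One parsed instrument output file: metadata plus per-well records."""

    metadata: PlateMetadata
    records: pd.DataFrame  # RECORD_COLUMNS

    def __post_init__(self) -> None:
        dup = self.records.duplicated(subset=["well", "antigen"])
        if dup.any():
            raise ParseError(
                f"duplicate (well, antigen) records in {self.metadata.source_file!r}"
            )
        wells_by_antigen = self.records.groupby("antigen")["well"].apply(frozenset)
        if wells_by_antigen.nunique() > 1:
            raise ParseError("antigens observed on differing well sets")

    @property
    def antigens(self) -> list[str]:
        return sorted(self.records["antigen"].unique())

    def to_frame(self) -> pd.DataFrame:
        """Records joined with metadata columns (one merged-dataset chunk)."""
        out = self.records.copy()
        out["batch_name"] = self.metadata.batch_name
        out["batch_datetime"] = self.metadata.batch_datetime
        out["instrument_serial"] = self.metadata.instrument_serial
        out["source_file"] = self.metadata.source_file
        out["plate_format"] = self.metadata.plate_format
        return out[MERGED_COLUMNS]


# ---------------------------------------------------------------------------
# xPONENT-style CSV


def _read_csv_rows(path: Path) -> list[list[str]]:
    with open(path, "r", encoding="utf-8-sig", newline="") as fh:
        return [row for row in csv.reader(fh)]


def parse_xponent(path: str | Path, roles: RoleConfig | None = None) -> PlateData:
    """Parse a single-plate xPONENT-style CSV export.

    Raises :class:`UnsupportedPlateLayoutError` for files holding more than
    one plate run or a non-96-well layout, and :class:`MissingBlockError`
    when one of the Median / Net MFI / Count blocks is absent.
    """
    path = Path(path)
    roles = roles or RoleConfig()
    rows = _read_csv_rows(path)

    meta: dict[str, str] = {}
    blocks: dict[str, pd.DataFrame] = {}
    i = 0
    n = len(rows)
    while i < n:
        row = rows[i]
        if not row or not row[0].strip():
            i += 1
            continue
        key = row[0].strip()
        if key.lower().startswith("datatype"):
            name = row[1].strip() if len(row) > 1 else ""
            if name not in _BLOCK_MAP:
                # tolerate extra vendor blocks: skip to next marker/blank
                i += 1
                while i < n and rows[i] and rows[i][0].strip() and not rows[i][0].strip().lower().startswith("datatype"):
                    i += 1
                continue
            if name in blocks:
                raise UnsupportedPlateLayoutError(
                    f"multiple {name!r} blocks found in {path.name}: "
                    "files containing multiple plate runs are not accepted"
                )
            block, i = _parse_block(rows, i + 1, path.name, name)
            blocks[name] = block
        else:
            if len(row) > 1:
                meta[key.lower()] = row[1].strip()
            i += 1

    missing = [b for b in _BLOCK_MAP if b not in blocks]
    if missing:
        raise MissingBlockError(
            f"{path.name}: missing required block(s): {', '.join(missing)}"
        )

    plate_format = int(meta.get("plateformat", "96"))
    metadata = PlateMetadata(
        batch_name=meta.get("batch", path.stem),
        batch_datetime=parse_datetime(meta.get("date", "")),
        instrument_serial=meta.get("sn", meta.get("serial", "")),
        source_file=path.name,
        plate_format=plate_format,
    )
    records = _join_blocks(blocks, roles, path.name)
    return PlateData(metadata=metadata, records=records)


def _parse_block(
    rows: list[list[str]], start: int, fname: str, name: str
) -> tuple[pd.DataFrame, int]:
    """Parse one labelled block; returns (well-indexed frame, next row index)."""
    i = start
    n = len(rows)
    while i < n and (not rows[i] or not rows[i][0].strip()):
        i += 1
    if i >= n:
        raise MissingBlockError(f"{fname}: block {name!r} has no header row")
    header = [c.strip() for c in rows[i]]
    if len(header) < 3 or header[0].lower() != "location":
        raise ParseError(f"{fname}: malformed header for block {name!r}")
    antigens = [c for c in header[2:] if c]
    i += 1
    data: list[list[str]] = []
    while i < n:
        row = rows[i]
        if not row or not row[0].strip():
            break
        if row[0].strip().lower().startswith("datatype"):
            break
        data.append([c.strip() for c in row])
        i += 1
    if not data:
        raise MissingBlockError(f"{fname}: block {name!r} has no data rows")
    recs = []
    for order, row in enumerate(data, start=1):
        well_row, well_col = parse_well(row[0])
        rec = {
            "well": f"{well_row}{well_col}",
            "well_row": well_row,
            "well_col": well_col,
            "sample_id": row[1],
            "read_order": order,
        }
        for antigen, cell in zip(antigens, row[2:]):
            rec[antigen] = float(cell) if cell != "" else float("nan")
        recs.append(rec)
    frame = pd.DataFrame(recs)
    if frame["well"].duplicated().any():
        raise UnsupportedPlateLayoutError(
            f"{fname}: repeated well locations in block {name!r}: "
            "files containing multiple plate runs are not accepted"
        )
    return frame, i


def _join_blocks(
    blocks: dict[str, pd.DataFrame], roles: RoleConfig, fname: str
) -> pd.DataFrame:
    ref = blocks["Median"]
    antigen_cols = [c for c in ref.columns if c not in
                    ("well", "well_row", "well_col", "sample_id", "read_order")]
    long_parts = []
    base = ref[["well", "well_row", "well_col", "sample_id", "read_order"]]
    for name, col in _BLOCK_MAP.items():
        block = blocks[name]
        cols = [c for c in block.columns if c not in
                ("well", "well_row", "well_col", "sample_id", "read_order")]
        if set(cols) != set(antigen_cols):
            raise ParseError(f"{fname}: blocks report differing antigen sets")
        if set(block["well"]) != set(ref["well"]):
            raise ParseError(f"{fname}: blocks report differing well sets")
        melted = block.melt(
            id_vars=["well"], value_vars=antigen_cols,
            var_name="antigen", value_name=col,
        )
        long_parts.append(melted.set_index(["well", "antigen"])[col])
    values = pd.concat(long_parts, axis=1).reset_index()
    out = values.merge(base, on="well", how="left")
    out["role"] = out["sample_id"].map(roles.role_of)
    out["bead_count"] = out["bead_count"].round().astype(int)
    if (out["bead_count"] < 0).any():
        raise ParseError(f"{fname}: negative bead counts")
    out = out.sort_values(["antigen", "read_order"], kind="stable").reset_index(drop=True)
    return out[RECORD_COLUMNS]


def write_xponent(plate: PlateData, path: str | Path) -> Path:
    """Serialize a plate back to the documented xPONENT-style CSV dialect.

    Byte-stable: MFI values are written with one decimal, counts as
    integers, and the block row order follows ``read_order``; parsing a
    written file and re-writing it reproduces the bytes exactly.
    """
    path = Path(path)
    md = plate.metadata
    antigens = plate.antigens
    wide = plate.records.pivot(index="well", columns="antigen",
                               values=["mfi", "net_mfi", "bead_count"])
    order = (
        plate.records[["well", "sample_id", "read_order"]]
        .drop_duplicates("well")
        .sort_values("read_order")
    )
    lines: list[str] = [
        "Program,xPONENT",
        f"Batch,{md.batch_name}",
        f"Date,{md.batch_datetime.strftime('%Y-%m-%d %H:%M:%S')}",
        f"SN,{md.instrument_serial}",
        f"PlateFormat,{md.plate_format}",
        "",
    ]
    for name, col in _BLOCK_MAP.items():
        lines.append(f"DataType:,{name}")
        lines.append("Location,Sample," + ",".join(antigens))
        for _, wrow in order.iterrows():
            cells = [wrow["well"], wrow["sample_id"]]
            for antigen in antigens:
                v = wide.loc[wrow["well"], (col, antigen)]
                cells.append(f"{int(v):d}" if col == "bead_count" else f"{v:.1f}")
            lines.append(",".join(cells))
        lines.append("")
    path.write_text("\n".join(lines), encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# BPM-style workbook

_BPM_SHEETS = {"FI": "mfi", "FI—Bkgd": "net_mfi", "Bead Count": "bead_count"}


def _normalize_sheet_name(name: str) -> str:
    # em dash / en dash / hyphen variants collapse to "-"
    return re.sub(r"[—–−-]", "-", name.strip())


def parse_bpm(path: str | Path, roles: RoleConfig | None = None) -> PlateData:
    """Parse a Bio-Plex-Manager-style multi-sheet workbook.

    The workbook must carry the sheets ``FI``, ``FI—Bkgd`` (dash variants
    accepted) and ``Bead Count``; a missing sheet raises
    :class:`MissingSheetError` naming it.  Wells are aligned across sheets
    by well address, so the sheets need not share row order.
    """
    from openpyxl import load_workbook

    path = Path(path)
    roles = roles or RoleConfig()
    wb = load_workbook(path, read_only=True, data_only=True)
    by_norm = {_normalize_sheet_name(t): t for t in wb.sheetnames}
    sheets: dict[str, str] = {}
    for canonical in _BPM_SHEETS:
        norm = _normalize_sheet_name(canonical)
        if norm not in by_norm:
            raise MissingSheetError(
                f"{path.name}: missing required attribute: sheet {canonical!r}"
            )
        sheets[canonical] = by_norm[norm]

    meta: dict[str, str] = {}
    blocks: dict[str, pd.DataFrame] = {}
    for canonical, title in sheets.items():
        ws = wb[title]
        rows = [[("" if c is None else c) for c in r] for r in ws.iter_rows(values_only=True)]
        # leading key/value metadata rows (on the FI sheet) precede the table
        i = 0
        while i < len(rows):
            first = str(rows[i][0]).strip() if rows[i] else ""
            if first.lower() == "well":
                break
            if first and len(rows[i]) > 1 and str(rows[i][1]).strip():
                meta.setdefault(first.lower(), str(rows[i][1]).strip())
            i += 1
        if i >= len(rows):
            raise ParseError(f"{path.name}: sheet {title!r} has no Well header row")
        header = [str(c).strip() for c in rows[i]]
        antigens = [c for c in header[2:] if c]
        recs = []
        for order, row in enumerate(rows[i + 1:], start=1):
            if not row or not str(row[0]).strip():
                break
            well_row, well_col = parse_well(str(row[0]))
            rec = {
                "well": f"{well_row}{well_col}",
                "sample_id": str(row[1]).strip(),
                "read_order": order,
            }
            for antigen, cell in zip(antigens, row[2:]):
                rec[antigen] = float(cell) if cell != "" else float("nan")
            recs.append(rec)
        frame = pd.DataFrame(recs)
        if frame.empty:
            raise ParseError(f"{path.name}: sheet {title!r} has no data rows")
        if frame["well"].duplicated().any():
            raise UnsupportedPlateLayoutError(
                f"{path.name}: repeated well locations in sheet {title!r}"
            )
        blocks[canonical] = frame
    wb.close()

    ref = blocks["FI"]
    antigen_cols = [c for c in ref.columns if c not in ("well", "sample_id", "read_order")]
    parts = []
    for canonical, col in _BPM_SHEETS.items():
        block = blocks[canonical]
        cols = [c for c in block.columns if c not in ("well", "sample_id", "read_order")]
        if set(cols) != set(antigen_cols):
            raise ParseError(f"{path.name}: sheets report differing antigen sets")
        if set(block["well"]) != set(ref["well"]):
            raise ParseError(f"{path.name}: sheets report differing well sets")
        melted = block.melt(id_vars=["well"], value_vars=antigen_cols,
                            var_name="antigen", value_name=col)
        parts.append(melted.set_index(["well", "antigen"])[col])
    values = pd.concat(parts, axis=1).reset_index()
    base = ref[["well", "sample_id", "read_order"]]
    out = values.merge(base, on="well", how="left")
    rc = out["well"].map(parse_well)
    out["well_row"] = [r for r, _ in rc]
    out["well_col"] = [c for _, c in rc]
    out["role"] = out["sample_id"].map(roles.role_of)
    out["bead_count"] = out["bead_count"].round().astype(int)
    out = out.sort_values(["antigen", "read_order"], kind="stable").reset_index(drop=True)

    metadata = PlateMetadata(
        batch_name=meta.get("batch", path.stem),
        batch_datetime=parse_datetime(meta.get("date", "")),
        instrument_serial=meta.get("sn", meta.get("serial", "")),
        source_file=path.name,
        plate_format=int(meta.get("plateformat", "96")),
    )
    return PlateData(metadata=metadata, records=out[RECORD_COLUMNS])


def write_bpm(plate: PlateData, path: str | Path) -> Path:
    """Serialize a plate to the BPM-style workbook layout (three sheets)."""
    from openpyxl import Workbook

    path = Path(path)
    md = plate.metadata
    antigens = plate.antigens
    wide = plate.records.pivot(index="well", columns="antigen",
                               values=["mfi", "net_mfi", "bead_count"])
    order = (
        plate.records[["well", "sample_id", "read_order"]]
        .drop_duplicates("well")
        .sort_values("read_order")
    )
    wb = Workbook()
    wb.remove(wb.active)
    for canonical, col in _BPM_SHEETS.items():
        ws = wb.create_sheet(title=canonical)
        if canonical == "FI":
            ws.append(["Batch", md.batch_name])
            ws.append(["Date", md.batch_datetime.strftime("%Y-%m-%d %H:%M:%S")])
            ws.append(["SN", md.instrument_serial])
            ws.append(["PlateFormat", md.plate_format])
            ws.append([])
        ws.append(["Well", "Sample"] + antigens)
        for _, wrow in order.iterrows():
            cells: list = [wrow["well"], wrow["sample_id"]]
            for antigen in antigens:
                v = wide.loc[wrow["well"], (col, antigen)]
                cells.append(int(v) if col == "bead_count" else float(v))
            ws.append(cells)
    wb.save(path)
    return path


# ---------------------------------------------------------------------------
# merging and export


def merge_plates(
    plates: Iterable[PlateData],
    existing: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Merge parsed plates (and optionally a previously merged dataset)
    into the canonical long-format dataset.

    Record counts are conserved; a duplicated (batch, well, antigen) key
    across the inputs raises :class:`DuplicateBatchError` listing the
    offending batches.
    """
    parts = [p.to_frame() for p in plates]
    if existing is not None:
        parts.insert(0, existing[MERGED_COLUMNS].copy())
    if not parts:
        raise EmptyDatasetError("no plates and no existing dataset given")
    merged = pd.concat(parts, ignore_index=True)
    dup = merged.duplicated(subset=["batch_name", "well", "antigen"], keep=False)
    if dup.any():
        batches = sorted(merged.loc[dup, "batch_name"].unique())
        raise DuplicateBatchError(
            "duplicate (batch, well, antigen) records for batch(es): "
            + ", ".join(batches)
        )
    return merged


def sort_chronologically(ds: pd.DataFrame) -> pd.DataFrame:
    """Stable chronological order: run date-time, then batch name."""
    return ds.sort_values(["batch_datetime", "batch_name"], kind="stable")


def export_dataset(ds: pd.DataFrame, layout: str, path: str | Path) -> Path:
    """Write the merged dataset as CSV in ``long`` or ``wide`` layout.

    The long layout has one row per (batch, well, antigen) and round-trips
    through :func:`import_merged`; the wide layout has one row per
    (batch, well) with per-antigen MFI, net-MFI and bead-count columns.
    """
    path = Path(path)
    if ds is None or len(ds) == 0:
        raise EmptyDatasetError("refusing to export an empty dataset")
    if layout == "long":
        out = ds[MERGED_COLUMNS].copy()
        out["batch_datetime"] = pd.to_datetime(out["batch_datetime"]).dt.strftime(
            "%Y-%m-%d %H:%M:%S"
        )
        out.to_csv(path, index=False)
    elif layout == "wide":
        base_cols = ["batch_name", "batch_datetime", "instrument_serial",
                     "source_file", "well", "well_row", "well_col",
                     "sample_id", "role", "read_order"]
        wide = ds.pivot_table(
            index=base_cols,
            columns="antigen",
            values=["mfi", "net_mfi", "bead_count"],
            aggfunc="first",
        )
        wide.columns = [f"{measure}_{antigen}" for measure, antigen in wide.columns]
        wide = wide.reset_index()
        wide["batch_datetime"] = pd.to_datetime(wide["batch_datetime"]).dt.strftime(
            "%Y-%m-%d %H:%M:%S"
        )
        wide = wide.sort_values(["batch_name", "read_order"], kind="stable")
        wide.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown layout {layout!r} (expected 'long' or 'wide')")
    return path


def import_merged(path: str | Path) -> pd.DataFrame:
    """Re-import a previously exported long-layout merged dataset."""
    path = Path(path)
    ds = pd.read_csv(path)
    missing = [c for c in MERGED_COLUMNS if c not in ds.columns]
    if missing:
        raise ParseError(
            f"{path.name}: not a merged long-layout dataset; missing columns "
            + ", ".join(missing)
        )
    ds["batch_datetime"] = pd.to_datetime(ds["batch_datetime"])
    ds["bead_count"] = ds["bead_count"].astype(int)
    return ds[MERGED_COLUMNS]
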