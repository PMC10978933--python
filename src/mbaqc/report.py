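"""Pipeline runner and report-bundle writer.

``run_pipeline`` reads any mix of plate files and previously merged
datasets, runs the three QC stages and writes the downloadable bundle:

======================================  =======================================
File                                    Content
======================================  =======================================
Raw_data.csv                            merged dataset, long layout
Raw_data_wide.csv                       merged dataset, wide layout
Summary_results.xlsx                    four bead-QC summary tables
Bead-QC-plots.zip                       bead fluctuation plots per plate
Bead-QC-plate-plots.zip                 bead plate plots per plate
MFI-QC-plate-plots.zip                  MFI plate plots per plate
MFI-Heat-Maps.zip                       MFI heatmaps per plate
Control_tracking_plots.zip              control charts per antigen
2cl_3cl_repeat_summary.csv              per-point control data, 2/3-sigma rules
2cl_3cl_summary.csv                     per-pair summary, 2/3-sigma rules
Nelson_repeat_summary.csv               per-point control data, Nelson rules
Nelson_summary.csv                      per-pair summary, Nelson rules
======================================  =======================================

``simulate`` wraps the synthetic-study generator for the CLI.
"""

from __future__ import annotations

import logging
import zipfile
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

import matplotlib.pyplot as plt

from mbaqc import plots
from mbaqc.bead_qc import BeadQCConfig, flag_bead_counts, summarize_bead_qc
from mbaqc.control import SpcChartSpec, spc_summary, track_controls
from mbaqc.errors import MbaQcError, NoBackgroundWellError
from mbaqc.io import (
    PlateData,
    RoleConfig,
    export_dataset,
    import_merged,
    merge_plates,
    parse_bpm,
    parse_xponent,
)
from mbaqc.mfi_qc import MfiQCConfig
from mbaqc.synth import SyntheticStudySpec, default_anomalies, generate_study

log = logging.getLogger("mbaqc")


@dataclass
class RunConfig:
    """Parameters of one pipeline run (defaults are the documented QC
    defaults: 20/35 beads, 30% plate failure, warning MFI 100, I-MR with
    the 2/3-sigma protocol, 20 reference plates)."""

    inputs: list[str] = field(default_factory=list)
    out_dir: str = "mbaqc_output"
    lower_beads: int = 20
    upper_beads: int = 35
    plate_fail_pct: float = 30.0
    warning_mfi: float = 100.0
    method: str = "imr"
    protocol: str = "cl23"
    reference_k: int = 20
    average_replicates: bool = True
    value_col: str = "net_mfi"
    control_names: tuple[str, ...] = ("neg", "pos800", "pos2400", "pos7200")
    make_plots: bool = True
    # simulate-only
    seed: int = 1
    n_plates: int = 32
    with_anomalies: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        if "control_names" in raw:
            raw["control_names"] = tuple(raw["control_names"])
        return cls(**raw)

    @property
    def bead_cfg(self) -> BeadQCConfig:
        return BeadQCConfig(
            lower_threshold=self.lower_beads,
            upper_threshold=self.upper_beads,
            plate_fail_fraction=self.plate_fail_pct / 100.0,
        )

    @property
    def mfi_cfg(self) -> MfiQCConfig:
        return MfiQCConfig(warning_mfi=self.warning_mfi)

    @property
    def chart_spec(self) -> SpcChartSpec:
        return SpcChartSpec(
            method=self.method, reference_k=self.reference_k, protocol=self.protocol
        )


@dataclass
class ReportBundle:
    out_dir: Path
    files: list[Path]
    merged: pd.DataFrame
    notices: list[str]

    def names(self) -> set[str]:
        return {p.name for p in self.files}


def load_inputs(
    paths: list[str | Path], roles: RoleConfig
) -> tuple[list[PlateData], pd.DataFrame | None, list[str]]:
    """Parse plate files and/or previously merged datasets.

    Returns (plates, existing merged dataset or None, per-file errors)."""
    plates: list[PlateData] = []
    existing: pd.DataFrame | None = None
    errors: list[str] = []
    for p in paths:
        p = Path(p)
        try:
            if p.suffix.lower() == ".xlsx":
                plates.append(parse_bpm(p, roles))
            elif _looks_merged(p):
                ds = import_merged(p)
                existing = ds if existing is None else pd.concat(
                    [existing, ds], ignore_index=True
                )
            else:
                plates.append(parse_xponent(p, roles))
        except (MbaQcError, ValueError, OSError) as exc:
            errors.append(f"{p}: {exc}")
    return plates, existing, errors


def _looks_merged(path: Path) -> bool:
    if path.suffix.lower() != ".csv":
        return False
    with open(path, "r", encoding="utf-8-sig") as fh:
        head = fh.readline()
    return "batch_name" in head and "antigen" in head


def _zip_figures(zip_path: Path, figures: dict) -> Path:
    """Render figures (name -> zero-arg factory) straight into a zip; each
    figure is closed as soon as it is written to keep memory flat."""
    tmp = zip_path.parent / (zip_path.stem + "_png")
    tmp.mkdir(parents=True, exist_ok=True)
    with zipfile.ZipFile(zip_path, "w", zipfile.ZIP_DEFLATED) as zf:
        for name, make_fig in figures.items():
            fig = make_fig() if callable(make_fig) else make_fig
            png = tmp / name
            fig.savefig(png, dpi=80)
            plt.close(fig)
            zf.write(png, arcname=name)
            png.unlink()
    tmp.rmdir()
    return zip_path


def run_pipeline(cfg: RunConfig) -> ReportBundle:
    """Parse, merge, run all QC stages and write the full report bundle.

    Raises :class:`MbaQcError` when any input fails to parse or no input
    is given; control-tracking outputs are skipped with a logged notice
    when the dataset has no usable control series.
    """
    if not cfg.inputs:
        raise MbaQcError("no input files given")
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    roles = RoleConfig(control_names=cfg.control_names)
    plates, existing, errors = load_inputs(cfg.inputs, roles)
    if errors:
        raise MbaQcError("failed to parse input(s):\n" + "\n".join(errors))
    merged = merge_plates(plates, existing)

    notices: list[str] = []
    written: list[Path] = []

    written.append(export_dataset(merged, "long", out_dir / "Raw_data.csv"))
    written.append(export_dataset(merged, "wide", out_dir / "Raw_data_wide.csv"))

    # bead QC
    flagged = flag_bead_counts(merged, cfg.bead_cfg)
    per_antigen, per_plate = summarize_bead_qc(flagged, cfg.bead_cfg)
    below_upper = per_antigen.assign(
        pct_below_upper=100.0 * (per_antigen["n_failed"] + per_antigen["n_warn"])
        / per_antigen["n_wells"]
    )[["batch_name", "antigen", "pct_below_upper"]]
    below_lower = per_antigen.assign(
        pct_below_lower=100.0 * per_antigen["n_failed"] / per_antigen["n_wells"]
    )[["batch_name", "antigen", "pct_below_lower"]]
    xlsx = out_dir / "Summary_results.xlsx"
    with pd.ExcelWriter(xlsx) as writer:
        below_upper.to_excel(writer, sheet_name="pct_below_upper", index=False)
        below_lower.to_excel(writer, sheet_name="pct_below_lower", index=False)
        per_antigen.to_excel(writer, sheet_name="failed_wells", index=False)
        per_plate.to_excel(writer, sheet_name="failed_antigens", index=False)
    written.append(xlsx)

    # control tracking, both violation protocols
    n_points = 0
    for protocol, prefix in (("cl23", "2cl_3cl"), ("nelson", "Nelson")):
        spec = SpcChartSpec(
            method=cfg.method, reference_k=cfg.reference_k, protocol=protocol
        )
        results = track_controls(
            merged, spec, average_replicates=cfg.average_replicates,
            value_col=cfg.value_col,
        )
        if not results:
            notices.append(
                f"control tracking ({protocol}) skipped: no usable control series"
            )
            continue
        summary, flagged_pts = spc_summary(results)
        repeat_path = out_dir / f"{prefix}_repeat_summary.csv"
        summary_path = out_dir / f"{prefix}_summary.csv"
        flagged_out = flagged_pts.copy()
        flagged_out["batch_datetime"] = pd.to_datetime(
            flagged_out["batch_datetime"]
        ).dt.strftime("%Y-%m-%d %H:%M:%S")
        flagged_out.to_csv(repeat_path, index=False)
        summary.to_csv(summary_path, index=False)
        written += [repeat_path, summary_path]
        if protocol == "cl23":
            cl23_results = results
            n_points = int(sum(len(r.series) for r in results))

    # plots
    if cfg.make_plots:
        from functools import partial

        bead_figs, fluct_figs, mfi_figs, heat_figs = {}, {}, {}, {}
        for plate in plates:
            stem = plate.metadata.batch_name.replace(" ", "_")
            bead_figs[f"{stem}_bead_plate.png"] = partial(
                plots.bead_plate_figure, plate, cfg.bead_cfg
            )
            fluct_figs[f"{stem}_bead_fluctuation.png"] = partial(
                plots.fluctuation_figure, plate, cfg.bead_cfg
            )
            try:
                plates_bg = plate.records[plate.records["role"] == "background"]
                if plates_bg.empty:
                    raise NoBackgroundWellError(
                        f"plate {plate.metadata.batch_name!r} has no background well"
                    )
                mfi_figs[f"{stem}_mfi_plate.png"] = partial(
                    plots.mfi_plate_figure, plate, cfg.mfi_cfg
                )
            except NoBackgroundWellError as exc:
                notices.append(f"MFI plate plot skipped: {exc}")
            heat_figs[f"{stem}_mfi_heatmap.png"] = partial(plots.heatmap_figure, plate)
        written.append(_zip_figures(out_dir / "Bead-QC-plots.zip", fluct_figs))
        written.append(_zip_figures(out_dir / "Bead-QC-plate-plots.zip", bead_figs))
        written.append(_zip_figures(out_dir / "MFI-QC-plate-plots.zip", mfi_figs))
        written.append(_zip_figures(out_dir / "MFI-Heat-Maps.zip", heat_figs))
        ct_figs = {}
        try:
            for antigen in sorted(merged["antigen"].unique()):
                sub = [r for r in cl23_results if r.series.antigen == antigen]
                if sub:
                    ct_figs[f"{antigen}_control_tracking.png"] = partial(
                        plots.control_tracking_figure, cl23_results, antigen
                    )
        except NameError:
            pass
        if ct_figs:
            written.append(
                _zip_figures(out_dir / "Control_tracking_plots.zip", ct_figs)
            )
        else:
            notices.append("control tracking plots skipped: no usable control series")

    run_log = out_dir / "run_log.txt"
    lines = [
        f"plates parsed: {len(plates)}",
        f"records merged: {len(merged)}",
        f"bead flags: fail={int((flagged['bead_flag'] == 'fail').sum())} "
        f"warn={int((flagged['bead_flag'] == 'warn').sum())}",
        f"failed plate-antigen combinations: {int(per_antigen['plate_failed'].sum())}",
        f"control points tracked (cl23): {n_points}",
    ] + [f"notice: {n}" for n in notices]
    run_log.write_text("\n".join(lines) + "\n")
    written.append(run_log)
    for notice in notices:
        log.warning(notice)
    return ReportBundle(out_dir=out_dir, files=written, merged=merged, notices=notices)


def simulate(cfg: RunConfig) -> tuple[list[Path], dict[str, pd.DataFrame]]:
    """Generate a synthetic study under ``out_dir`` (plate files plus
    ground-truth tables)."""
    spec = SyntheticStudySpec(n_plates=cfg.n_plates, seed=cfg.seed,
                              control_names=cfg.control_names)
    anomalies = default_anomalies() if cfg.with_anomalies else []
    anomalies = [
        a for a in anomalies if all(1 <= p <= spec.n_plates for p in a.target_plates)
    ]
    return generate_study(spec, anomalies, cfg.out_dir)
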