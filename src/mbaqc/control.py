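"""Statistical process control of assay controls over time.

Each plate in a study carries the same set of assay controls (e.g. a
negative serum pool and positive pools at two dilutions).  For every
control-antigen pair the background-subtracted control MFI is tracked
chronologically across plates and evaluated with one of three control
charts:

* **Levey-Jennings** — center = mean, sigma = the long-term (sample)
  standard deviation over all points;
* **Individuals-Moving-Range (I-MR)** — sigma is the short-term estimate
  ``mean moving range / d2`` with ``d2 = 1.128`` (the expected relative
  range of subgroups of n = 2 under normality); the companion MR chart
  plots successive absolute differences against an upper control limit
  ``UCL = D4 x mean moving range`` with ``D4 = 3.267``;
* **modified Shewhart** — center and sigma are fixed from the first *k*
  reference plates (default 20) and applied to the whole series.

Violations are assessed either with the 2-sigma/3-sigma protocol (a point
at or outside 3 sigma is out of control; a point outside 2 sigma is a
"CL2 warning") or with the eight standard Nelson run rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mbaqc.errors import EmptySeriesError, InsufficientDataError

#: expected relative range of subgroups of size 2 (sigma = mean MR / d2)
D2_INDIVIDUALS = 1.128
#: MR-chart upper-control-limit multiplier (UCL = D4 * mean MR)
D4_MOVING_RANGE = 3.267


@dataclass
class ControlSeries:
    """Chronological series of one control's MFI for one antigen."""

    control: str
    antigen: str
    #: columns: observation (1-based), batch_name, batch_datetime, value
    points: pd.DataFrame
    averaged_replicates: bool
    n_missing: int  # plates in the study lacking this control-antigen pair

    @property
    def values(self) -> np.ndarray:
        return self.points["value"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class SpcChartSpec:
    """Chart method and violation protocol selection."""

    method: str = "imr"  # levey_jennings | imr | shewhart
    reference_k: int = 20  # shewhart only
    protocol: str = "cl23"  # cl23 | nelson

    def __post_init__(self) -> None:
        if self.method not in ("levey_jennings", "imr", "shewhart"):
            raise ValueError(f"unknown chart method {self.method!r}")
        if self.protocol not in ("cl23", "nelson"):
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if self.reference_k < 2:
            raise ValueError("reference_k must be >= 2")


@dataclass(frozen=True)
class SpcLimits:
    """Center line and sigma with the derived k-sigma control limits."""

    center: float
    sigma: float
    method: str

    def upper(self, k: int) -> float:
        return self.center + k * self.sigma

    def lower(self, k: int) -> float:
        return self.center - k * self.sigma


@dataclass
class MovingRangeChart:
    """Absolute successive differences of a control series."""

    #: columns: observation (of the later point), batch_name, mr, out_of_control
    points: pd.DataFrame
    mean_mr: float
    ucl: float


def build_control_series(
    ds: pd.DataFrame,
    control: str,
    antigen: str,
    average_replicates: bool = True,
    value_col: str = "net_mfi",
) -> ControlSeries:
    """Extract the chronological series of one control-antigen pair.

    Replicate control wells on a plate are averaged into a single point per
    plate (arithmetic mean) when ``average_replicates`` is set; otherwise
    each well contributes its own point.  Plates in the dataset lacking
    the pair are counted in ``n_missing``.  Points are sorted by run
    date-time with batch name as the deterministic tie-break.
    """
    if "value" in ds.columns and "sample_id" not in ds.columns:
        return _series_from_simple(ds, control, antigen)
    sub = ds[
        (ds["role"] == "control")
        & (ds["sample_id"].str.lower() == control.lower())
        & (ds["antigen"] == antigen)
    ]
    sub = sub[sub[value_col].notna()]
    if sub.empty:
        raise EmptySeriesError(
            f"no data anywhere for control {control!r} / antigen {antigen!r}"
        )
    n_batches_total = ds["batch_name"].nunique()
    if average_replicates:
        pts = (
            sub.groupby(["batch_name", "batch_datetime"], sort=False)[value_col]
            .mean()
            .reset_index()
            .rename(columns={value_col: "value"})
        )
    else:
        pts = sub[["batch_name", "batch_datetime", "well", value_col]].rename(
            columns={value_col: "value"}
        )
    sort_cols = ["batch_datetime", "batch_name"] + (
        ["well"] if not average_replicates else []
    )
    pts = pts.sort_values(sort_cols, kind="stable").reset_index(drop=True)
    pts.insert(0, "observation", np.arange(1, len(pts) + 1))
    return ControlSeries(
        control=control,
        antigen=antigen,
        points=pts,
        averaged_replicates=average_replicates,
        n_missing=n_batches_total - pts["batch_name"].nunique(),
    )


def _series_from_simple(table: pd.DataFrame, control: str, antigen: str) -> ControlSeries:
    sub = table[
        (table["control"].str.lower() == control.lower())
        & (table["antigen"] == antigen)
    ]
    sub = sub[sub["value"].notna()]
    if sub.empty:
        raise EmptySeriesError(
            f"no data anywhere for control {control!r} / antigen {antigen!r}"
        )
    pts = (
        sub.groupby("date", sort=False)["value"].mean().reset_index()
        .rename(columns={"date": "batch_datetime"})
    )
    pts["batch_name"] = pts["batch_datetime"].dt.strftime("%Y-%m-%d %H:%M:%S")
    pts = pts.sort_values(["batch_datetime", "batch_name"], kind="stable")
    pts = pts.reset_index(drop=True)
    pts.insert(0, "observation", np.arange(1, len(pts) + 1))
    pts = pts[["observation", "batch_name", "batch_datetime", "value"]]
    return ControlSeries(
        control=control,
        antigen=antigen,
        points=pts,
        averaged_replicates=True,
        n_missing=int(table["date"].nunique() - pts["batch_datetime"].nunique()),
    )


def read_simple_control_csv(path) -> pd.DataFrame:
    """Read the simplified four-column control CSV (date, control, antigen,
    value) accepted in lieu of instrument output files."""
    table = pd.read_csv(path)
    table.columns = [c.strip().lower() for c in table.columns]
    required = ["date", "control", "antigen", "value"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(
            "simplified control CSV must have columns date, control, antigen, "
            f"value; missing: {', '.join(missing)}"
        )
    table["date"] = pd.to_datetime(table["date"])
    table["value"] = table["value"].astype(float)
    return table[required]


def moving_ranges(values: np.ndarray) -> np.ndarray:
    """Absolute differences between consecutive (date-ordered) points."""
    return np.abs(np.diff(np.asarray(values, dtype=float)))


def estimate_limits(s: ControlSeries, spec: SpcChartSpec) -> SpcLimits:
    """Center line and sigma for the chosen chart method.

    ``levey_jennings``: mean and sample (n-1) standard deviation over all
    points.  ``imr``: mean center; sigma = mean moving range / d2.
    ``shewhart``: mean and sample standard deviation of the first
    ``reference_k`` points only, applied to the whole series.
    """
    v = s.values
    minimum = spec.reference_k if spec.method == "shewhart" else 2
    if len(v) < minimum:
        raise InsufficientDataError(
            f"{s.control}/{s.antigen}: {len(v)} points, but method "
            f"{spec.method!r} needs at least {minimum}"
        )
    if spec.method == "levey_jennings":
        center = float(np.mean(v))
        sigma = float(np.std(v, ddof=1))
    elif spec.method == "imr":
        center = float(np.mean(v))
        sigma = float(np.mean(moving_ranges(v)) / D2_INDIVIDUALS)
    else:  # shewhart
        ref = v[: spec.reference_k]
        center = float(np.mean(ref))
        sigma = float(np.std(ref, ddof=1))
    return SpcLimits(center=center, sigma=sigma, method=spec.method)


def moving_range_chart(s: ControlSeries) -> MovingRangeChart:
    """MR chart of a series: successive |differences|, their mean, and the
    upper control limit ``D4 x mean MR``.

    A range at or above the UCL is out of control; with a degenerate UCL of
    zero (constant series) nothing is flagged.
    """
    if len(s) < 2:
        raise InsufficientDataError(
            f"{s.control}/{s.antigen}: moving-range chart needs >= 2 points"
        )
    mr = moving_ranges(s.values)
    mean_mr = float(np.mean(mr))
    ucl = D4_MOVING_RANGE * mean_mr
    pts = pd.DataFrame(
        {
            "observation": s.points["observation"].to_numpy()[1:],
            "batch_name": s.points["batch_name"].to_numpy()[1:],
            "mr": mr,
            "out_of_control": (mr >= ucl) & (ucl > 0),
        }
    )
    return MovingRangeChart(points=pts, mean_mr=mean_mr, ucl=ucl)


# ---------------------------------------------------------------------------
# violation protocols


@dataclass(frozen=True)
class NelsonConfig:
    """Run lengths of the eight standard Nelson rules (defaults are the
    published values)."""

    rule2_run: int = 9  # same side of center
    rule3_run: int = 6  # monotone trend
    rule4_run: int = 14  # alternation
    rule5_window: int = 3  # 2 of 3 beyond 2 sigma, same side
    rule6_window: int = 5  # 4 of 5 beyond 1 sigma, same side
    rule7_run: int = 15  # within 1 sigma
    rule8_run: int = 8  # beyond 1 sigma, either side


def nelson_rule_hits(
    values: np.ndarray, center: float, sigma: float, cfg: NelsonConfig | None = None
) -> list[set[int]]:
    """Evaluate the 8 Nelson rules; returns, per point, the set of rule
    numbers completing at that point.

    Rules: (1) one point beyond 3 sigma; (2) ``rule2_run`` in a row on one
    side of center; (3) ``rule3_run`` in a row steadily increasing or
    decreasing; (4) ``rule4_run`` in a row alternating up and down;
    (5) 2 of 3 beyond 2 sigma on the same side; (6) 4 of 5 beyond 1 sigma
    on the same side; (7) ``rule7_run`` in a row within 1 sigma;
    (8) ``rule8_run`` in a row beyond 1 sigma on either side.  Zone rules
    (1, 5-8) use strict "beyond"; points exactly on the center line belong
    to neither side.  A rule is recorded at the point where its pattern
    completes (and at every point extending the pattern).
    """
    cfg = cfg or NelsonConfig()
    v = np.asarray(values, dtype=float)
    n = len(v)
    hits: list[set[int]] = [set() for _ in range(n)]
    dev = v - center
    side = np.sign(dev)  # 0 when exactly on center

    def beyond(k: float) -> np.ndarray:
        if sigma > 0:
            return np.abs(dev) > k * sigma
        return np.abs(dev) > 0

    # rule 1: single point beyond 3 sigma
    for i in np.nonzero(beyond(3))[0]:
        hits[i].add(1)

    # rule 2: run on one side of center
    run = 0
    for i in range(n):
        if side[i] != 0 and (i > 0 and side[i] == side[i - 1]):
            run += 1
        elif side[i] != 0:
            run = 1
        else:
            run = 0
        if run >= cfg.rule2_run:
            hits[i].add(2)

    # rule 3: monotone trend (strict)
    if n >= 2:
        d = np.sign(np.diff(v))
        run = 0
        for i in range(1, n):
            step = d[i - 1]
            if step != 0 and (run == 0 or step == last_step):  # noqa: F821
                run += 1
            elif step != 0:
                run = 1
            else:
                run = 0
            last_step = step
            if run >= cfg.rule3_run - 1:
                hits[i].add(3)

    # rule 4: alternation (strict up/down)
    if n >= 2:
        d = np.sign(np.diff(v))
        run = 1
        for i in range(1, n):
            step = d[i - 1]
            if step == 0:
                run = 1
            elif i >= 2 and d[i - 2] != 0 and step == -d[i - 2]:
                run += 1
            else:
                run = 2
            if run >= cfg.rule4_run:
                hits[i].add(4)

    # rules 5 and 6: m of window beyond k sigma, same side
    for rule, k, window, m in (
        (5, 2.0, cfg.rule5_window, cfg.rule5_window - 1),
        (6, 1.0, cfg.rule6_window, cfg.rule6_window - 1),
    ):
        bey = beyond(k)
        for i in range(window - 1, n):
            idx = range(i - window + 1, i + 1)
            for sgn in (1, -1):
                cnt = sum(1 for j in idx if bey[j] and side[j] == sgn)
                if cnt >= m:
                    hits[i].add(rule)
                    break

    # rule 7: run within 1 sigma
    if sigma > 0:
        within = np.abs(dev) <= sigma
        run = 0
        for i in range(n):
            run = run + 1 if within[i] else 0
            if run >= cfg.rule7_run:
                hits[i].add(7)

    # rule 8: run beyond 1 sigma on either side
    bey1 = beyond(1)
    run = 0
    for i in range(n):
        run = run + 1 if bey1[i] else 0
        if run >= cfg.rule8_run:
            hits[i].add(8)

    return hits


def evaluate_violations(
    s: ControlSeries,
    lim: SpcLimits,
    protocol: str = "cl23",
    nelson_cfg: NelsonConfig | None = None,
) -> pd.DataFrame:
    """Per-point verdicts for a control series under the given limits.

    ``cl23`` protocol: a point **at or outside** the 3-sigma limits is
    ``out_of_control``; a point outside the 2-sigma limits (but not out of
    control) is a ``cl2_warning``; all others are ``in_control``.  With a
    degenerate sigma of zero only a nonzero deviation violates.

    ``nelson`` protocol: the eight Nelson rules are scanned; a point where
    any rule fires is ``out_of_control`` and its rule numbers are recorded.
    """
    v = s.values
    dev = np.abs(v - lim.center)
    out = s.points.copy()
    if protocol == "cl23":
        if lim.sigma > 0:
            ooc = dev >= 3 * lim.sigma
            warn = (dev > 2 * lim.sigma) & ~ooc
        else:
            ooc = dev > 0
            warn = np.zeros(len(v), dtype=bool)
        status = np.where(ooc, "out_of_control", np.where(warn, "cl2_warning", "in_control"))
        rules = ["" for _ in v]
    elif protocol == "nelson":
        hits = nelson_rule_hits(v, lim.center, lim.sigma, nelson_cfg)
        status = np.array(
            ["out_of_control" if h else "in_control" for h in hits], dtype=object
        )
        rules = [";".join(str(r) for r in sorted(h)) for h in hits]
    else:
        raise ValueError(f"unknown protocol {protocol!r}")
    out["status"] = status
    out["rules"] = rules
    out["repeat"] = out["status"] != "in_control"
    return out


# ---------------------------------------------------------------------------
# whole-study evaluation and summaries


@dataclass
class ControlTrackingResult:
    """Everything computed for one control-antigen pair."""

    series: ControlSeries
    limits: SpcLimits
    verdicts: pd.DataFrame
    mr_chart: MovingRangeChart | None
    spec: SpcChartSpec


def track_controls(
    ds: pd.DataFrame,
    spec: SpcChartSpec | None = None,
    controls: list[str] | None = None,
    antigens: list[str] | None = None,
    average_replicates: bool = True,
    value_col: str = "net_mfi",
    nelson_cfg: NelsonConfig | None = None,
) -> list[ControlTrackingResult]:
    """Evaluate every control-antigen pair present in the dataset.

    Pairs with too few points for the chart method are skipped.  Controls
    default to all control-role sample IDs; antigens to all antigens.
    """
    spec = spec or SpcChartSpec()
    if controls is None:
        controls = sorted(ds.loc[ds["role"] == "control", "sample_id"].unique())
    if antigens is None:
        antigens = sorted(ds["antigen"].unique())
    results = []
    for control in controls:
        for antigen in antigens:
            try:
                series = build_control_series(
                    ds, control, antigen, average_replicates, value_col
                )
                limits = estimate_limits(series, spec)
            except (EmptySeriesError, InsufficientDataError):
                continue
            verdicts = evaluate_violations(series, limits, spec.protocol, nelson_cfg)
            mr = moving_range_chart(series) if spec.method == "imr" else None
            results.append(
                ControlTrackingResult(
                    series=series, limits=limits, verdicts=verdicts,
                    mr_chart=mr, spec=spec,
                )
            )
    return results


def spc_summary(
    results: list[ControlTrackingResult],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The control-tracking output tables.

    Returns ``(summary, flagged)``:

    * ``summary`` — one row per control-antigen pair: missing datapoints;
      mean, median, max, min and standard deviation of the tracked MFI;
      the 1-3 sigma upper and lower control limits; the percentage of
      points out of control; and counts per violation type.
    * ``flagged`` — per-point metadata for every charted point
      (observation number, date, control, antigen, batch, value, verdict,
      repeat status, rule numbers).
    """
    summary_rows = []
    flagged_parts = []
    for res in results:
        s, lim, verdicts = res.series, res.limits, res.verdicts
        v = s.values
        n_ooc = int((verdicts["status"] == "out_of_control").sum())
        n_warn = int((verdicts["status"] == "cl2_warning").sum())
        row = {
            "control": s.control,
            "antigen": s.antigen,
            "method": res.spec.method,
            "protocol": res.spec.protocol,
            "n_points": len(v),
            "n_missing": s.n_missing,
            "mean": float(np.mean(v)),
            "median": float(np.median(v)),
            "max": float(np.max(v)),
            "min": float(np.min(v)),
            "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
            "center": lim.center,
            "sigma": lim.sigma,
        }
        for k in (1, 2, 3):
            row[f"upper_{k}sigma"] = lim.upper(k)
            row[f"lower_{k}sigma"] = lim.lower(k)
        row["n_out_of_control"] = n_ooc
        row["pct_out_of_control"] = 100.0 * n_ooc / len(v)
        row["n_cl2_warning"] = n_warn
        if res.spec.protocol == "nelson":
            all_rules = [r for cell in verdicts["rules"] for r in cell.split(";") if r]
            for rule in range(1, 9):
                row[f"n_rule_{rule}"] = sum(1 for r in all_rules if int(r) == rule)
        summary_rows.append(row)

        flag = verdicts.copy()
        flag.insert(1, "control", s.control)
        flag.insert(2, "antigen", s.antigen)
        flagged_parts.append(flag)

    summary = pd.DataFrame(summary_rows)
    flagged = (
        pd.concat(flagged_parts, ignore_index=True)
        if flagged_parts
        else pd.DataFrame()
    )
    return summary, flagged
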