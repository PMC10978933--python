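"""Control-chart limits, moving ranges, violation protocols, summaries."""

import numpy as np
import pandas as pd
import pytest

from mbaqc.control import (
    D2_INDIVIDUALS,
    D4_MOVING_RANGE,
    ControlSeries,
    NelsonConfig,
    SpcChartSpec,
    build_control_series,
    estimate_limits,
    evaluate_violations,
    moving_range_chart,
    nelson_rule_hits,
    read_simple_control_csv,
    spc_summary,
    track_controls,
)
from mbaqc.errors import EmptySeriesError, InsufficientDataError

from _oracles import nelson_rule2_scan


def make_series(values, control="ctrl", antigen="ag") -> ControlSeries:
    values = list(values)
    pts = pd.DataFrame(
        {
            "observation": np.arange(1, len(values) + 1),
            "batch_name": [f"plate {i}" for i in range(1, len(values) + 1)],
            "batch_datetime": pd.date_range("2023-01-01", periods=len(values), freq="D"),
            "value": [float(v) for v in values],
        }
    )
    return ControlSeries(control, antigen, pts, True, 0)


# ---------------------------------------------------------------------- limits


def test_imr_hand_example():
    """Series (10, 12, 11, 14): mean MR = 2, sigma = 2/1.128, center 11.75."""
    s = make_series([10, 12, 11, 14])
    lim = estimate_limits(s, SpcChartSpec(method="imr"))
    assert lim.center == pytest.approx(11.75)
    assert lim.sigma == pytest.approx(2.0 / 1.128)
    assert lim.sigma == pytest.approx(1.7730, abs=1e-4)
    assert lim.upper(3) == pytest.approx(11.75 + 5.3191, abs=1e-4)
    assert lim.lower(3) == pytest.approx(11.75 - 5.3191, abs=1e-4)


def test_levey_jennings_uses_sample_sd():
    s = make_series([10, 12, 11, 14])
    lim = estimate_limits(s, SpcChartSpec(method="levey_jennings"))
    assert lim.center == pytest.approx(11.75)
    assert lim.sigma == pytest.approx(np.std([10, 12, 11, 14], ddof=1))


def test_constant_series_all_methods_degenerate():
    s = make_series([7.0] * 25)
    for method in ("levey_jennings", "imr", "shewhart"):
        lim = estimate_limits(s, SpcChartSpec(method=method))
        assert lim.sigma == 0.0
        assert lim.upper(3) == lim.lower(3) == lim.center == 7.0
        verdicts = evaluate_violations(s, lim, "cl23")
        assert (verdicts["status"] == "in_control").all()
        assert (evaluate_violations(s, lim, "nelson")["status"] == "in_control").all()


def test_methods_share_center_on_any_series():
    rng = np.random.default_rng(5)
    s = make_series(rng.normal(100, 5, 30))
    lj = estimate_limits(s, SpcChartSpec(method="levey_jennings"))
    imr = estimate_limits(s, SpcChartSpec(method="imr"))
    assert lj.center == pytest.approx(imr.center)


def test_shewhart_limits_fixed_by_reference_subset():
    rng = np.random.default_rng(6)
    base = rng.normal(100, 5, 25)
    spec = SpcChartSpec(method="shewhart", reference_k=20)
    lim_a = estimate_limits(make_series(base), spec)
    shifted = base.copy()
    shifted[20:] += 500  # points after the reference window
    lim_b = estimate_limits(make_series(shifted), spec)
    assert lim_a.center == lim_b.center
    assert lim_a.sigma == lim_b.sigma
    ref = base[:20]
    assert lim_a.center == pytest.approx(ref.mean())
    assert lim_a.sigma == pytest.approx(ref.std(ddof=1))


def test_insufficient_data_errors():
    with pytest.raises(InsufficientDataError, match="2"):
        estimate_limits(make_series([1.0]), SpcChartSpec(method="imr"))
    with pytest.raises(InsufficientDataError, match="20"):
        estimate_limits(make_series(range(10)), SpcChartSpec(method="shewhart"))
    with pytest.raises(InsufficientDataError):
        moving_range_chart(make_series([1.0]))


# ---------------------------------------------------------------- moving range


def test_moving_range_hand_example():
    """(10, 12, 11, 14) -> MR (2, 1, 3), mean 2.0, UCL = 2.0 x 3.267."""
    chart = moving_range_chart(make_series([10, 12, 11, 14]))
    assert chart.points["mr"].tolist() == [2.0, 1.0, 3.0]
    assert chart.mean_mr == pytest.approx(2.0)
    assert chart.ucl == pytest.approx(6.534)
    assert chart.ucl / chart.mean_mr == pytest.approx(D4_MOVING_RANGE)


def test_moving_range_constant_series():
    chart = moving_range_chart(make_series([5.0] * 10))
    assert (chart.points["mr"] == 0).all()
    assert chart.ucl == 0.0
    assert not chart.points["out_of_control"].any()


def test_moving_range_flags_at_or_above_ucl():
    chart = moving_range_chart(make_series([0, 1, 0, 1, 0, 1, 0, 50]))
    flagged = chart.points[chart.points["out_of_control"]]
    assert flagged["mr"].tolist() == [50.0]


# ------------------------------------------------------------------ protocols


def test_cl23_inclusive_at_three_sigma():
    """A point exactly at center + 3 sigma is out of control (inclusive)."""
    s = make_series([10, 12, 11, 14])
    lim = estimate_limits(s, SpcChartSpec(method="imr"))
    probe = make_series(list(s.values) + [lim.upper(3)])
    verdicts = evaluate_violations(probe, lim, "cl23")
    assert verdicts["status"].iloc[-1] == "out_of_control"
    just_in = make_series(list(s.values) + [np.nextafter(lim.upper(3), lim.center)])
    v2 = evaluate_violations(just_in, lim, "cl23")
    assert v2["status"].iloc[-1] != "out_of_control"


def test_cl2_warning_band():
    s = make_series([10, 12, 11, 14])
    lim = estimate_limits(s, SpcChartSpec(method="imr"))
    probe = make_series([lim.center + 2.5 * lim.sigma])
    verdicts = evaluate_violations(probe, lim, "cl23")
    assert verdicts["status"].iloc[0] == "cl2_warning"


def test_nelson_rule1_strict_beyond():
    center, sigma = 12.0, 2.0  # exact binary floats: the boundary is exact
    hits = nelson_rule_hits(np.array([12.0, center + 3 * sigma]), center, sigma)
    assert 1 not in hits[-1]  # exactly at 3 sigma: not beyond
    hits = nelson_rule_hits(np.array([12.0, center + 3 * sigma + 0.01]), center, sigma)
    assert 1 in hits[-1]


def test_nelson_rule2_fires_at_ninth_point():
    values = [5.0] * 3 + [11.0] * 9  # center pulled below the run
    center = float(np.mean(values))
    hits = nelson_rule_hits(np.array(values), center, 10.0)
    fired = {i for i, h in enumerate(hits) if 2 in h}
    assert fired == nelson_rule2_scan(values, center)
    assert min(fired) == 11  # the 9th consecutive same-side point


def test_nelson_rule3_monotone_run():
    values = np.array([5, 4, 1, 2, 3, 4, 5, 6, 3], dtype=float)
    hits = nelson_rule_hits(values, float(values.mean()), 10.0)
    assert 3 in hits[7]  # 1,2,3,4,5,6 completes at index 7
    assert all(3 not in h for h in hits[:7])


def test_nelson_rule4_alternation():
    values = [10 + (1 if i % 2 else -1) for i in range(14)]
    hits = nelson_rule_hits(np.array(values, dtype=float), 10.0, 5.0)
    assert 4 in hits[13]
    assert all(4 not in h for h in hits[:13])


def test_nelson_zone_rules_5_and_6():
    sigma, center = 1.0, 0.0
    values = np.array([2.5, 0.0, 2.5, 0, 0, 0, 0, 0], dtype=float)
    hits = nelson_rule_hits(values, center, sigma)
    assert 5 in hits[2]  # 2 of 3 beyond 2 sigma, same side
    values6 = np.array([1.5, 1.5, 0.0, 1.5, 1.5, 0, 0], dtype=float)
    hits6 = nelson_rule_hits(values6, center, sigma)
    assert 6 in hits6[4]  # 4 of 5 beyond 1 sigma, same side


def test_nelson_zone_rules_7_and_8():
    sigma, center = 1.0, 0.0
    inside = np.array([0.5, -0.5] * 8, dtype=float)  # 16 points within 1 sigma
    hits = nelson_rule_hits(inside, center, sigma)
    assert 7 in hits[14] and 7 in hits[15]
    outside = np.array([1.5, -1.5] * 4, dtype=float)  # 8 beyond 1 sigma
    hits8 = nelson_rule_hits(outside, center, sigma)
    assert 8 in hits8[7]
    assert all(8 not in h for h in hits8[:7])


def test_nelson_run_lengths_configurable():
    values = [1.0] * 5 + [0.0]
    cfg = NelsonConfig(rule2_run=5)
    hits = nelson_rule_hits(np.array(values), 0.5, 10.0, cfg)
    assert 2 in hits[4]


# ------------------------------------------------------------ series building


def test_duplicate_control_wells_averaged(merged_full):
    series = build_control_series(merged_full, "pos800", "antigen-3")
    plate1 = merged_full[
        (merged_full["batch_name"] == "plate 1")
        & (merged_full["sample_id"] == "pos800")
        & (merged_full["antigen"] == "antigen-3")
    ]
    assert len(plate1) == 2  # run in duplicate
    expected = plate1["net_mfi"].mean()
    got = series.points.set_index("batch_name").loc["plate 1", "value"]
    assert got == pytest.approx(expected)


def test_simple_mean_example():
    ds = pd.DataFrame(
        {
            "batch_name": ["p1", "p1"],
            "batch_datetime": pd.to_datetime(["2023-01-01"] * 2),
            "sample_id": ["neg", "neg"],
            "role": ["control", "control"],
            "antigen": ["ag", "ag"],
            "net_mfi": [100.0, 110.0],
        }
    )
    series = build_control_series(ds, "neg", "ag")
    assert series.points["value"].item() == pytest.approx(105.0)


def test_series_sorted_chronologically_despite_upload_order(merged_full):
    shuffled = merged_full.sample(frac=1.0, random_state=0)
    series = build_control_series(shuffled, "neg", "antigen-3")
    times = series.points["batch_datetime"].to_numpy()
    assert (np.diff(times) > np.timedelta64(0, "s")).all()
    assert series.points["observation"].tolist() == list(range(1, len(series) + 1))


def test_missing_plates_counted(merged_full):
    """antigen-2 is present on 19 of 32 plates: series length 19, 13 missing."""
    series = build_control_series(merged_full, "pos7200", "antigen-2")
    assert len(series) == 19
    assert series.n_missing == 13
    full = build_control_series(merged_full, "pos7200", "antigen-3")
    assert len(full) == 32 and full.n_missing == 0


def test_empty_series_error(merged_full):
    with pytest.raises(EmptySeriesError):
        build_control_series(merged_full, "not-a-control", "antigen-3")


def test_simple_four_column_csv(tmp_path):
    path = tmp_path / "controls.csv"
    path.write_text(
        "date,control,antigen,value\n"
        "2023-01-02,neg,ag,12\n"
        "2023-01-01,neg,ag,10\n"
        "2023-01-03,neg,ag,11\n"
        "2023-01-04,neg,ag,14\n"
        "2023-01-04,pos,ag,99\n"
    )
    table = read_simple_control_csv(path)
    series = build_control_series(table, "neg", "ag")
    assert series.points["value"].tolist() == [10.0, 12.0, 11.0, 14.0]
    lim = estimate_limits(series, SpcChartSpec(method="imr"))
    assert lim.sigma == pytest.approx(2.0 / D2_INDIVIDUALS)


# -------------------------------------------------------------------- summary


def test_summary_pct_out_of_control():
    values = list(np.tile([10.0, 12, 11, 14], 5))
    s = make_series(values[:19] + [200.0])  # 1 of 20 far out
    spec = SpcChartSpec(method="levey_jennings")
    lim = estimate_limits(s, spec)
    verdicts = evaluate_violations(s, lim, "cl23")
    from mbaqc.control import ControlTrackingResult

    res = ControlTrackingResult(s, lim, verdicts, None, spec)
    summary, flagged = spc_summary([res])
    row = summary.iloc[0]
    assert row["n_points"] == 20
    assert row["pct_out_of_control"] == pytest.approx(100.0 * row["n_out_of_control"] / 20)
    assert row["mean"] == pytest.approx(np.mean(s.values))
    assert row["upper_3sigma"] == pytest.approx(lim.upper(3))
    assert len(flagged) == 20  # per-point table covers every charted point
    assert flagged["repeat"].sum() == row["n_out_of_control"] + row["n_cl2_warning"]


def test_track_controls_covers_all_pairs(merged_full):
    results = track_controls(merged_full, SpcChartSpec(method="imr"))
    pairs = {(r.series.control, r.series.antigen) for r in results}
    assert len(pairs) == 4 * 3  # 4 controls x 3 antigens
    summary, _ = spc_summary(results)
    assert set(summary["antigen"]) == {"antigen-1", "antigen-2", "antigen-3"}


# -------------------------------------------------------- statistical checks


def test_imr_sigma_estimate_unbiased():
    """mean MR / d2 recovers the true sigma of iid normal data (n = 10^4)."""
    rng = np.random.default_rng(12345)
    true_sigma = 7.0
    s = make_series(rng.normal(50.0, true_sigma, 10_000))
    lim = estimate_limits(s, SpcChartSpec(method="imr"))
    assert lim.sigma == pytest.approx(true_sigma, rel=0.01)


def test_levey_jennings_three_sigma_coverage():
    """Fraction of iid normal points beyond +-3 sigma ~ 0.0027 (n = 10^5)."""
    rng = np.random.default_rng(20240501)
    n = 100_000
    values = rng.normal(0.0, 1.0, n)
    pts = pd.DataFrame(
        {
            "observation": np.arange(1, n + 1),
            "batch_name": np.char.add("p", np.arange(n).astype(str)),
            "batch_datetime": pd.date_range("2020-01-01", periods=n, freq="min"),
            "value": values,
        }
    )
    s = ControlSeries("c", "a", pts, True, 0)
    lim = estimate_limits(s, SpcChartSpec(method="levey_jennings"))
    verdicts = evaluate_violations(s, lim, "cl23")
    frac = (verdicts["status"] == "out_of_control").mean()
    p = 0.0027
    ci = 2.576 * np.sqrt(p * (1 - p) / n)
    assert abs(frac - p) < ci
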