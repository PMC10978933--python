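"""Bead-count flagging, plate summaries and fluctuation series."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mbaqc.bead_qc import (
    BeadQCConfig,
    classify_counts,
    flag_bead_counts,
    fluctuation_series,
    summarize_bead_qc,
)
from mbaqc.errors import UnknownAntigenError
from mbaqc.io import merge_plates, parse_xponent
from mbaqc.synth import AnomalySpec, SyntheticStudySpec, generate_study

from _oracles import bead_flags_bruteforce


@pytest.mark.parametrize(
    "count, flag",
    [(0, "fail"), (19, "fail"), (20, "warn"), (34, "warn"), (35, "pass"), (500, "pass")],
)
def test_default_threshold_boundaries(count, flag):
    """fail below 20, warn below 35, pass at/above 35 — strict '<' rules."""
    assert classify_counts([count], BeadQCConfig())[0] == flag


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    counts=st.lists(st.integers(min_value=0, max_value=200), min_size=1, max_size=60),
    lower=st.integers(min_value=0, max_value=50),
    delta=st.integers(min_value=0, max_value=50),
)
def test_flag_partition_and_threshold_monotonicity(counts, lower, delta):
    cfg = BeadQCConfig(lower_threshold=lower, upper_threshold=lower + delta)
    flags = classify_counts(counts, cfg)
    assert set(flags) <= {"pass", "warn", "fail"}  # exactly one flag per record
    # raising the lower threshold never decreases fails
    cfg_up = BeadQCConfig(lower_threshold=lower + 1, upper_threshold=lower + delta + 1)
    assert (classify_counts(counts, cfg_up) == "fail").sum() >= (flags == "fail").sum()
    # raising the upper threshold never decreases warn+fail
    cfg_wide = BeadQCConfig(lower_threshold=lower, upper_threshold=lower + delta + 5)
    assert (classify_counts(counts, cfg_wide) != "pass").sum() >= (flags != "pass").sum()


def test_flags_match_bruteforce_oracle(small_study):
    """Package flags equal a naive per-record scan on every well-antigen
    record of a study with injected low-bead plates."""
    _, paths, _ = small_study
    ds = merge_plates([parse_xponent(p) for p in paths])
    flagged = flag_bead_counts(ds)
    oracle = bead_flags_bruteforce(ds["bead_count"].tolist())
    assert flagged["bead_flag"].tolist() == oracle


def _make_flagged(n_fail: int, n_total: int = 96) -> pd.DataFrame:
    counts = [0] * n_fail + [100] * (n_total - n_fail)
    return pd.DataFrame(
        {
            "batch_name": "plate x",
            "antigen": "ag",
            "role": "unknown",
            "bead_count": counts,
            "bead_flag": ["fail"] * n_fail + ["pass"] * (n_total - n_fail),
        }
    )


@pytest.mark.parametrize(
    "n_fail, n_total, failed",
    [
        (29, 96, True),  # 30.2% >= 30%
        (28, 96, False),  # 29.2%
        (30, 100, True),  # exactly 30.0%: inclusive
        (0, 96, False),
    ],
)
def test_plate_failure_fraction_inclusive(n_fail, n_total, failed):
    per_antigen, per_plate = summarize_bead_qc(_make_flagged(n_fail, n_total))
    assert per_antigen["fraction_failed"].item() == pytest.approx(n_fail / n_total)
    assert per_antigen["plate_failed"].item() == failed
    assert per_plate["n_failed_antigens"].item() == (1 if failed else 0)


def test_injected_low_bead_plates_fail_exactly(small_study):
    """Only the plates targeted by the low-bead injection fail the >=30% rule."""
    _, paths, truth = small_study
    ds = merge_plates([parse_xponent(p) for p in paths])
    per_antigen, _ = summarize_bead_qc(flag_bead_counts(ds))
    failed_batches = set(per_antigen.loc[per_antigen["plate_failed"], "batch_name"])
    assert failed_batches == set(truth["bead"]["batch_name"])


def test_ground_truth_flags_recovered(small_study):
    _, paths, truth = small_study
    ds = merge_plates([parse_xponent(p) for p in paths])
    flagged = flag_bead_counts(ds).set_index(["batch_name", "well", "antigen"])
    for _, row in truth["bead"].iterrows():
        rec = flagged.loc[(row["batch_name"], row["well"], row["antigen"])]
        assert rec["bead_flag"] == row["expected_flag"]


def test_fluctuation_series_order_and_mean(one_plate):
    antigen = one_plate.antigens[0]
    series = fluctuation_series(one_plate, antigen)
    orders = series.points["read_order"].to_numpy()
    assert (np.diff(orders) > 0).all()
    assert series.mean_count == pytest.approx(series.points["bead_count"].mean())
    assert series.thresholds == (20, 35)


def test_fluctuation_unknown_antigen_lists_available(one_plate):
    with pytest.raises(UnknownAntigenError, match="antigen-1"):
        fluctuation_series(one_plate, "nonexistent")


def test_simulated_clog_fails_only_late_reads(tmp_path):
    """Counts forced low after read 48 produce fail flags only there."""
    spec = SyntheticStudySpec(n_plates=1, seed=21)
    (path,), _ = generate_study(spec, [], tmp_path)
    plate = parse_xponent(path)
    rec = plate.records.copy()
    rec.loc[rec["read_order"] > 48, "bead_count"] = 5
    rec.loc[rec["read_order"] <= 48, "bead_count"] = 80
    plate.records = rec
    series = fluctuation_series(plate, plate.antigens[0])
    fails = series.points[series.points["bead_flag"] == "fail"]
    assert len(fails) == 48
    assert (fails["read_order"] > 48).all()


def test_role_restricted_denominator():
    df = _make_flagged(10, 96)
    df.loc[:4, "role"] = "standard"  # 5 failing standards
    cfg = BeadQCConfig(include_all_roles=False)
    per_antigen, _ = summarize_bead_qc(df, cfg)
    assert per_antigen["n_wells"].item() == 91
    assert per_antigen["n_failed"].item() == 5
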