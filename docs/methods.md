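# Methods

This note documents the statistical procedures, the defaults and the
design choices behind `mbaqc`, and what the synthetic-data tests do and
do not demonstrate about real instrument data.

## Data model

All QC modules read one long-format table with a row per
(batch, well, antigen) and columns `mfi` (median fluorescence intensity,
arbitrary units), `net_mfi` (MFI minus background, may be negative),
`bead_count` (non-negative integer), `sample_id`, `role`
(standard/control/background/unknown), `read_order` (position of the well
row in the source file), plus plate metadata (batch name, run date-time,
instrument serial number, source file). Within a plate, (well, antigen)
is unique and every antigen is observed on the same well set; across a
merged dataset, (batch, well, antigen) is unique.

**Role inference.** Instrument files carry no explicit role column, so
roles are derived from the sample-ID labelling convention: exact
case-insensitive matches of the configured control names (default `neg`,
`pos800`, `pos2400`, `pos7200`), prefixes `Standard`/`Background`, and the
short prefixes `S`/`B` only when followed entirely by digits (so `Serum12`
remains an unknown). The convention is configurable via `RoleConfig`.
`pos2400` is included as the fourth default so that a plate carries a
negative pool and positive pools at three dilutions; studies with three
controls simply never match the fourth name.

**Timestamps** parse as ISO-8601 with a single US-style fallback
(`MM/DD/YYYY HH:MM`); anything else is a hard parse error rather than a
silent default, because the control charts depend on correct chronology.
Equal run date-times are tie-broken by batch name (lexicographic), then
input order, to keep chart ordering deterministic.

**Net MFI reconciliation.** Instrument files can carry both a
precomputed net-MFI block and background wells, and the two need not
agree. Both are kept: the `net_mfi` column is whatever the file reports,
while MFI *flagging* always recomputes against the background wells (max
MFI over background wells per antigen). Control tracking uses the
`net_mfi` column by default (switchable to raw MFI).

## Bead-count QC

A well **fails** when `bead_count < lower` (default 20) and **warns**
when `lower ≤ bead_count < upper` (default 35); both comparisons are
strict `<` at the threshold, so a count of exactly 20 warns and 35
passes. A plate fails an antigen when
`fraction_failed ≥ plate_fail_fraction` (default 0.30, inclusive — a
plate with exactly 30.0 % failed wells is failed). Wells with no data for
an antigen are excluded from the denominator; a config switch restricts
the denominator to sample+control wells (standards and backgrounds are
still flagged per well, they just stop counting toward plate failure).
Flags are computed per antigen and never pooled: the per-plate table then
lists which antigens failed on each plate.

## MFI QC

Per plate and antigen, the background threshold is the **maximum** raw
MFI over the background wells. A well is **red** when its raw MFI is at
or below that threshold (inclusive; background wells are therefore red by
definition) and **yellow** when it is above background but its
background-based net MFI is at or below the warning level (default 100,
inclusive). Red takes precedence. There is deliberately no MFI-based
plate pass/fail verdict — the flags support visual pattern review
(row/column artifacts from pipetting errors) rather than an automated
call. Heatmaps use log10 of the *raw* MFI so background subtraction
cannot produce undefined values; non-positive or missing MFI renders as
an absent (NA) cell.

## Control tracking

For each control–antigen pair, replicate control wells on a plate are
averaged (arithmetic mean) into one point; plates lacking the pair are
excluded from all computations and counted as missing. Points are sorted
chronologically. Three chart methods:

* **Levey-Jennings** — center = mean, σ = sample standard deviation
  (n−1) over all points (the long-term estimate).
* **I-MR** — center = mean; σ = (mean moving range)/d₂ with d₂ = 1.128,
  the expected relative range of subgroups of size 2 under normality, so
  mean-MR/d₂ is an unbiased short-term σ estimate. The companion MR chart
  plots |Δ| between consecutive points against UCL = D₄ × mean MR with
  D₄ = 3.267; a range at or above the UCL is out of control. The UCL rule
  is guarded with `UCL > 0`: on a constant series every range is zero and
  the literal `mr ≥ 0` would flag everything.
* **modified Shewhart** — center and σ (sample SD) from the first
  `reference_k` points only (default 20; at least that many points are
  required), applied to the whole series. The reference subset's sample
  SD is used for σ rather than its mean moving range; the choice is a
  convention and is stated here because both are defensible.

**Violation protocols.** Under `cl23`, a point at or **outside 3σ**
(inclusive) is out of control and a point strictly outside 2σ (but not
out of control) is a CL2 warning. With σ = 0 (constant series) only a
nonzero deviation violates, so a constant series has no violations.
Under `nelson`, the eight standard run rules are scanned — (1) one point
beyond 3σ, (2) 9 in a row on one side of center, (3) 6 in a row monotone,
(4) 14 in a row alternating, (5) 2 of 3 beyond 2σ same side, (6) 4 of 5
beyond 1σ same side, (7) 15 in a row within 1σ, (8) 8 in a row beyond 1σ
either side — with run lengths configurable. Zone rules use strict
"beyond"; rule 1 is therefore strict while the cl23 protocol's 3σ bound
is inclusive, matching the respective conventions; both are asserted in
tests. Points exactly on the center line belong to neither side and
break side-runs. A rule is recorded at the point where its pattern
completes and at every point extending it. A point's status is
out-of-control iff any rule fires there, with the rule numbers recorded.

The **flagged-plates table** carries every charted point (observation
number, date, control, antigen, batch, value, status, rule numbers) with
a boolean `repeat` column marking any point whose verdict is not
in-control — the operational "candidate plates to repeat" notion, left as
a flag for user review rather than an automated repeat decision. The
**summary table** reports, per pair: missing points; mean, median, max,
min, SD of the tracked value; 1–3σ upper/lower limits; % out of control;
and counts per violation type.

A simplified four-column CSV (`date, control, antigen, value`) is
accepted in lieu of instrument files for control tracking only.

## Synthetic studies

The generator emulates a serosurveillance study: per plate, a 10-step
threefold standard curve in singlet (top 30 000 MFI), four controls,
background, and 38 samples in duplicate — 96 occupied wells, filled
row-major A1..H12 so read order is the well order. Baseline MFI is
lognormal around a per-role level (multiplicative noise σ = 0.05 on the
log scale; controls at 60/9 000/3 500/1 200 MFI; samples with
log10-normal(2.7, 0.6) latent levels shared by duplicates; background
≈ 30), and bead counts are negative-binomial (mean 80, size 50, so
baseline counts below 20 are ~4σ events). The default 32-plate panel
places antigen-1 on plates 1–29, antigen-2 on plates 14–32 and antigen-3
everywhere, reproducing an unequal 29/19/32 coverage; run date-times
advance one day per plate. Values are written at fixed precision, which
makes generation and the CSV dialect byte-stable: same seed ⇒ identical
bytes, and parse → serialize is the identity.

Anomalies: `low_bead_bias` multiplies a plate's counts by 0.18 (mean
drops to ~14, far past the 30 % failure rule); `row_artifact` /
`column_artifact` force a full row/column (default row D, column 5 —
positions that avoid the background wells) to a uniform fraction of the
background MFI across all antigens, guaranteeing red flags;
`control_shift` multiplies one control's MFI by 6 on each target plate,
rotating through the four controls so each affected series carries a
single isolated spike — a deviation that dominates any of the three σ
estimates and is out of control under every chart method. Every injected
cell/point is recorded in ground-truth tables with the flag it must
receive at default configuration. (Had several shifts landed in the
*same* series, the sustained contamination of the moving-range σ could
pull an individual shifted point toward the 3σ boundary; the rotation
avoids relying on that margin.)

**What the synthetic tests do not show.** Real exports vary in header
layout, locale formatting and firmware dialects beyond the documented
one; real MFI distributions are heavier-tailed and drift with reagent
lots; real bead-count failures are spatially correlated (clogs) rather
than plate-wide rescalings. Passing the oracle-agreement tests
demonstrates the correctness of the flagging and charting arithmetic, not
robustness to arbitrary vendor files.

## Problem sizes and numerics

The test suite uses 5-plate and 32-plate studies (the sizes of the
validation designs), 10⁴ points for the σ-unbiasedness check and 10⁵
points for the 3σ-coverage check (binomial 99 % CI around 0.0027).
Flag comparisons at thresholds are exact integer comparisons; chart
boundaries are floating-point and the inclusive/exclusive behaviour is
tested at exactly representable values. All randomness flows from a
single integer seed through `numpy.random.default_rng`.

## Known limitations

* Only the documented xPONENT-style CSV dialect and BPM-style workbook
  layout are parsed; 384-well and multi-plate files are rejected by
  design, not supported.
* No MFI-based plate failure verdict, no automated root-cause
  classification (clog vs pipetting), no interactive charts.
* The Shewhart method requires at least `reference_k` points; short
  studies should use Levey-Jennings or I-MR (at least 20 plates are
  recommended before fixing Shewhart limits).
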