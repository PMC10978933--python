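# mbaqc — quality control for multiplex bead assay serosurveillance data

Serological surveillance studies increasingly use the Luminex xMAP
multiplex bead assay (MBA) to measure antibodies against many antigens at
once on 96-well plates. Every plate and every antigen must pass quality
control before its median fluorescence intensity (MFI) values can be
trusted: wells need enough beads per antigen region for a reliable median,
signal must sit clearly above the plate's buffer-only background, and the
assay controls carried on every plate must stay inside statistical process
control limits across the weeks or months of a study. Doing this by hand in
spreadsheets is slow and error-prone once a study grows to dozens of plates
and 20 antigens.

`mbaqc` is a Python library (with a thin CLI) for exactly this workflow.
It is aimed at laboratory scientists and epidemiologists running MBA
serosurveys, and at analysts who need the merged per-well dataset the QC
is computed from.

## What it does

1. **Parse and merge.** Reads single-plate xPONENT-style CSV exports and
   Bio-Plex-Manager-style workbooks (sheets `FI`, `FI—Bkgd`, `Bead
   Count`), validates the 96-well layout, and merges any number of plates
   — plus previously merged datasets — into one long-format table: one
   row per (batch, well, antigen) with MFI, net MFI, bead count, well
   role, read order and plate metadata.
2. **Bead-count QC.** Wells are flagged `fail` when the bead count is
   below the lower threshold (default 20 beads/well) and `warn` below the
   upper threshold (default 35, the vendor-recommended minimum). A plate
   fails an antigen when the fraction of failed wells is ≥ 30 %
   (inclusive). Fluctuation series in instrument read order expose
   clogging patterns.
3. **MFI QC.** Wells at or below the plate background (the highest
   background well per antigen) are flagged red; wells above background
   with net MFI at or below a warning level (default 100) are yellow.
   Log10 plate heatmaps of the raw MFI visualise plate-wide patterns.
4. **Control tracking.** For every control–antigen pair the
   background-subtracted control MFI is averaged over replicate wells,
   ordered by run date and charted with one of

   * **Levey-Jennings**: center x̄, σ = long-term sample SD,
   * **I-MR**: σ = (mean moving range)/d₂ with d₂ = 1.128; companion MR
     chart with UCL = D₄ × (mean MR), D₄ = 3.267,
   * **modified Shewhart**: center and σ frozen from the first *k*
     reference plates (default 20).

   Violations follow either the 2σ/3σ protocol (at or outside 3σ ⇒ out of
   control; outside 2σ ⇒ CL2 warning) or the eight standard Nelson run
   rules.
5. **Reporting.** `run_pipeline` writes the download bundle: long/wide
   merged datasets, a four-table bead summary workbook, zipped faceted
   plots (bead plate/fluctuation, MFI plate, heatmaps, control charts) and
   the control-tracking point and summary CSVs.
6. **Synthetic studies.** A deterministic generator emulates a full study
   (10-step threefold standard curve in singlet; 4 controls, background
   and 38 samples in duplicate = 96 wells) with injectable anomalies —
   low-bead plates, row/column MFI artifacts, shifted controls — and
   ground-truth tables of the flags each anomaly must receive.

## Worked example

```python
from mbaqc import (SyntheticStudySpec, default_anomalies, generate_study,
                   parse_xponent, merge_plates, flag_bead_counts,
                   summarize_bead_qc)

paths, truth = generate_study(SyntheticStudySpec(seed=1),
                              default_anomalies(), "scratch/example_study")
merged = merge_plates([parse_xponent(p) for p in paths])
per_antigen, per_plate = summarize_bead_qc(flag_bead_counts(merged))
print(per_antigen[per_antigen["plate_failed"]]
      [["batch_name", "antigen", "fraction_failed"]].to_string(index=False))
```

prints

```
batch_name   antigen  fraction_failed
  plate 10 antigen-1         0.989583
  plate 10 antigen-3         0.979167
  plate 25 antigen-1         0.989583
  plate 25 antigen-2         0.979167
  plate 25 antigen-3         1.000000
```

— the only failed plate–antigen combinations are on plates 10 and 25, the
two plates whose bead counts the generator biased low; `fraction_failed`
is the share of that plate's 96 wells below 20 beads. Control tracking on
the same study (`examples/05_control_tracking.py`) flags the four
shifted-control plates as out of control, e.g.

```
control   antigen batch_name   value         status
    neg antigen-1    plate 7   357.7 out_of_control
 pos800 antigen-1   plate 11 51428.2 out_of_control
pos2400 antigen-2   plate 14 21420.1 out_of_control
pos7200 antigen-3   plate 29  7455.6 out_of_control
```

The `examples/` directory has one short script per capability
(simulation, parsing/merging, bead QC, MFI flags, control tracking, full
report); each prints the numbers it computes and what they mean. The same
operations are available from the shell:

```bash
mbaqc simulate --out study --seed 1
mbaqc report study/plate_*.csv --out report
mbaqc control-track study/plate_*.csv --method imr --protocol cl23 --out ct
```

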