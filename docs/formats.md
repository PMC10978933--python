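# File formats

## xPONENT-style single-plate CSV

One file per 96-well plate run. A short key-value metadata header is
followed by three labelled blocks, each introduced by a `DataType:`
marker line. Quoted fields, a UTF-8 byte-order mark and trailing empty
lines are tolerated; extra vendor blocks are skipped.

```
Program,xPONENT
Batch,plate 1
Date,2023-01-05 09:30:00
SN,LX200-12345
PlateFormat,96

DataType:,Median
Location,Sample,antigen-1,antigen-2
A1,Standard1,31017.4,28815.9
A2,Standard2,9379.2,10112.3
...

DataType:,Net MFI
Location,Sample,antigen-1,antigen-2
A1,Standard1,30987.8,28786.1
...

DataType:,Count
Location,Sample,antigen-1,antigen-2
A1,Standard1,63,71
...
```

* `Median` = raw MFI, `Net MFI` = background-subtracted MFI, `Count` =
  bead count; each block has one row per well (well location, sample ID,
  one column per antigen), all blocks over the same wells and antigens.
* Row order defines the instrument read order.
* A repeated block of the same type, a `PlateFormat` other than 96, or a
  well address outside A1..H12 means a multi-plate or 384-well file and
  is rejected as an unsupported layout.
* Dates are ISO-8601, with `MM/DD/YYYY HH:MM` accepted as a fallback.

## Bio-Plex-Manager-style workbook (`.xlsx`)

Multiple-analyte layout with three required sheets: `FI` (raw MFI),
`FI—Bkgd` (net MFI; em dash, en dash or hyphen accepted) and
`Bead Count`. Each sheet has a header row `Well, Sample, <antigen>...`
followed by one row per well; the `FI` sheet may carry the key-value
metadata rows (`Batch`, `Date`, `SN`, `PlateFormat`) above its table.
Sheets are aligned by well address, so row order may differ between
sheets. A missing sheet raises an error naming it.

## Merged long-format dataset (CSV)

One row per (batch, well, antigen); columns `batch_name`,
`batch_datetime`, `instrument_serial`, `source_file`, `plate_format`,
`well`, `well_row`, `well_col`, `sample_id`, `role`, `antigen`, `mfi`,
`net_mfi`, `bead_count`, `read_order`. This is what `Raw_data.csv`
contains and what `import_merged` re-reads; it can be uploaded alongside
or in lieu of instrument files.

## Simplified control CSV

Four columns — `date, control, antigen, value` — accepted by the
control-tracking module in lieu of instrument files. Replicate rows per
date are averaged.
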