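"""Parse single-plate instrument files and merge them into the long-format
dataset every QC module reads.

Run examples/01_simulate_study.py first to create the input files.
"""

from pathlib import Path

from mbaqc import export_dataset, merge_plates, parse_xponent

paths = sorted(Path("scratch/example_study").glob("plate_*.csv"))
plates = [parse_xponent(p) for p in paths]
merged = merge_plates(plates)

print(f"parsed {len(plates)} plates; merged dataset has {len(merged)} records")
print(f"(one record per batch x well x antigen; "
      f"{merged['batch_name'].nunique()} batches, "
      f"{merged['antigen'].nunique()} antigens)")
long_path = export_dataset(merged, "long", Path("scratch/Raw_data.csv"))
wide_path = export_dataset(merged, "wide", Path("scratch/Raw_data_wide.csv"))
print(f"exports: {long_path} (long), {wide_path} (wide)")
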