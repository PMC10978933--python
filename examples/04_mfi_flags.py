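"""Flag wells by MFI against the plate background and build a heatmap.

Red: raw MFI at or below the highest background well (signal
indistinguishable from buffer).  Yellow: above background but net MFI at
or below the warning level (default 100).  Run
examples/01_simulate_study.py first.
"""

from pathlib import Path

from mbaqc import flag_mfi, heatmap_matrix, parse_xponent, plate_background

plate = parse_xponent("scratch/example_study/plate_02.csv")  # column artifact
for antigen in plate.antigens:
    bg = plate_background(plate, antigen)
    flags = flag_mfi(plate, antigen)
    red = flags[flags["mfi_flag"] == "red"]
    by_col = {int(c): int(n) for c, n in red["well_col"].value_counts().sort_index().items()}
    print(f"{antigen}: background {bg:.1f} MFI, {len(red)} red wells "
          f"(per column: {by_col})")

# Column 5 is fully red for every antigen: the injected column-wise
# pipetting artifact.  The remaining red wells are the background wells
# themselves and the lowest standards.
hm = heatmap_matrix(plate, plate.antigens[0])
print(f"heatmap log10-MFI range: {hm.grid[~(hm.grid != hm.grid)].min():.2f}"
      f" .. {hm.grid[~(hm.grid != hm.grid)].max():.2f}")
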