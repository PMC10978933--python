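"""Flag wells by bead count and call failed plates.

A well fails below 20 beads (statistically unreliable), warns below 35
(the vendor-recommended minimum); a plate fails an antigen when >= 30% of
wells fail.  Run examples/01_simulate_study.py first.
"""

from pathlib import Path

from mbaqc import flag_bead_counts, merge_plates, parse_xponent, summarize_bead_qc

paths = sorted(Path("scratch/example_study").glob("plate_*.csv"))
merged = merge_plates([parse_xponent(p) for p in paths])

flagged = flag_bead_counts(merged)  # defaults: fail < 20, warn < 35
per_antigen, per_plate = summarize_bead_qc(flagged)

n_fail = (flagged["bead_flag"] == "fail").sum()
n_warn = (flagged["bead_flag"] == "warn").sum()
print(f"{n_fail} failing and {n_warn} warning wells of {len(flagged)} records")
print("\nfailed plate-antigen combinations (>= 30% failed wells):")
print(per_antigen[per_antigen["plate_failed"]]
      [["batch_name", "antigen", "fraction_failed"]].to_string(index=False))
print("\nantigens failed per plate:")
print(per_plate[per_plate["n_failed_antigens"] > 0].to_string(index=False))
# The two failed plates are exactly the ones the generator biased low.
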