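"""Generate a synthetic 32-plate study with the demonstration anomalies.

Writes one xPONENT-dialect CSV per plate plus ground-truth tables listing
every injected anomaly and the QC flag it should receive.
"""

from pathlib import Path

from mbaqc import SyntheticStudySpec, default_anomalies, generate_study

out = Path("scratch/example_study")
spec = SyntheticStudySpec(seed=1)  # 32 plates, 3 antigens, 4 controls
paths, truth = generate_study(spec, default_anomalies(), out)

print(f"wrote {len(paths)} plate files to {out}/")
print(f"low-bead ground truth rows:   {len(truth['bead'])}")
print(f"MFI-artifact ground truth:    {len(truth['mfi'])}")
print(f"shifted-control ground truth: {len(truth['control'])}")
print(truth["control"].to_string(index=False))
# Each row above is one control-antigen point that the control-tracking
# module must flag; the bead/MFI tables play the same role for the other
# QC modules.
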