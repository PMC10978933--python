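"""Shared helper: build a minimal one-antigen plate from well tuples."""

from datetime import datetime

import numpy as np
import pandas as pd

from mbaqc.io import PlateData, PlateMetadata


def tiny_plate(wells):
    """``wells``: iterable of (well, sample_id, role, mfi)."""
    rows = []
    for order, (well, sid, role, mfi) in enumerate(wells, start=1):
        rows.append(
            {
                "well": well,
                "well_row": well[0],
                "well_col": int(well[1:]),
                "sample_id": sid,
                "role": role,
                "antigen": "ag",
                "mfi": float(mfi),
                "net_mfi": np.nan,
                "bead_count": 50,
                "read_order": order,
            }
        )
    md = PlateMetadata("tiny", datetime(2023, 1, 1), "SN", "tiny.csv", 96)
    return PlateData(metadata=md, records=pd.DataFrame(rows))
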