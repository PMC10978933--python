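"""Independent brute-force re-implementations used as oracles.

These deliberately avoid the package's own code paths (and vectorised
numpy/pandas shortcuts): plain Python loops over plain records, the way a
spreadsheet recomputation would proceed.
"""

from __future__ import annotations


def bead_flags_bruteforce(counts, lower: int = 20, upper: int = 35) -> list[str]:
    """Naive per-record bead-count classification."""
    flags = []
    for count in counts:
        if count < lower:
            flags.append("fail")
        elif count < upper:
            flags.append("warn")
        else:
            flags.append("pass")
    return flags


def imr_cl23_spreadsheet(rows, control: str, antigen: str):
    """Spreadsheet-style I-MR 2/3-sigma verdicts for one control-antigen pair.

    ``rows``: iterable of plain dicts with keys batch_name, batch_datetime,
    sample_id, antigen, net_mfi.  Replicate wells are averaged per plate,
    plates sorted by run date (batch name as tie-break), sigma = mean
    moving range / 1.128, a point at/ outside 3 sigma is out of control and
    one outside 2 sigma is a warning.  Returns [(batch_name, status), ...]
    in chronological order.
    """
    per_plate: dict = {}
    for r in rows:
        if r["antigen"] != antigen:
            continue
        if str(r["sample_id"]).lower() != control.lower():
            continue
        key = (r["batch_datetime"], r["batch_name"])
        per_plate.setdefault(key, []).append(float(r["net_mfi"]))
    if not per_plate:
        return []
    points = sorted(per_plate.items())
    values = [sum(v) / len(v) for _, v in points]
    center = sum(values) / len(values)
    ranges = [abs(b - a) for a, b in zip(values, values[1:])]
    sigma = (sum(ranges) / len(ranges)) / 1.128 if ranges else 0.0
    out = []
    for (key, _), v in zip(points, values):
        dev = abs(v - center)
        if sigma > 0:
            if dev >= 3 * sigma:
                status = "out_of_control"
            elif dev > 2 * sigma:
                status = "cl2_warning"
            else:
                status = "in_control"
        else:
            status = "out_of_control" if dev > 0 else "in_control"
        out.append((key[1], status))
    return out


def nelson_rule2_scan(values, center, run: int = 9) -> set[int]:
    """Indices where a run of ``run`` same-side points completes."""
    hits = set()
    for i in range(len(values)):
        window = values[i - run + 1: i + 1] if i >= run - 1 else []
        if window and (all(v > center for v in window) or all(v < center for v in window)):
            hits.add(i)
    return hits
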