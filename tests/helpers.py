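"""Shared test utilities, including the independent rule oracle.

The brute-force oracle below re-states every screening rule as plain
scalar Python, written directly from the rule definitions.  It shares
no code with the vectorised engine and is the reference the engine is
checked against.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

THRESHOLD_RULES = {
    "second_if_ge_130_80": (130, 80),
    "second_if_ge_135_85": (135, 85),
    "second_if_ge_140_90": (140, 90),
}
WINDOW_RULES = {
    "second_if_130_145_80_95": (130, 145, 80, 95),
    "second_if_130_150_80_100": (130, 150, 80, 100),
    "second_if_130_155_80_105": (130, 155, 80, 105),
}


def brute_force_diagnoses(s1, s2, s3, d1, d2, d3) -> dict[str, bool]:
    """All ten rule outcomes for one reading triple, by direct restatement."""

    def htn(s, d):
        return s >= 140 or d >= 90

    out = {
        "standard": htn((s2 + s3) / 2, (d2 + d3) / 2),
        "first": htn(s1, d1),
        "second": htn(s2, d2),
        "avg_first_two": htn((s1 + s2) / 2, (d1 + d2) / 2),
    }
    for rule, (s_lo, d_lo) in THRESHOLD_RULES.items():
        if s1 >= s_lo or d1 >= d_lo:
            out[rule] = htn(s2, d2)
        else:
            out[rule] = htn(s1, d1)
    for rule, (s_lo, s_hi, d_lo, d_hi) in WINDOW_RULES.items():
        if (s_lo <= s1 <= s_hi) or (d_lo <= d1 <= d_hi):
            out[rule] = htn(s2, d2)
        else:
            out[rule] = htn(s1, d1)
    return out


def bp_records(triples) -> pd.DataFrame:
    """Build a minimal cohort frame from (s1,s2,s3,d1,d2,d3) tuples."""
    arr = np.asarray(triples, dtype=float)
    n = len(arr)
    return pd.DataFrame({
        "person_id": np.arange(n),
        "country": "C1",
        "region": "R1",
        "sbp1": arr[:, 0], "sbp2": arr[:, 1], "sbp3": arr[:, 2],
        "dbp1": arr[:, 3], "dbp2": arr[:, 4], "dbp3": arr[:, 5],
    })


#: Probe pairs for readings 2 and 3 in grid scans: straddle the 140/90
#: diagnostic boundary and the averaging behaviour of the mean-based rules.
SECOND_READING_PROBES = [(125, 75), (139, 89), (140, 90), (152, 96), (135, 91)]
THIRD_READING_PROBES = [(120, 70), (139, 89), (141, 91), (158, 99), (130, 95)]


def reading_grid(sbp_range=(118, 162), dbp_range=(72, 108)) -> pd.DataFrame:
    """Exhaustive first-reading grid crossed with the probe pairs."""
    rows = []
    for s1 in range(sbp_range[0], sbp_range[1] + 1):
        for d1 in range(dbp_range[0], dbp_range[1] + 1):
            for s2, d2 in SECOND_READING_PROBES:
                for s3, d3 in THIRD_READING_PROBES:
                    rows.append((s1, s2, s3, d1, d2, d3))
    return bp_records(rows)
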