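"""Bundled worked example: a six-case microdissection series.

Twelve TLS samples (two microdissected TLSs per case, six endometrial-cancer
cases) with their measured distance from the tumor invasive margin, total
in-frame IgG BCR reads, reads belonging to clones shared with the paired
intratumoral TIL sample, and the number of unique shared clones (top-30
clones per sample, CDR3 amino-acid identity).  Cases 1-3 carry only
margin-adjacent TLSs; cases 4-6 each carry at least one distal TLS.

One sample's total read count (case 3, TLS 2) is not recoverable from the
published material and is stored as missing; its shared-clone percentage is
therefore not computable here.

These numbers let the classification and overlap arithmetic be exercised on
real measured values without any slide or sequencing data.
"""

from __future__ import annotations

import pandas as pd

_ROWS = [
    # case, tls, distance_um, total_inframe_reads, common_clone_reads, unique_common_clones
    (1, 1, 140, 12954, 0, 0),
    (1, 2, 240, 10507, 0, 0),
    (2, 1, 160, 6086, 0, 0),
    (2, 2, 190, 20724, 17, 1),
    (3, 1, 300, 8035, 0, 0),
    (3, 2, 320, None, 1, 1),
    (4, 1, 565, 18430, 3651, 5),
    (4, 2, 850, 11271, 0, 0),
    (5, 1, 1230, 130044, 0, 0),
    (5, 2, 1880, 100542, 40155, 2),
    (6, 1, 1000, 12025, 1517, 4),
    (6, 2, 3760, 6151, 341, 1),
]


def repertoire_summary() -> pd.DataFrame:
    """The twelve microdissected TLS samples as a tidy table."""
    df = pd.DataFrame(
        _ROWS,
        columns=[
            "case", "tls_id", "distance_um", "total_inframe_reads",
            "common_clone_reads", "unique_common_clones",
        ],
    )
    df["total_inframe_reads"] = df["total_inframe_reads"].astype("Int64")
    return df


def cohort_stage_counts() -> dict[str, dict[str, int]]:
    """Per-cohort FIGO stage counts (institutional n=96, public archive n=463,
    checkpoint-inhibitor n=20); missing stage is its own level."""
    return {
        "institutional": {"I": 60, "II": 3, "III": 26, "IV": 3, "NA": 4},
        "archive": {"I": 295, "II": 43, "III": 102, "IV": 23},
        "ici": {"I": 4, "II": 1, "III": 12, "IV": 3},
    }


def cohort_histology_counts() -> dict[str, dict[str, int]]:
    """Per-cohort histology counts."""
    return {
        "institutional": {"endometrioid": 69, "serous": 26, "other": 1},
        "archive": {"endometrioid": 354, "serous": 109, "other": 0},
        "ici": {"endometrioid": 10, "serous": 1, "other": 9},
    }
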