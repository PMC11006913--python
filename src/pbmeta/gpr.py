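"""Reader/writer for the GPR-like probe quantification dialect.

Tab-separated text with >=2 leading ``key=value`` header lines (one pair
per line, ``PMTGain`` required) followed by a column-header row and one
row per probe.  Required columns::

    Block  Row  Column  ID  F_protein_Median  B_protein_Median
    F_cy3_Median  B_cy3_Median  Flags

Intensities are integers in [0, 65536]; negative GenePix-style flags mark
bad probes.  Reading then writing a file reproduces it byte-for-byte.
"""

from __future__ import annotations

import io
from pathlib import Path

import pandas as pd

REQUIRED_COLUMNS = [
    "Block", "Row", "Column", "ID",
    "F_protein_Median", "B_protein_Median",
    "F_cy3_Median", "B_cy3_Median", "Flags",
]


class GprFormatError(ValueError):
    pass


def read_gpr_frame(path) -> tuple[pd.DataFrame, dict]:
    """Parse a dialect file into (probe table, header metadata)."""
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path, "r", encoding="ascii") as fh:
        lines = fh.readlines()
    body_start = None
    for i, line in enumerate(lines):
        stripped = line.rstrip("\n")
        if "=" in stripped and "\t" not in stripped:
            key, _, value = stripped.partition("=")
            meta[key] = value
        else:
            body_start = i
            break
    if body_start is None or len(meta) < 2:
        raise GprFormatError(f"{path.name}: expected >=2 key=value header lines")
    if "PMTGain" not in meta:
        raise GprFormatError(f"{path.name}: missing PMTGain header")
    table = pd.read_csv(io.StringIO("".join(lines[body_start:])), sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise GprFormatError(f"{path.name}: missing required column(s) {missing}")
    if table["ID"].duplicated().any():
        dup = table.loc[table["ID"].duplicated(), "ID"].iloc[0]
        raise GprFormatError(f"{path.name}: duplicate probe_id {dup!r}")
    return table, meta


def write_gpr(path, table: pd.DataFrame, meta: dict) -> None:
    """Write a probe table in the dialect; inverse of :func:`read_gpr_frame`."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise GprFormatError(f"cannot write, missing column(s) {missing}")
    if "PMTGain" not in meta:
        raise GprFormatError("PMTGain metadata required")
    with open(path, "w", encoding="ascii", newline="\n") as fh:
        for key, value in meta.items():
            fh.write(f"{key}={value}\n")
        table.to_csv(fh, sep="\t", index=False, lineterminator="\n")
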