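"""Readers and writers for pair-assay tables, feature tables and FASTA.

All tabular I/O is UTF-8 CSV (RFC-4180 style) with a header row; tab
delimiters are accepted via ``delimiter="\\t"`` or a ``.tsv`` extension.
Readers validate rather than coerce: every rejection names the offending
1-based data row (header excluded).  Writers emit floats at six decimals
and preserve row order end-to-end, so downstream "keep first"
deduplication is well defined.

``read_feature_table`` also ingests externally published feature tables:
a case-insensitive alias map normalizes their column names onto the
canonical ten-feature order.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .pt_features import FACTORS, FEATURE_COLUMNS, LABEL_COLUMN, AssayRecord
from .star_entropy import InvalidSequenceError, validate_peptide

__all__ = [
    "PAIR_COLUMNS",
    "TableFormatError",
    "read_pairs_table",
    "write_pairs_table",
    "read_feature_table",
    "write_feature_table",
    "read_fasta",
    "write_descriptor_table",
    "write_json",
]

#: Canonical pair-table columns, in order.
PAIR_COLUMNS = (
    "query_seq",
    "ref_seq",
    "ref_activity",
    "query_activity",
    "org",
    "host",
    "proc",
    "tech",
    "adju",
)

# Case-insensitive aliases accepted for feature-table columns, covering
# plausible namings of deposited tables (subscripted theta/epsilon forms).
FEATURE_ALIASES: dict[str, tuple[str, ...]] = {
    "e_ref": ("e_ref", "er", "eref", "epsilon_r", "e(r)", "ref_class"),
    "q_theta5_seq": ("q_theta5_seq", "qtheta5_seq", "qtheta5(seq)", "q_t5_seq"),
    "q_theta0_org": ("q_theta0_org", "qtheta0_org", "qtheta0(org)", "q_t0_org"),
    "q_theta0_tech": ("q_theta0_tech", "qtheta0_tech", "qtheta0(tech)", "q_t0_tech"),
    "d_theta5_seq": ("d_theta5_seq", "dtheta5_seq", "dtheta5(seq)", "delta_theta5_seq"),
    "d_theta0_host": ("d_theta0_host", "dtheta0_host", "dtheta0(host)", "delta_theta0_host"),
    "d_theta0_adju": ("d_theta0_adju", "dtheta0_adju", "dtheta0(adju)", "delta_theta0_adju", "d_theta0_adj"),
    "d_theta0_proc": ("d_theta0_proc", "dtheta0_proc", "dtheta0(proc)", "delta_theta0_proc"),
    "d_theta0_org": ("d_theta0_org", "dtheta0_org", "dtheta0(org)", "delta_theta0_org"),
    "d_theta0_tech": ("d_theta0_tech", "dtheta0_tech", "dtheta0(tech)", "delta_theta0_tech"),
    LABEL_COLUMN: ("label", "class", "eq", "e_q", "epsilon_q", "output"),
}


class TableFormatError(ValueError):
    """Malformed table content; the message cites the offending row."""


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_pairs_table(path: str | Path, delimiter: str | None = None) -> list[AssayRecord]:
    """Read and validate a pair-assay table into records.

    The header must contain every canonical column (order-insensitive,
    extras ignored).  Activity classes must be literal 0/1; sequences must
    be valid peptides; condition categories must be non-empty.
    """
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=sep)
        if reader.fieldnames is None:
            raise TableFormatError(f"{path}: empty file, header expected")
        missing = [c for c in PAIR_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise TableFormatError(f"{path}: missing columns {missing}")
        records: list[AssayRecord] = []
        for row_no, row in enumerate(reader, start=1):
            try:
                records.append(
                    AssayRecord(
                        query_seq=validate_peptide(row["query_seq"]),
                        ref_seq=validate_peptide(row["ref_seq"]),
                        ref_activity=_parse_class(row["ref_activity"]),
                        query_activity=_parse_class(row["query_activity"]),
                        conditions={f: row[f] for f in FACTORS},
                    )
                )
            except (ValueError, InvalidSequenceError) as exc:
                raise TableFormatError(f"{path}: row {row_no}: {exc}") from exc
    return records


def _parse_class(value: str) -> int:
    value = value.strip()
    if value not in ("0", "1"):
        raise ValueError(f"activity class must be 0 or 1, got {value!r}")
    return int(value)


def write_pairs_table(
    records: Sequence[AssayRecord], path: str | Path, delimiter: str | None = None
) -> Path:
    """Write records as a canonical pair table; row order preserved."""
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=sep)
        writer.writerow(PAIR_COLUMNS)
        for r in records:
            writer.writerow(
                [r.query_seq, r.ref_seq, r.ref_activity, r.query_activity]
                + [r.conditions[f] for f in FACTORS]
            )
    return path


def _canonical_name(raw: str) -> str | None:
    key = raw.strip().lower()
    for canonical, aliases in FEATURE_ALIASES.items():
        if key == canonical or key in aliases:
            return canonical
    return None


def read_feature_table(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Read a 10-feature + label table, normalizing column names and order.

    Column names are matched case-insensitively against the alias map; the
    result carries the canonical columns in canonical order.  Non-finite
    values are rejected with the row and column named.
    """
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    raw = pd.read_csv(path, sep=sep)
    rename: dict[str, str] = {}
    for col in raw.columns:
        canonical = _canonical_name(str(col))
        if canonical is not None:
            rename[col] = canonical
    table = raw.rename(columns=rename)
    wanted = list(FEATURE_COLUMNS) + [LABEL_COLUMN]
    missing = [c for c in wanted if c not in table.columns]
    if missing:
        raise TableFormatError(
            f"{path}: missing feature columns {missing} "
            f"(found {list(raw.columns)})"
        )
    table = table[wanted]
    values = table[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    bad = np.argwhere(~np.isfinite(values))
    if bad.size:
        r, c = bad[0]
        raise TableFormatError(
            f"{path}: non-finite value at row {r + 1}, column "
            f"{FEATURE_COLUMNS[c]!r}"
        )
    for col, kind in ((LABEL_COLUMN, "label"), ("e_ref", "reference class")):
        col_vals = table[col].to_numpy()
        if not np.isin(col_vals, (0, 1)).all():
            bad_row = int(np.flatnonzero(~np.isin(col_vals, (0, 1)))[0])
            raise TableFormatError(
                f"{path}: {kind} must be 0 or 1 at row {bad_row + 1}"
            )
    return table.astype({"e_ref": int, LABEL_COLUMN: int})


def write_feature_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write the feature table with floats at six decimals."""
    path = Path(path)
    cols = list(FEATURE_COLUMNS) + [LABEL_COLUMN]
    out = table[cols]
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(cols)
        for row in out.itertuples(index=False):
            writer.writerow(
                [int(row[0])]
                + [f"{v:.6f}" for v in row[1:-1]]
                + [int(row[-1])]
            )
    return path


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read (id, sequence) pairs from a FASTA file; sequences validated."""
    entries = []
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        try:
            validate_peptide(seq)
        except InvalidSequenceError as exc:
            raise TableFormatError(f"{path}: record {record.id!r}: {exc}") from exc
        entries.append((record.id, seq))
    return entries


def write_descriptor_table(
    theta: Mapping[str, Iterable[float]], path: str | Path, k_max: int = 5
) -> Path:
    """Write per-sequence entropy descriptors as CSV (six decimals)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sequence"] + [f"theta{k}" for k in range(k_max + 1)])
        for seq, values in theta.items():
            writer.writerow([seq] + [f"{v:.6f}" for v in values])
    return path


def write_json(payload: dict, path: str | Path) -> Path:
    """Write a JSON sidecar (configs, generative truth, run logs)."""
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return path
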