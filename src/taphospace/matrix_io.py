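"""Reading and writing character matrices.

Two carriers are supported: NEXUS (a DATA or CHARACTERS block with
DATATYPE=STANDARD, SYMBOLS "0 1", MISSING=?) and delimited tables with fixed
leading metadata columns.  Standard NEXUS has no slot for stage metadata, so
the canonical carrier for unit records is a sidecar delimited table keyed by
unit_id; an embedded bracketed UNITMETA comment block is also written and
accepted on read, which makes the NEXUS round-trip self-contained.
"""

from __future__ import annotations

import io
import re
import warnings
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .matrix import (
    CharacterMatrix,
    UnitRecord,
    symbols_from_states,
    validate,
)

__all__ = [
    "NexusParseError",
    "read_nexus",
    "write_nexus",
    "read_table",
    "write_table",
    "read_metadata_table",
    "write_metadata_table",
]

METADATA_COLUMNS = ["unit_id", "taxon", "unit_class", "ontogenetic_rank", "decay_stage", "label"]

_STATE_CHARS = set("01?-")


class NexusParseError(ValueError):
    """Raised for malformed NEXUS input; message names the offending line."""


def _parse_int_or_none(value) -> Optional[int]:
    if value is None:
        return None
    if isinstance(value, float) and np.isnan(value):
        return None
    s = str(value).strip()
    if s == "" or s.lower() in ("na", "nan", "none"):
        return None
    return int(float(s))


def _record_from_mapping(m: dict) -> UnitRecord:
    return UnitRecord(
        unit_id=str(m["unit_id"]),
        taxon=str(m.get("taxon") or ""),
        unit_class=str(m.get("unit_class") or "fossil_specimen"),
        ontogenetic_rank=_parse_int_or_none(m.get("ontogenetic_rank")),
        decay_stage=_parse_int_or_none(m.get("decay_stage")),
        label="" if pd.isna(m.get("label")) else str(m.get("label") or ""),
    )


def read_metadata_table(path) -> dict[str, UnitRecord]:
    """Read a sidecar metadata table (CSV or TSV by extension) keyed by unit_id."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    if "unit_id" not in df.columns:
        raise ValueError(f"metadata table {path} lacks a unit_id column")
    return {str(r["unit_id"]): _record_from_mapping(r) for r in df.to_dict("records")}


def write_metadata_table(matrix: CharacterMatrix, path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    _metadata_frame(matrix).to_csv(path, sep=sep, index=False)


def _metadata_frame(matrix: CharacterMatrix) -> pd.DataFrame:
    rows = []
    for u in matrix.units:
        rows.append(
            {
                "unit_id": u.unit_id,
                "taxon": u.taxon,
                "unit_class": u.unit_class,
                "ontogenetic_rank": "" if u.ontogenetic_rank is None else u.ontogenetic_rank,
                "decay_stage": "" if u.decay_stage is None else u.decay_stage,
                "label": u.label,
            }
        )
    return pd.DataFrame(rows, columns=METADATA_COLUMNS)


# ---------------------------------------------------------------------------
# NEXUS
# ---------------------------------------------------------------------------

_UNITMETA_RE = re.compile(r"\[UNITMETA\n(.*?)\n\]", re.DOTALL)


def _strip_comments(text: str) -> str:
    """Remove bracketed NEXUS comments, preserving line structure."""
    out = []
    depth = 0
    for ch in text:
        if ch == "[":
            depth += 1
        elif ch == "]":
            depth = max(0, depth - 1)
        elif depth == 0 or ch == "\n":
            out.append(ch)
    return "".join(out)


def _tokenize_label(line: str, lineno: int) -> tuple[str, str]:
    """Split a MATRIX row into (label, state string); label may be quoted."""
    line = line.strip()
    if line.startswith("'"):
        end = line.find("'", 1)
        while end != -1 and end + 1 < len(line) and line[end + 1] == "'":
            end = line.find("'", end + 2)
        if end == -1:
            raise NexusParseError(f"line {lineno}: unterminated quoted label")
        label = line[1:end].replace("''", "'")
        rest = line[end + 1 :]
    else:
        parts = line.split(None, 1)
        if len(parts) < 2:
            raise NexusParseError(f"line {lineno}: matrix row lacks states: {line!r}")
        label, rest = parts
    return label, rest.strip()


def read_nexus(path, metadata: Optional[dict[str, UnitRecord] | str | Path] = None) -> CharacterMatrix:
    """Read a STANDARD-datatype NEXUS character matrix.

    Unit metadata is taken, in order of precedence, from the ``metadata``
    argument (a sidecar table path or a prebuilt unit_id -> UnitRecord
    mapping), else from an embedded ``[UNITMETA ...]`` comment block, else
    defaulted: units become fossil_specimen with both stage fields unset.

    Gap symbols ('-') are read as unknown with a warning; polymorphic states
    such as ``{01}`` are rejected.
    """
    raw = Path(path).read_text()
    if not raw.lstrip().upper().startswith("#NEXUS"):
        raise NexusParseError("line 1: file does not start with #NEXUS")

    meta_map: Optional[dict[str, UnitRecord]] = None
    if metadata is not None:
        meta_map = metadata if isinstance(metadata, dict) else read_metadata_table(metadata)
    else:
        m = _UNITMETA_RE.search(raw)
        if m:
            df = pd.read_csv(io.StringIO(m.group(1)), dtype=str)
            meta_map = {str(r["unit_id"]): _record_from_mapping(r) for r in df.to_dict("records")}

    text = _strip_comments(raw)
    lines = text.split("\n")

    in_block = False
    in_matrix = False
    nchar = None
    labels: list[str] = []
    rows: list[list[float]] = []
    gap_seen = False

    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        upper = stripped.upper()
        if not in_block:
            if upper.startswith("BEGIN DATA") or upper.startswith("BEGIN CHARACTERS"):
                in_block = True
            continue
        if in_matrix:
            if stripped == ";" or upper.startswith("END"):
                in_matrix = False
                if upper.startswith("END"):
                    in_block = False
                continue
            if not stripped:
                continue
            body = stripped[:-1].rstrip() if stripped.endswith(";") else stripped
            if body:
                if nchar == 0:
                    label, statestr = body, ""
                else:
                    label, statestr = _tokenize_label(body, lineno)
                statestr = statestr.replace(" ", "").replace("\t", "")
                if "{" in statestr or "(" in statestr:
                    raise NexusParseError(
                        f"line {lineno}: polymorphic states are not supported (matrix is binary)"
                    )
                bad = set(statestr) - _STATE_CHARS
                if bad:
                    raise NexusParseError(
                        f"line {lineno}: unsupported state symbol(s) {sorted(bad)}; "
                        "allowed symbols are 0, 1, ?, -"
                    )
                if "-" in statestr:
                    gap_seen = True
                    statestr = statestr.replace("-", "?")
                if nchar is not None and len(statestr) != nchar:
                    raise NexusParseError(
                        f"line {lineno}: row {label!r} has {len(statestr)} states, expected {nchar}"
                    )
                labels.append(label)
                rows.append([{"0": 0.0, "1": 1.0}.get(c, np.nan) for c in statestr])
            if stripped.endswith(";"):
                in_matrix = False
            continue
        if upper.startswith("DIMENSIONS"):
            m = re.search(r"NCHAR\s*=\s*(\d+)", upper)
            if m:
                nchar = int(m.group(1))
        elif upper.startswith("FORMAT"):
            dt = re.search(r"DATATYPE\s*=\s*(\w+)", upper)
            if dt and dt.group(1) != "STANDARD":
                raise NexusParseError(f"line {lineno}: unsupported DATATYPE={dt.group(1)}")
        elif upper.startswith("MATRIX"):
            in_matrix = True
        elif upper.startswith("END"):
            in_block = False

    if nchar is None and not rows:
        raise NexusParseError("no DATA or CHARACTERS block with a MATRIX found")
    if gap_seen:
        warnings.warn("gap symbol '-' encountered; treated as unknown ('?')", stacklevel=2)

    dupes = {x for x in labels if labels.count(x) > 1}
    if dupes:
        raise NexusParseError(f"duplicate taxon labels: {sorted(dupes)}")

    n = nchar if nchar is not None else (len(rows[0]) if rows else 0)
    characters = [f"c{i + 1}" for i in range(n)]
    units = []
    for lab in labels:
        if meta_map and lab in meta_map:
            units.append(meta_map[lab].copy())
        else:
            units.append(UnitRecord(unit_id=lab, label=lab))
    states = np.asarray(rows, dtype=float).reshape(len(labels), n)
    return CharacterMatrix(characters=characters, units=units, states=states)


def _quote_label(label: str) -> str:
    if re.fullmatch(r"[\w.\-]+", label):
        return label
    return "'" + label.replace("'", "''") + "'"


def write_nexus(matrix: CharacterMatrix, path, embed_metadata: bool = True) -> None:
    """Write a STANDARD-datatype NEXUS file (MISSING=?, GAP=-).

    With ``embed_metadata`` the unit records travel in a bracketed UNITMETA
    comment, so ``read_nexus(write_nexus(m))`` is the identity on states,
    orders and metadata.
    """
    report = validate(matrix)
    if not report.is_valid:
        raise ValueError(f"refusing to write invalid matrix: {report.errors}")
    buf = ["#NEXUS"]
    if embed_metadata and matrix.units:
        csv_text = _metadata_frame(matrix).to_csv(index=False).strip("\n")
        buf.append("[UNITMETA\n" + csv_text + "\n]")
    buf.append("BEGIN DATA;")
    buf.append(f"    DIMENSIONS NTAX={matrix.n_units} NCHAR={matrix.n_characters};")
    buf.append('    FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=? GAP=-;')
    buf.append("    MATRIX")
    width = max((len(_quote_label(u.unit_id)) for u in matrix.units), default=0) + 2
    for u, row in zip(matrix.units, matrix.states):
        buf.append("    " + _quote_label(u.unit_id).ljust(width) + "".join(symbols_from_states(row)))
    buf.append("    ;")
    buf.append("END;")
    Path(path).write_text("\n".join(buf) + "\n")


# ---------------------------------------------------------------------------
# Delimited tables
# ---------------------------------------------------------------------------


def read_table(path, dialect: str = "csv") -> CharacterMatrix:
    """Read a character matrix from a delimited table.

    Expected layout: the metadata columns (unit_id, taxon, unit_class,
    ontogenetic_rank, decay_stage, optionally label) followed by one column
    per character.  Blank or NA cells in character columns map to unknown.
    """
    sep = {"csv": ",", "tsv": "\t"}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'csv' or 'tsv'")
    df = pd.read_csv(path, sep=sep, dtype=str)
    mandatory = ["unit_id", "taxon", "unit_class", "ontogenetic_rank", "decay_stage"]
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise ValueError(f"table {path} lacks mandatory metadata columns: {missing}")
    meta_cols = [c for c in METADATA_COLUMNS if c in df.columns]
    char_cols = [c for c in df.columns if c not in meta_cols]
    units = [_record_from_mapping(r) for r in df[meta_cols].to_dict("records")]
    states = np.full((len(df), len(char_cols)), np.nan)
    for j, col in enumerate(char_cols):
        for i, v in enumerate(df[col]):
            if v is None or (isinstance(v, float) and np.isnan(v)):
                continue
            s = str(v).strip()
            if s in ("", "?", "NA", "nan"):
                continue
            if s not in ("0", "1"):
                raise ValueError(f"invalid state {s!r} for unit {units[i].unit_id}, character {col}")
            states[i, j] = float(s)
    return CharacterMatrix(characters=char_cols, units=units, states=states)


def write_table(matrix: CharacterMatrix, path, dialect: str = "csv") -> None:
    sep = {"csv": ",", "tsv": "\t"}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'csv' or 'tsv'")
    df = _metadata_frame(matrix)
    for j, c in enumerate(matrix.characters):
        df[c] = symbols_from_states(matrix.states[:, j])
    df.to_csv(path, sep=sep, index=False)
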