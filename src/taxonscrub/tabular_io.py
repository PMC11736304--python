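"""Reading and writing the three workflow tables (CSV and XLSX dialects).

Three tables move through the pipeline: the original occurrence table, the
suggestion spreadsheet a reviewer edits, and the corrected output.  Row
numbers everywhere are 1-based over *retained data rows* (header excluded,
fully blank lines dropped) — i.e. what a reviewer sees in a spreadsheet
application minus the header row.  Unmapped columns are carried through the
pipeline untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .errors import EmptyInputError, InputError, OutputError, SchemaError, ValidationError

#: the eight logical rank slots, in fixed order
SLOTS: tuple[str, ...] = (
    "kingdom", "phylum", "class", "order", "family", "genus", "species", "scientificName",
)

#: placeholder marking a skipped slot in a column mapping
SKIP = "x"

SUGGESTION_HEADER = ["Rows", "Type", "Wrong Name", "Suggested Name",
                     "ID Source", "Source", "Change"]


@dataclass(frozen=True)
class ColumnMapping:
    """Binding of the eight logical slots to physical column names (or skip)."""

    slots: tuple[Optional[str], ...]

    def __post_init__(self) -> None:
        if len(self.slots) != len(SLOTS):
            raise SchemaError(f"column mapping needs exactly {len(SLOTS)} entries, "
                              f"got {len(self.slots)}")
        bound = [s for s in self.slots if s is not None]
        if not bound:
            raise SchemaError("column mapping skips every slot; nothing to verify")
        if len(set(bound)) != len(bound):
            raise SchemaError("column mapping binds the same physical column twice")

    @classmethod
    def from_columns(cls, names: Sequence[Optional[str]]) -> "ColumnMapping":
        padded = list(names) + [None] * (len(SLOTS) - len(names))
        return cls(slots=tuple(padded))

    @classmethod
    def identity(cls) -> "ColumnMapping":
        return cls(slots=SLOTS)

    def column_for(self, slot: str) -> Optional[str]:
        return self.slots[SLOTS.index(slot)]

    @property
    def mapped_slots(self) -> list[str]:
        return [s for s, c in zip(SLOTS, self.slots) if c is not None]


@dataclass
class OccurrenceTable:
    """An occurrence table plus its slot mapping and provenance.

    ``frame`` holds every original column as raw strings in input order;
    mapped slots are accessed through ``cell``/``column``.
    """

    frame: pd.DataFrame
    mapping: ColumnMapping
    source_path: Optional[Path] = None
    n_blank_skipped: int = 0

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    def cell(self, row: int, slot: str) -> str:
        """Cell at 1-based data row ``row`` for a logical slot."""
        col = self.mapping.column_for(slot)
        if col is None:
            raise KeyError(f"slot {slot!r} is not mapped")
        return self.frame.iloc[row - 1][col]

    def set_cell(self, row: int, slot: str, value: str) -> None:
        col = self.mapping.column_for(slot)
        if col is None:
            raise KeyError(f"slot {slot!r} is not mapped")
        self.frame.iloc[row - 1, self.frame.columns.get_loc(col)] = value

    def column(self, slot: str) -> pd.Series:
        col = self.mapping.column_for(slot)
        if col is None:
            raise KeyError(f"slot {slot!r} is not mapped")
        return self.frame[col]

    def copy(self) -> "OccurrenceTable":
        return OccurrenceTable(frame=self.frame.copy(), mapping=self.mapping,
                               source_path=self.source_path,
                               n_blank_skipped=self.n_blank_skipped)


@dataclass(frozen=True)
class SuggestionRow:
    """One reviewable correction: which rows, which slot, wrong vs suggested."""

    row_refs: tuple[int, ...]
    rank_type: str
    wrong_name: str
    suggested_name: str
    id_source: str
    source_id: int
    change: str = "no"
    similarity: Optional[float] = None

    @property
    def is_flag_only(self) -> bool:
        return self.suggested_name == ""


def _read_raw_frame(path: Path) -> tuple[pd.DataFrame, int]:
    """Read CSV/XLSX into an all-string frame; drop fully blank lines, counting them."""
    suffix = path.suffix.lower()
    if suffix == ".csv":
        try:
            df = pd.read_csv(path, dtype=str, keep_default_na=False,
                             skip_blank_lines=False, encoding="utf-8-sig")
        except UnicodeDecodeError:
            df = pd.read_csv(path, dtype=str, keep_default_na=False,
                             skip_blank_lines=False, encoding="latin-1")
        except pd.errors.EmptyDataError:
            raise EmptyInputError(f"{path} has no header row")
    elif suffix == ".xlsx":
        df = pd.read_excel(path, dtype=str, keep_default_na=False, engine="openpyxl")
    else:
        raise InputError(f"unsupported file extension {suffix!r} (need .csv or .xlsx)")
    df = df.fillna("").astype(str)
    blank = (df == "").all(axis=1)
    n_blank = int(blank.sum())
    df = df.loc[~blank].reset_index(drop=True)
    return df, n_blank


def read_occurrences(path: str | Path, mapping: ColumnMapping) -> OccurrenceTable:
    """Read an occurrence table, materializing the mapped slots.

    Fully blank lines are skipped and counted; retained-row numbering is not
    shifted by them.  Missing mapped columns raise before any processing.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"occurrence file not found: {path}")
    df, n_blank = _read_raw_frame(path)
    if df.empty:
        raise EmptyInputError(f"{path} contains no data rows")
    header = {c.strip().lower(): c for c in df.columns}
    resolved: list[Optional[str]] = []
    missing: list[str] = []
    for slot, col in zip(SLOTS, mapping.slots):
        if col is None:
            resolved.append(None)
        elif col in df.columns:
            resolved.append(col)
        elif col.strip().lower() in header:
            resolved.append(header[col.strip().lower()])
        else:
            missing.append(col)
            resolved.append(None)
    if missing:
        raise SchemaError(f"{path} is missing mapped column(s): {', '.join(missing)}")
    return OccurrenceTable(frame=df, mapping=ColumnMapping(slots=tuple(resolved)),
                           source_path=path, n_blank_skipped=n_blank)


def _suggestion_frame(rows: Iterable[SuggestionRow]) -> pd.DataFrame:
    ordered = sorted(rows, key=lambda r: (r.row_refs[0] if r.row_refs else 0,
                                          SLOTS.index(r.rank_type)))
    with_sim = any(r.similarity is not None for r in ordered)
    header = SUGGESTION_HEADER + (["Similarity"] if with_sim else [])
    data = []
    for r in ordered:
        rec = [", ".join(str(n) for n in r.row_refs), r.rank_type, r.wrong_name,
               r.suggested_name, r.id_source, str(r.source_id), r.change]
        if with_sim:
            rec.append("" if r.similarity is None else f"{r.similarity:.4f}")
        data.append(rec)
    return pd.DataFrame(data, columns=header)


def write_suggestions(rows: Iterable[SuggestionRow], path: str | Path) -> Path:
    """Write the suggestion spreadsheet (deterministic row order)."""
    path = Path(path)
    df = _suggestion_frame(rows)
    try:
        if path.suffix.lower() == ".csv":
            df.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")
        else:
            df.to_excel(path, index=False, engine="openpyxl")
    except OSError as exc:
        raise OutputError(f"cannot write suggestion file {path}: {exc}") from exc
    return path


def read_suggestions(path: str | Path) -> list[SuggestionRow]:
    """Read back a (possibly hand-edited) suggestion spreadsheet.

    The Change column accepts only yes/no, case-insensitively; anything else
    is a validation error listing the offending rows.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"suggestion file not found: {path}")
    df, _ = _read_raw_frame(path)
    missing = [c for c in SUGGESTION_HEADER if c not in df.columns]
    if missing:
        raise SchemaError(f"{path} is missing suggestion column(s): {', '.join(missing)}")
    rows: list[SuggestionRow] = []
    problems: list[str] = []
    for i, rec in enumerate(df.to_dict("records"), start=1):
        change = rec["Change"].strip().lower()
        if change not in ("yes", "no"):
            problems.append(f"row {i}: Change={rec['Change']!r} (expected yes/no)")
            continue
        try:
            refs = tuple(int(tok) for tok in rec["Rows"].split(",") if tok.strip())
        except ValueError:
            problems.append(f"row {i}: Rows={rec['Rows']!r} is not a comma-joined "
                            "list of integers")
            continue
        if rec["Type"] not in SLOTS:
            problems.append(f"row {i}: Type={rec['Type']!r} is not a known rank slot")
            continue
        sim_raw = rec.get("Similarity", "")
        rows.append(SuggestionRow(
            row_refs=refs, rank_type=rec["Type"], wrong_name=rec["Wrong Name"],
            suggested_name=rec["Suggested Name"], id_source=rec["ID Source"],
            source_id=int(rec["Source"]) if rec["Source"].strip() else 0,
            change=change,
            similarity=float(sim_raw) if sim_raw.strip() else None,
        ))
    if problems:
        raise ValidationError(f"{path} has invalid suggestion rows", details=problems)
    return rows


def write_table(table: OccurrenceTable, path: str | Path) -> Path:
    """Write the table with all original columns, preserving column and row order."""
    path = Path(path)
    try:
        if path.suffix.lower() == ".csv":
            table.frame.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")
        else:
            table.frame.to_excel(path, index=False, engine="openpyxl")
    except OSError as exc:
        raise OutputError(f"cannot write table {path}: {exc}") from exc
    return path
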