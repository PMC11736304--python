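"""Pipeline orchestration: build suggestions, apply reviewed corrections,
and summarize a run.

The pipeline has two passes.  The *check* pass verifies every distinct name
in every mapped rank column once (a name occurring in 400 rows is verified
once, and the suggestion row lists all 400 rows), writing a suggestion table
a reviewer can accept or reject per row.  The *fix* pass applies the
accepted suggestions back onto the original table, touching only the cells
named by accepted rows.

Species-column convention: a two-token cell is taken as a full binomial; a
one-token cell is treated as a bare epithet and joined with the same row's
genus cell to form the query.  A one-token cell with no usable genus cannot
be verified and becomes a flag-only suggestion row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .checklist import Checklist
from .errors import ConfigError, ConflictError, ValidationError
from .matching import Config, verify_taxon
from .nameparse import parse_scientific_name
from .tabular_io import SLOTS, OccurrenceTable, SuggestionRow


@dataclass
class NameOccurrenceIndex:
    """Per slot: raw cell string → (sorted row numbers, frequency)."""

    by_slot: dict[str, dict[str, list[int]]] = field(default_factory=dict)

    def frequency(self, slot: str, name: str) -> int:
        return len(self.by_slot.get(slot, {}).get(name, []))


@dataclass
class RunSummary:
    """The figures shown in the summary panels of a run."""

    total_occurrences: int = 0
    total_taxon_names: int = 0
    errors_by_rank: dict[str, int] = field(default_factory=dict)
    top3_ranks: list[tuple[str, int]] = field(default_factory=list)

    def format_lines(self) -> list[str]:
        lines = [
            f"Total Occurrences: {self.total_occurrences}",
            f"Total Taxon Names: {self.total_taxon_names}",
        ]
        if self.top3_ranks:
            tops = ", ".join(f"{slot} ({n})" for slot, n in self.top3_ranks)
            lines.append(f"Top 3 Taxonomic Ranks with Errors: {tops}")
        else:
            lines.append("Top 3 Taxonomic Ranks with Errors: none")
        return lines


def collect_names(table: OccurrenceTable) -> NameOccurrenceIndex:
    """Index every distinct non-empty raw cell per mapped slot.

    Deduplication is on the raw string — "Animalia" and "animalia" are two
    entries — preserving the reviewer's view of exactly what the data says;
    case handling happens inside matching.
    """
    idx = NameOccurrenceIndex()
    for slot in table.mapping.mapped_slots:
        names: dict[str, list[int]] = {}
        for row, value in enumerate(table.column(slot), start=1):
            if value.strip() == "":
                continue
            names.setdefault(value, []).append(row)
        idx.by_slot[slot] = names
    return idx


def _slot_rank(slot: str) -> str:
    return "species" if slot in ("species", "scientificName") else slot


def _species_queries(table: OccurrenceTable, names: dict[str, list[int]],
                     ) -> list[tuple[str, Optional[str], list[int]]]:
    """Expand species-slot entries to (raw cell, query string or None, rows).

    One-token cells are joined with the row's genus; rows of the same raw
    cell that pair with different genera become separate query groups.
    """
    genus_mapped = table.mapping.column_for("genus") is not None
    out: list[tuple[str, Optional[str], list[int]]] = []
    for raw, rows in names.items():
        parsed = parse_scientific_name(raw)
        if len(parsed.canonical.split()) >= 2 or not parsed.is_parseable:
            out.append((raw, raw if parsed.is_parseable else None, rows))
            continue
        # bare epithet: group rows by the genus cell they join with
        groups: dict[str, list[int]] = {}
        for row in rows:
            genus = table.cell(row, "genus").strip() if genus_mapped else ""
            groups.setdefault(genus, []).append(row)
        for genus, grows in groups.items():
            query = f"{genus} {raw.strip()}" if genus else None
            out.append((raw, query, grows))
    return out


def build_suggestions(table: OccurrenceTable, checklist: Checklist,
                      config: Config) -> tuple[list[SuggestionRow], RunSummary]:
    """Verify every unique name and produce the reviewable suggestion rows.

    Exact matches produce nothing.  Fuzzy matches produce one row carrying
    the best candidate; names with no match at all produce a flag-only row
    (empty suggestion) so the reviewer still sees them.
    """
    if len(checklist) == 0:
        raise ConfigError("cannot build suggestions against an empty checklist")
    idx = collect_names(table)
    suggestions: list[SuggestionRow] = []
    for slot in table.mapping.mapped_slots:
        names = idx.by_slot[slot]
        rank = _slot_rank(slot)
        if slot == "species":
            queries = _species_queries(table, names)
        else:
            queries = [(raw, raw, rows) for raw, rows in names.items()]
        for raw, query, rows in queries:
            if query is None:
                suggestions.append(SuggestionRow(
                    row_refs=tuple(rows), rank_type=slot, wrong_name=raw,
                    suggested_name="", id_source="", source_id=checklist.source_id))
                continue
            result = verify_taxon(query, rank, checklist, config)
            if result.match_type == "Exact":
                continue
            if result.match_type == "Fuzzy":
                best = result.best
                suggested = best.record.canonical_name
                if slot == "species" and query != raw:
                    # joined-epithet query: write back only the epithet
                    suggested = suggested.split()[-1]
                suggestions.append(SuggestionRow(
                    row_refs=tuple(rows), rank_type=slot, wrong_name=raw,
                    suggested_name=suggested, id_source=best.record.taxon_id,
                    source_id=best.record.source_id,
                    similarity=best.similarity if config.with_stats else None))
            else:
                suggestions.append(SuggestionRow(
                    row_refs=tuple(rows), rank_type=slot, wrong_name=raw,
                    suggested_name="", id_source="", source_id=checklist.source_id))
    summary = summarize(table, suggestions, index=idx)
    return suggestions, summary


def summarize(table: OccurrenceTable, suggestions: list[SuggestionRow],
              index: Optional[NameOccurrenceIndex] = None) -> RunSummary:
    """Compute the panel figures: row count, unique names, errors per rank."""
    idx = index if index is not None else collect_names(table)
    total_names = sum(len(names) for names in idx.by_slot.values())
    errors: dict[str, int] = {slot: 0 for slot in table.mapping.mapped_slots}
    for s in suggestions:
        errors[s.rank_type] = errors.get(s.rank_type, 0) + 1
    ranked = sorted(((slot, n) for slot, n in errors.items() if n > 0),
                    key=lambda kv: (-kv[1], SLOTS.index(kv[0])))
    return RunSummary(total_occurrences=table.n_rows,
                      total_taxon_names=total_names,
                      errors_by_rank=errors,
                      top3_ranks=ranked[:3])


def apply_corrections(table: OccurrenceTable,
                      suggestions: list[SuggestionRow]) -> OccurrenceTable:
    """Apply accepted suggestions, returning a corrected copy of the table.

    Only rows with change=yes and a non-empty suggested name act; each
    replaces the slot cell (which must still equal the wrong name) in every
    referenced row.  All validation happens before any cell is mutated.
    """
    accepted = [s for s in suggestions if s.change == "yes" and not s.is_flag_only]
    problems: list[str] = []
    conflicts: list[str] = []
    for s in accepted:
        if table.mapping.column_for(s.rank_type) is None:
            problems.append(f"slot {s.rank_type!r} is not mapped in the table")
            continue
        for row in s.row_refs:
            if not 1 <= row <= table.n_rows:
                problems.append(f"row {row} out of range 1..{table.n_rows} "
                                f"({s.rank_type} {s.wrong_name!r})")
                continue
            cell = table.cell(row, s.rank_type)
            if cell != s.wrong_name:
                conflicts.append(f"row {row}, {s.rank_type}: expected "
                                 f"{s.wrong_name!r}, found {cell!r}")
    if problems:
        raise ValidationError("suggestion rows reference rows outside the table",
                              details=problems)
    if conflicts:
        raise ConflictError("cells no longer hold the expected wrong names",
                            details=conflicts)
    corrected = table.copy()
    for s in accepted:
        for row in s.row_refs:
            corrected.set_cell(row, s.rank_type, s.suggested_name)
    return corrected
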