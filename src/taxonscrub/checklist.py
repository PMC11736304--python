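"""Reference checklists: the local taxonomy that names are verified against.

A checklist is a flat table of accepted names with ranks and (optionally)
higher classification.  It stands in for a remote taxonomic backbone; the
integer source code records which backbone a checklist represents, using the
conventional codes 1 (Catalog of Life), 4 (NCBI), 11 (GBIF) and
180 (iNaturalist).

Two column layouts are accepted:

* flat: ``taxon_id, scientific_name, rank`` plus optional ancestor columns
  ``kingdom … species``;
* Darwin Core Taxon terms: ``taxonID, scientificName, taxonRank``.

Canonical names are computed on load by stripping authorship, and an exact
index keyed by ``(rank, case-folded canonical)`` supports O(1) exact lookup.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import EmptyChecklistError, InputError, SchemaError
from .nameparse import normalize, parse_scientific_name

#: closed rank vocabulary, highest to lowest
RANKS: tuple[str, ...] = (
    "kingdom", "phylum", "class", "order", "family", "genus", "species", "subspecies",
)

#: source code → human-readable backbone name
SOURCES: dict[int, str] = {
    1: "Catalog of Life",
    4: "NCBI",
    11: "GBIF",
    180: "iNaturalist",
}

_DWC_ALIASES = {"taxonid": "taxon_id", "scientificname": "scientific_name",
                "taxonrank": "rank"}
_ANCESTOR_COLS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")


@dataclass(frozen=True)
class SourceCode:
    value: int

    def __post_init__(self) -> None:
        if self.value not in SOURCES:
            raise ValueError(
                f"unknown source id {self.value}; valid codes: "
                + ", ".join(f"{k} ({v})" for k, v in SOURCES.items())
            )

    @property
    def label(self) -> str:
        return SOURCES[self.value]


@dataclass(frozen=True)
class TaxonRecord:
    """One checklist entry."""

    taxon_id: str
    source_id: int
    scientific_name: str
    canonical_name: str
    rank: str
    classification: Mapping[str, str] = field(default_factory=dict)


@dataclass
class LoadReport:
    n_loaded: int = 0
    n_skipped_unknown_rank: int = 0
    skipped_ranks: list[str] = field(default_factory=list)


@dataclass
class Checklist:
    """An indexed collection of :class:`TaxonRecord`."""

    records: list[TaxonRecord]
    source_id: int
    exact_index: dict[tuple[str, str], list[TaxonRecord]] = field(default_factory=dict)
    by_rank: dict[str, list[TaxonRecord]] = field(default_factory=dict)
    load_report: LoadReport = field(default_factory=LoadReport)

    def __post_init__(self) -> None:
        seen: set[tuple[int, str]] = set()
        for r in self.records:
            key = (r.source_id, r.taxon_id)
            if key in seen:
                raise SchemaError(f"duplicate (source_id, taxon_id) pair {key}")
            seen.add(key)
        self._reindex()

    def _reindex(self) -> None:
        self.exact_index = {}
        self.by_rank = {r: [] for r in RANKS}
        for rec in self.records:
            self.exact_index.setdefault((rec.rank, normalize(rec.canonical_name)), []).append(rec)
            self.by_rank[rec.rank].append(rec)

    def __len__(self) -> int:
        return len(self.records)


def load_checklist(path: str | Path, source_id: int) -> Checklist:
    """Load a checklist CSV, computing canonical names for every record.

    Rows whose rank is outside the closed vocabulary are skipped and counted
    in ``load_report`` rather than erroring, so real-world exports load.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"checklist file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8-sig")
    df.columns = [_DWC_ALIASES.get(c.strip().lower(), c.strip().lower()) for c in df.columns]
    for col in ("taxon_id", "scientific_name", "rank"):
        if col not in df.columns:
            raise SchemaError(f"checklist {path} is missing mandatory column '{col}'")

    report = LoadReport()
    records: list[TaxonRecord] = []
    ancestors_present = [c for c in _ANCESTOR_COLS if c in df.columns]
    for row in df.itertuples(index=False):
        d = dict(zip(df.columns, row))
        rank = d["rank"].strip().lower()
        if rank not in RANKS:
            report.n_skipped_unknown_rank += 1
            if rank not in report.skipped_ranks:
                report.skipped_ranks.append(rank)
            continue
        parsed = parse_scientific_name(d["scientific_name"])
        if not parsed.canonical:
            report.n_skipped_unknown_rank += 1
            continue
        classification = {c: d[c].strip() for c in ancestors_present if d[c].strip()}
        records.append(TaxonRecord(
            taxon_id=d["taxon_id"].strip(),
            source_id=source_id,
            scientific_name=d["scientific_name"].strip(),
            canonical_name=parsed.canonical,
            rank=rank,
            classification=classification,
        ))
    report.n_loaded = len(records)
    if not records:
        raise EmptyChecklistError(f"checklist {path} contains no usable records")
    cl = Checklist(records=records, source_id=source_id)
    cl.load_report = report
    return cl


def lookup_exact(checklist: Checklist, name: str, rank: str,
                 fold_case: bool = True) -> Sequence[TaxonRecord]:
    """All records whose canonical name equals ``name`` at ``rank``.

    With ``fold_case`` the comparison is case-insensitive (and whitespace
    tolerant); without it, only byte-identical canonicals match.  An empty
    result is a valid outcome, never an error.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    hits = checklist.exact_index.get((rank, normalize(name)), [])
    if fold_case:
        return list(hits)
    query = " ".join(name.split())
    return [r for r in hits if r.canonical_name == query]
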