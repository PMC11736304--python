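"""The verification engine: exact-then-fuzzy matching against a checklist.

A query name is first looked up exactly (after authorship stripping and,
by default, case folding).  Only when the exact lookup fails is fuzzy
matching attempted, using the optimal string alignment (OSA) distance —
unit-cost substitutions, insertions, deletions and adjacent transpositions,
the four classic typo operations.  A candidate is kept when its distance is
within ``max_edit_distance`` AND its similarity

    sim(a, b) = 1 - d(a, b) / max(|a|, |b|)

clears ``main_taxon_threshold``.  Candidates are returned in a fully
deterministic order so two runs over the same inputs produce identical
suggestion files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

from .checklist import RANKS, Checklist, TaxonRecord, lookup_exact
from .errors import ConfigError
from .nameparse import ParsedName, normalize, parse_scientific_name

#: sentinel returned by :func:`edit_distance` when the distance exceeds the cap
OVER_CAP: int = -1

_CONFIG_KEYS = {
    "withAllMatches": "with_all_matches",
    "withCapitalization": "with_capitalization",
    "withSpeciesGroup": "with_species_group",
    "withUninomialFuzzyMatch": "with_uninomial_fuzzy_match",
    "mainTaxonThreshold": "main_taxon_threshold",
    "withStats": "with_stats",
    "maxEditDistance": "max_edit_distance",
}


@dataclass(frozen=True)
class Config:
    """Matching configuration (the six classic keys plus the distance cap).

    ``with_all_matches`` off limits output to the single best candidate;
    ``with_capitalization`` makes comparison case-insensitive;
    ``with_species_group`` extends species queries to subspecies records;
    ``with_uninomial_fuzzy_match`` enables fuzzy matching for one-word names
    (genus and higher); ``main_taxon_threshold`` is the minimum similarity
    in [0, 1]; ``with_stats`` records per-query counters; and
    ``max_edit_distance`` bounds the OSA distance (default 2 — "minor
    errors").
    """

    with_all_matches: bool = False
    with_capitalization: bool = True
    with_species_group: bool = False
    with_uninomial_fuzzy_match: bool = True
    main_taxon_threshold: float = 0.75
    with_stats: bool = False
    max_edit_distance: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.main_taxon_threshold <= 1.0:
            raise ConfigError("mainTaxonThreshold must lie in [0, 1]")
        if self.max_edit_distance < 0:
            raise ConfigError("maxEditDistance must be non-negative")


def load_config(path: str | Path) -> Config:
    """Read a JSON config file with the camelCase keys; unknown keys are an error."""
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} must be a JSON object")
    unknown = sorted(set(raw) - set(_CONFIG_KEYS))
    if unknown:
        raise ConfigError(f"config {path} has unknown keys: {', '.join(unknown)}")
    return Config(**{_CONFIG_KEYS[k]: v for k, v in raw.items()})


@dataclass(frozen=True)
class Candidate:
    record: TaxonRecord
    edit_distance: int
    similarity: float


@dataclass
class MatchStats:
    comparisons: int = 0
    candidates_kept: int = 0


@dataclass
class MatchResult:
    query: ParsedName
    rank: str
    match_type: str  # Exact | Fuzzy | NoMatch
    best: Optional[Candidate] = None
    candidates: list[Candidate] = field(default_factory=list)
    stats: Optional[MatchStats] = None
    parse_failed: bool = False

    @property
    def stats_recorded(self) -> bool:
        return self.stats is not None


def edit_distance(a: str, b: str, cap: int) -> int:
    """Optimal string alignment distance between ``a`` and ``b``, or
    :data:`OVER_CAP` when it exceeds ``cap``.

    OSA counts unit-cost substitutions, insertions, deletions and adjacent
    transpositions, never editing the same substring twice.  The computation
    is banded: only the diagonal strip of width ``2*cap+1`` is filled, so a
    scan over a large checklist stays cheap.
    """
    if cap < 0:
        raise ValueError("cap must be non-negative")
    if a == b:
        return 0
    la, lb = len(a), len(b)
    if abs(la - lb) > cap:
        return OVER_CAP
    if la == 0 or lb == 0:
        d = max(la, lb)
        return d if d <= cap else OVER_CAP

    big = cap + 1
    # rows over a, columns over b; keep three rows for the transposition term
    prev2: list[int] = []
    prev = [min(j, big) for j in range(lb + 1)]
    prev_row_min = 0
    for i in range(1, la + 1):
        lo = max(1, i - cap)
        hi = min(lb, i + cap)
        cur = [big] * (lb + 1)
        cur[0] = i if i <= cap else big
        row_min = cur[lo - 1] if lo == 1 else big
        for j in range(lo, hi + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            d = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
            if i > 1 and j > 1 and a[i - 1] == b[j - 2] and a[i - 2] == b[j - 1]:
                d = min(d, prev2[j - 2] + 1)
            cur[j] = min(d, big)
            row_min = min(row_min, cur[j])
        # a transposition can reach row i+1 from row i-1, so abandon only
        # after two consecutive rows exceed the cap
        if row_min > cap and prev_row_min > cap:
            return OVER_CAP
        prev_row_min = row_min
        prev2, prev = prev, cur
    return prev[lb] if prev[lb] <= cap else OVER_CAP


def similarity(distance: int, a: str, b: str) -> float:
    """Length-normalized similarity ``1 - d / max(|a|, |b|)``; 1.0 iff d == 0."""
    m = max(len(a), len(b))
    return 1.0 if m == 0 else 1.0 - distance / m


def eligible_ranks(query: ParsedName, rank: str,
                   config: Config) -> tuple[frozenset[str], bool]:
    """Which checklist ranks to search and whether fuzzy matching is allowed.

    Uninomial queries search their own rank and get fuzzy matching only when
    ``with_uninomial_fuzzy_match`` is on.  Binomial/trinomial queries search
    species records — extended to subspecies under ``with_species_group`` —
    with fuzzy matching always permitted.
    """
    if query.structure == "uninomial":
        return frozenset({rank}), config.with_uninomial_fuzzy_match
    ranks = {"species", "subspecies"} if config.with_species_group else {"species"}
    return frozenset(ranks), True


def rank_candidates(cands: Sequence[Candidate]) -> list[Candidate]:
    """Deterministic candidate order: best similarity first, then smallest
    distance, then canonical name, then taxon id."""
    return sorted(cands, key=lambda c: (-c.similarity, c.edit_distance,
                                        c.record.canonical_name, c.record.taxon_id))


def _norm(name: str, config: Config) -> str:
    if config.with_capitalization:
        return normalize(name)
    return " ".join(name.split())


def fuzzy_match(query: ParsedName, rank: str, checklist: Checklist,
                config: Config, stats: Optional[MatchStats] = None) -> list[Candidate]:
    """Scan eligible records for near matches of ``query``.

    Returns candidates with OSA distance ≤ ``max_edit_distance`` and
    similarity ≥ ``main_taxon_threshold``, ordered by :func:`rank_candidates`;
    truncated to the single best entry unless ``with_all_matches`` is on.
    """
    if query.structure == "unparseable":
        raise ValueError("cannot fuzzy-match an unparseable name")
    ranks, fuzzy_ok = eligible_ranks(query, rank, config)
    if not fuzzy_ok:
        return []
    q = _norm(query.canonical, config)
    kept: list[Candidate] = []
    for r in sorted(ranks):
        for rec in checklist.by_rank.get(r, []):
            if stats is not None:
                stats.comparisons += 1
            target = _norm(rec.canonical_name, config)
            d = edit_distance(q, target, config.max_edit_distance)
            if d == OVER_CAP or d == 0:
                continue
            sim = similarity(d, q, target)
            if sim >= config.main_taxon_threshold:
                kept.append(Candidate(record=rec, edit_distance=d, similarity=sim))
    kept = rank_candidates(kept)
    if not config.with_all_matches:
        kept = kept[:1]
    if stats is not None:
        stats.candidates_kept = len(kept)
    return kept


def verify_taxon(query_string: str, rank: str, checklist: Checklist,
                 config: Config) -> MatchResult:
    """Verify one name at one rank: exact lookup first, fuzzy only on failure.

    Unparseable input yields a NoMatch result with ``parse_failed`` set —
    never an exception — so one bad cell cannot abort a batch run.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    parsed = parse_scientific_name(query_string)
    stats = MatchStats() if config.with_stats else None
    if not parsed.is_parseable:
        return MatchResult(query=parsed, rank=rank, match_type="NoMatch",
                           stats=stats, parse_failed=True)

    ranks, _ = eligible_ranks(parsed, rank, config)
    exact_hits: list[Candidate] = []
    for r in sorted(ranks):
        for rec in lookup_exact(checklist, parsed.canonical, r,
                                fold_case=config.with_capitalization):
            exact_hits.append(Candidate(record=rec, edit_distance=0, similarity=1.0))
    if exact_hits:
        ordered = rank_candidates(exact_hits)
        if not config.with_all_matches:
            ordered = ordered[:1]
        if stats is not None:
            stats.candidates_kept = len(ordered)
        return MatchResult(query=parsed, rank=rank, match_type="Exact",
                           best=ordered[0], candidates=ordered, stats=stats)

    cands = fuzzy_match(parsed, rank, checklist, config, stats=stats)
    if cands:
        return MatchResult(query=parsed, rank=rank, match_type="Fuzzy",
                           best=cands[0], candidates=cands, stats=stats)
    return MatchResult(query=parsed, rank=rank, match_type="NoMatch", stats=stats)
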