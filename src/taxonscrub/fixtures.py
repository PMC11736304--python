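"""Synthetic checklists, occurrence tables and seeded typo injection.

Every pipeline stage is testable offline: this module grows a small
hierarchical taxonomy of pronounceable made-up names (alternating
consonant/vowel syllables), samples occurrence rows from its lineages, and
corrupts a controlled fraction of cells with single-edit typos —
substitution, insertion, deletion or adjacent transposition — recording the
ground truth of every corruption.

Within-rank name separation is enforced by rejection sampling: with all
names at a rank at pairwise distance ≥ 2k+1, any ≤ k-edit corruption has a
provably unique nearest neighbour, so recovery can be asserted at 100%.

A packaged mini worked example (a vinegaroon collection dataset) is also
provided: a real whip-scorpion lineage (kingdom Animalia, order Uropygi,
genus Thelyphonelus) with the three classic hand-inserted misspellings
"Aanimalia", "Urophygi" and "Thelyphoneluss".
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .checklist import RANKS, Checklist, TaxonRecord, load_checklist
from .errors import GenerationError
from .matching import OVER_CAP, edit_distance
from .nameparse import normalize
from .tabular_io import SLOTS

_CONSONANTS = "bcdfglmnprstvz"
_VOWELS = "aeiou"

#: ranks that make up one lineage, root to tip
LINEAGE_RANKS: tuple[str, ...] = RANKS[:7]  # kingdom .. species

EDIT_OPS: tuple[str, ...] = ("substitute", "insert", "delete", "transpose")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset.

    ``names_per_rank`` defaults to a pyramid widening toward the tips with
    ``n_lineages`` species.  ``error_rate`` is the fraction of occurrence
    cells corrupted (``n_errors`` overrides it with an absolute count).
    """

    n_lineages: int = 8
    names_per_rank: Optional[dict[str, int]] = None
    min_pairwise_distance: int = 3
    n_rows: int = 20
    error_rate: float = 0.0
    n_errors: Optional[int] = None
    error_ops: tuple[str, ...] = EDIT_OPS
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must lie in [0, 1]")
        if self.min_pairwise_distance < 1:
            raise ValueError("min_pairwise_distance must be >= 1")
        unknown = set(self.error_ops) - set(EDIT_OPS)
        if unknown:
            raise ValueError(f"unknown edit operations: {sorted(unknown)}")

    def rank_counts(self) -> dict[str, int]:
        if self.names_per_rank is not None:
            counts = dict(self.names_per_rank)
            counts.setdefault("species", self.n_lineages)
            return counts
        n = self.n_lineages
        return {
            "kingdom": max(1, math.ceil(n / 8)),
            "phylum": max(1, math.ceil(n / 6)),
            "class": max(1, math.ceil(n / 5)),
            "order": max(1, math.ceil(n / 4)),
            "family": max(1, math.ceil(n / 3)),
            "genus": max(1, math.ceil(n / 2)),
            "species": n,
        }


@dataclass(frozen=True)
class TruthEntry:
    row: int
    slot: str
    original: str
    corrupted: str
    operation: str


@dataclass
class TruthTable:
    entries: list[TruthEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([e.__dict__ for e in self.entries],
                            columns=["row", "slot", "original", "corrupted", "operation"])


def _make_word(rng: random.Random, n_syllables: int, capitalize: bool) -> str:
    word = "".join(rng.choice(_CONSONANTS) + rng.choice(_VOWELS)
                   for _ in range(n_syllables))
    return word.capitalize() if capitalize else word


def _sample_separated(rng: random.Random, count: int, min_dist: int,
                      capitalize: bool, taken: set[str],
                      syllables: tuple[int, int] = (3, 5),
                      max_tries: int = 20000) -> list[str]:
    """Rejection-sample ``count`` words pairwise ≥ ``min_dist`` apart."""
    words: list[str] = []
    tries = 0
    while len(words) < count:
        tries += 1
        if tries > max_tries:
            raise GenerationError(
                f"cannot place {count} names at pairwise distance >= {min_dist}; "
                "request fewer names or a smaller separation")
        w = _make_word(rng, rng.randint(*syllables), capitalize)
        if normalize(w) in taken:
            continue
        if min_dist > 1 and any(
                edit_distance(w.lower(), v.lower(), min_dist - 1) != OVER_CAP
                for v in words):
            continue
        words.append(w)
        taken.add(normalize(w))
    return words


def generate_checklist(spec: FixtureSpec, path: str | Path,
                       source_id: int = 11) -> Path:
    """Write a synthetic hierarchical checklist CSV.

    Names at each rank are pairwise separated by at least
    ``spec.min_pairwise_distance`` edits (species compared as full
    binomials).  Classification is consistent along each lineage: every
    name's ancestors are recorded in the ancestor columns.
    """
    rng = random.Random(spec.seed)
    counts = spec.rank_counts()
    taken: set[str] = set()

    pools: dict[str, list[str]] = {}
    for rank in LINEAGE_RANKS[:-1]:  # kingdom .. genus
        pools[rank] = _sample_separated(rng, counts.get(rank, 1),
                                        spec.min_pairwise_distance, True, taken)
    # species: epithets joined with a round-robin genus; separation enforced
    # on the full binomial
    genera = pools["genus"]
    species: list[tuple[str, str]] = []  # (genus, binomial)
    tries = 0
    while len(species) < counts["species"]:
        tries += 1
        if tries > 20000:
            raise GenerationError(
                "cannot place species binomials at the requested separation; "
                "request fewer names or a smaller separation")
        genus = genera[len(species) % len(genera)]
        epithet = _make_word(rng, rng.randint(3, 5), False)
        binomial = f"{genus} {epithet}"
        if normalize(binomial) in taken:
            continue
        if spec.min_pairwise_distance > 1 and any(
                edit_distance(binomial.lower(), b.lower(),
                              spec.min_pairwise_distance - 1) != OVER_CAP
                for _, b in species):
            continue
        species.append((genus, binomial))
        taken.add(normalize(binomial))

    # parent assignment: round-robin keeps every branch populated
    parent: dict[tuple[str, str], str] = {}
    for upper, lower in zip(LINEAGE_RANKS[:-2], LINEAGE_RANKS[1:-1]):
        for i, name in enumerate(pools[lower]):
            parent[(lower, name)] = pools[upper][i % len(pools[upper])]

    def ancestors(rank: str, name: str) -> dict[str, str]:
        out: dict[str, str] = {}
        r, n = rank, name
        while r != "kingdom":
            above = LINEAGE_RANKS[LINEAGE_RANKS.index(r) - 1]
            n = parent[(r, n)]
            out[above] = n
            r = above
        return out

    rows: list[dict[str, str]] = []
    tid = 0
    for rank in LINEAGE_RANKS[:-1]:
        for name in pools[rank]:
            tid += 1
            rows.append({"taxon_id": f"T{tid}", "scientific_name": name,
                         "rank": rank, **ancestors(rank, name)})
    for genus, binomial in species:
        tid += 1
        rows.append({"taxon_id": f"T{tid}", "scientific_name": binomial,
                     "rank": "species", "genus": genus,
                     **ancestors("genus", genus)})

    cols = ["taxon_id", "scientific_name", "rank", *LINEAGE_RANKS[:-1]]
    df = pd.DataFrame(rows).reindex(columns=cols).fillna("")
    path = Path(path)
    df.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")
    return path


def _lineages_of(checklist: Checklist) -> list[dict[str, str]]:
    """One slot→name mapping per species record."""
    lineages = []
    for rec in checklist.by_rank["species"]:
        lin = dict(rec.classification)
        lin["species"] = rec.canonical_name
        lin["scientificName"] = rec.canonical_name
        lineages.append(lin)
    if not lineages:
        raise GenerationError("checklist has no species records to sample from")
    return lineages


def _corrupt(rng: random.Random, value: str, ops: Sequence[str],
             forbidden: set[str]) -> Optional[tuple[str, str]]:
    """One random single-edit typo on a letter of ``value``.

    Never touches spaces, never empties the string, never collides (case-
    insensitively) with a checklist name.  Returns (corrupted, op) or None
    when no acceptable corruption was found.
    """
    letters = [i for i, ch in enumerate(value) if not ch.isspace()]
    if not letters:
        return None
    for _ in range(200):
        op = rng.choice(list(ops))
        chars = list(value)
        if op == "substitute":
            i = rng.choice(letters)
            pool = _CONSONANTS + _VOWELS
            repl = rng.choice(pool)
            if repl == chars[i].lower():
                continue
            chars[i] = repl.upper() if chars[i].isupper() else repl
        elif op == "insert":
            i = rng.choice(letters)
            chars.insert(i + rng.choice((0, 1)), rng.choice(_CONSONANTS + _VOWELS))
        elif op == "delete":
            if len(letters) < 2:
                continue
            del chars[rng.choice(letters)]
        else:  # transpose
            pairs = [i for i in letters[:-1]
                     if i + 1 in letters and value[i] != value[i + 1]]
            if not pairs:
                continue
            i = rng.choice(pairs)
            chars[i], chars[i + 1] = chars[i + 1], chars[i]
        corrupted = "".join(chars)
        if corrupted != value and normalize(corrupted) not in forbidden:
            return corrupted, op
    return None


def generate_occurrences(checklist: Checklist, spec: FixtureSpec,
                         path: str | Path) -> tuple[Path, TruthTable]:
    """Sample occurrence rows from checklist lineages and inject typos.

    Each row fills all eight slots from one sampled lineage (the species and
    scientificName slots carry the full binomial); then
    ``n_errors`` (or ``⌊error_rate × cells⌋``) distinct cells each receive
    one random edit operation, with the ground truth recorded.
    """
    rng = random.Random(spec.seed + 1)
    lineages = _lineages_of(checklist)
    forbidden = {normalize(r.canonical_name) for r in checklist.records}

    rows: list[dict[str, str]] = []
    for _ in range(spec.n_rows):
        lin = lineages[rng.randrange(len(lineages))]
        rows.append({slot: lin.get(slot, "") for slot in SLOTS})

    n_cells = spec.n_rows * len(SLOTS)
    n_errors = spec.n_errors if spec.n_errors is not None \
        else math.floor(spec.error_rate * n_cells)
    if n_errors > n_cells:
        raise GenerationError(f"cannot corrupt {n_errors} of {n_cells} cells")

    all_cells = [(r, s) for r in range(1, spec.n_rows + 1) for s in SLOTS]
    truth = TruthTable()
    for r, slot in rng.sample(all_cells, n_errors):
        original = rows[r - 1][slot]
        if not original:
            continue
        got = _corrupt(rng, original, spec.error_ops, forbidden)
        if got is None:
            continue
        corrupted, op = got
        rows[r - 1][slot] = corrupted
        truth.entries.append(TruthEntry(row=r, slot=slot, original=original,
                                        corrupted=corrupted, operation=op))

    df = pd.DataFrame(rows, columns=list(SLOTS))
    path = Path(path)
    if path.suffix.lower() == ".xlsx":
        df.to_excel(path, index=False, engine="openpyxl")
    else:
        df.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")
    truth.entries.sort(key=lambda e: (e.row, SLOTS.index(e.slot)))
    return path, truth


# --- packaged worked example -------------------------------------------------

_UROPYGI_LINEAGE = {
    "kingdom": "Animalia", "phylum": "Arthropoda", "class": "Arachnida",
    "order": "Uropygi", "family": "Thelyphonidae",
    "genus": "Thelyphonelus", "species": "Thelyphonelus amazonicus",
}
_SECOND_LINEAGE = {
    "kingdom": "Animalia", "phylum": "Arthropoda", "class": "Arachnida",
    "order": "Uropygi", "family": "Thelyphonidae",
    "genus": "Mastigoproctus", "species": "Mastigoproctus giganteus",
}
_UROPYGI_TYPOS = [
    # (row, slot, original, corrupted) — the three classic hand-inserted errors
    (1, "kingdom", "Animalia", "Aanimalia"),
    (2, "genus", "Thelyphonelus", "Thelyphoneluss"),
    (3, "order", "Uropygi", "Urophygi"),
]


@dataclass(frozen=True)
class WorkedExample:
    checklist_path: Path
    occurrences_path: Path
    clean_path: Path
    truth: TruthTable
    source_id: int = 11


def uropygi_example(directory: str | Path, table_format: str = "csv") -> WorkedExample:
    """Write the packaged whip-scorpion worked example into ``directory``.

    Produces a mini GBIF-style checklist (two vinegaroon lineages), a
    3-row occurrence table with the three misspellings "Aanimalia",
    "Thelyphoneluss" and "Urophygi" injected (one per row), the clean
    pre-corruption table, and the truth table of the three injections.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    rows: list[dict[str, str]] = []
    tid = 0
    seen: set[tuple[str, str]] = set()
    for lin in (_UROPYGI_LINEAGE, _SECOND_LINEAGE):
        anc: dict[str, str] = {}
        for rank in LINEAGE_RANKS:
            name = lin[rank]
            if (rank, name) in seen:
                anc[rank] = name
                continue
            seen.add((rank, name))
            tid += 1
            rows.append({"taxon_id": f"T{tid}", "scientific_name": name,
                         "rank": rank, **anc})
            anc[rank] = name
    cl_path = directory / "uropygi_checklist.csv"
    cols = ["taxon_id", "scientific_name", "rank", *LINEAGE_RANKS[:-1]]
    pd.DataFrame(rows).reindex(columns=cols).fillna("").to_csv(
        cl_path, index=False, encoding="utf-8", lineterminator="\n")

    occ = [dict(_UROPYGI_LINEAGE, scientificName=_UROPYGI_LINEAGE["species"])
           for _ in range(3)]
    clean = pd.DataFrame(occ, columns=list(SLOTS))
    truth = TruthTable()
    dirty = clean.copy()
    for row, slot, original, corrupted in _UROPYGI_TYPOS:
        dirty.iloc[row - 1, dirty.columns.get_loc(slot)] = corrupted
        truth.entries.append(TruthEntry(row=row, slot=slot, original=original,
                                        corrupted=corrupted, operation="insert"))

    ext = ".xlsx" if table_format == "xlsx" else ".csv"
    occ_path = directory / f"uropygi_collection_modified{ext}"
    clean_path = directory / f"uropygi_collection_clean{ext}"
    for frame, p in ((dirty, occ_path), (clean, clean_path)):
        if ext == ".xlsx":
            frame.to_excel(p, index=False, engine="openpyxl")
        else:
            frame.to_csv(p, index=False, encoding="utf-8", lineterminator="\n")
    return WorkedExample(checklist_path=cl_path, occurrences_path=occ_path,
                         clean_path=clean_path, truth=truth)
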