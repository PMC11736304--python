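# taxonscrub

Detect and correct erroneous taxonomic names in biodiversity occurrence
spreadsheets.

Occurrence tables — the CSV/Excel files researchers keep before uploading to
portals such as GBIF — accumulate typographical errors in their rank columns
(kingdom … species, scientificName). Misspelled names break downstream
aggregation, so they must be found and fixed *before* the data propagates.
`taxonscrub` verifies every distinct name in a table against a local
reference checklist and drives a two-phase, human-in-the-loop correction
workflow:

1. **check** — every unique name in each mapped rank column is verified:
   exact matching first (after authorship stripping and case folding), and
   only on failure bounded fuzzy matching. Flagged names are written to a
   *suggestion spreadsheet* with the proposed correction, the matched taxon
   identifier, and a `Change` column (`yes`/`no`) for the reviewer.
2. **fix** — the reviewed suggestions are applied back onto the original
   table, replacing exactly the accepted cells and nothing else.

## The matching model

Names are reduced to canonical form (authorship and year removed, Unicode
NFC, whitespace collapsed, case folded). Fuzzy matching uses the **optimal
string alignment distance** *d(a, b)* — unit-cost substitutions, insertions,
deletions and adjacent transpositions, the four classic typo operations —
computed with a banded dynamic program capped at `maxEditDistance`
(default 2). A candidate *b* for query *a* is accepted when

```
d(a, b) ≤ maxEditDistance   and   sim(a, b) = 1 − d(a, b) / max(|a|, |b|) ≥ mainTaxonThreshold
```

with `mainTaxonThreshold = 0.75` by default. Candidates are ordered by
(descending similarity, ascending distance, name, taxon id), so runs are
fully deterministic. One-word names (genus and higher) get fuzzy matching
only when `withUninomialFuzzyMatch` is on; binomials are searched among
species records, extended to subspecies under `withSpeciesGroup`.

The reference checklist is a flat CSV (`taxon_id, scientific_name, rank`
plus optional ancestor columns; Darwin Core `taxonID/scientificName/
taxonRank` headers also accepted), tagged with a source code
(1 Catalog of Life, 4 NCBI, 11 GBIF, 180 iNaturalist).

## Worked example

The packaged mini dataset is a whip-scorpion (order Uropygi) collection with
three hand-inserted misspellings: kingdom `Animalia → Aanimalia`, order
`Uropygi → Urophygi`, genus `Thelyphonelus → Thelyphoneluss`. Running
`python examples/worked_example.py` prints:

```
Total Occurrences: 3
Total Taxon Names: 11
Top 3 Taxonomic Ranks with Errors: kingdom (1), order (1), genus (1)

  row(s) 1: kingdom 'Aanimalia' -> 'Animalia' (taxon T1)
  row(s) 3: order 'Urophygi' -> 'Uropygi' (taxon T4)
  row(s) 2: genus 'Thelyphoneluss' -> 'Thelyphonelus' (taxon T6)

Suggestions after applying corrections: 0
```

Each suggestion names the affected data rows, the rank column, the presumed
typo, the proposed checklist name, and the matched taxon identifier. Zero
suggestions on the second pass means every corrected cell now exact-matches
the checklist.

The same run from the shell (see `examples/cli_two_phase.sh`):

```sh
taxonscrub -os occurrences.csv \
  -r 'kingdom, phylum, class, order, family, genus, species, scientificName' \
  -ss suggestions -si 11 --checklist checklist.csv     # phase 1: check
# ... review suggestions.xlsx, set Change to yes/no ...
taxonscrub -os occurrences.csv -ss suggestions.xlsx -o corrected   # phase 2: fix
```

Use `x` in `-r` to skip a column (e.g. `-r 'kingdom, x, x, order, ...'`).
Other examples: `examples/verify_names.py` (single-name verification and
config knobs), `examples/synthetic_benchmark.py` (typo-injection recovery).

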