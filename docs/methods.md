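# Methods

This note documents the models, parameters and design choices behind
`taxonscrub`, in the spirit of a package vignette: what the procedure
assumes, what the knobs mean, and what the synthetic benchmarks do and do
not demonstrate.

## The verification procedure

A run touches three tables: the original occurrence table, the suggestion
spreadsheet, and the corrected output. Verification is *per name, per rank
column*: each distinct raw cell value in each mapped slot is verified
exactly once, regardless of how many rows it occurs in, and its suggestion
row lists every affected row. Rank columns are independent — no parent/child
consistency is enforced (a corrected genus does not rewrite scientificName
cells), because the workflow's contract is to touch exactly the cells a
reviewer accepted.

Verification of one name is strictly two-stage:

1. **Exact**: the canonical form (authorship stripped) is looked up in a
   hash index keyed by (rank, case-folded name). Any hit ends the search —
   fuzzy matching is never consulted when an exact match exists, which the
   tests assert via comparison counters.
2. **Fuzzy**: a linear scan over the records at the eligible ranks, keeping
   candidates within the distance cap and above the similarity threshold.

Outcomes map to suggestion rows as: Exact → no row; Fuzzy → a row proposing
the best candidate; NoMatch → a *flag-only* row (empty suggestion) so the
reviewer still sees the unresolvable name. Unparseable cells (empty,
four-plus tokens) yield NoMatch with a parse-failure marker rather than an
exception: one bad cell never aborts a batch.

## Name parsing

The authorship grammar is deliberately minimal and fully specified: (a)
everything from the first `(` onward is authorship; (b) after the leading
name token, a trailing run of capitalized tokens, 4-digit years and
connectives (`&`, `et`, `and`, `ex`, commas) is authorship; (c)
infraspecific markers (`var.`, `subsp.`, `ssp.`, `f.`) and the hybrid sign
are retained in the canonical string but excluded from token counting when
classifying structure (uninomial/binomial/trinomial). Unicode is NFC
normalized and diacritics are preserved. This is not a full nomenclatural
parser — virus names and hybrid formulas are out of scope — but it is total,
deterministic, and covers the citation styles found in rank columns.

## The distance and similarity

The metric is the optimal string alignment (restricted Damerau–Levenshtein)
distance: substitutions, insertions, deletions and adjacent transpositions
at unit cost, no substring edited twice. Transpositions matter because they
are one of the four dominant typing-error modes; plain Levenshtein would
score `Uropygi → Urpoygi` as 2 rather than 1. The DP is banded to diagonal
width `2·cap+1` with early abandon; because a transposition can reach row
*i+1* from row *i−1*, the abandon condition requires two consecutive rows
over the cap. The implementation is checked against a full uncapped DP
oracle and cross-checked against an independent Levenshtein library
(OSA ≤ Levenshtein always).

Similarity is `1 − d/max(|a|,|b|)`, the simplest length-normalized form
that makes a [0, 1] threshold meaningful: the same distance is more damning
on a short name. `similarity = 1 ⇔ distance = 0`, so a threshold of exactly
1.0 switches fuzzy matching off — the documented endpoint of the threshold's
semantics.

## Configuration

| key | default | meaning |
| --- | --- | --- |
| `withAllMatches` | false | off: keep only the best candidate; on: keep all passing candidates |
| `withCapitalization` | true | case-insensitive comparison |
| `withSpeciesGroup` | false | extend species queries to subspecies records |
| `withUninomialFuzzyMatch` | true | allow fuzzy matching for one-word names |
| `mainTaxonThreshold` | 0.75 | minimum similarity in [0, 1] |
| `withStats` | false | record per-query counters; emit a Similarity column |
| `maxEditDistance` | 2 | OSA distance cap ("minor errors") |

`withAllMatches=false` meaning "best match only" follows the tool's
documented wording; some verification services use the inverse convention,
which is why the semantics are spelled out here. The threshold default of
0.75 accepts a 2-edit error on names of 8+ characters and a 1-edit error on
names of 4+, which matches the length distribution of Latin names. The
numeric scale of the threshold is this package's own definition (similarity
as above); it is not calibrated to any remote service's score.

## Conventions with open alternatives

* **Species column**: a two-token cell is a full binomial; a one-token cell
  is a bare epithet joined with the row's genus cell to form the query (the
  corrected *epithet* is what gets written back). Both conventions occur in
  real data; this rule handles either without configuration. A bare epithet
  with no usable genus becomes a flag-only row.
* **scientificName column**: parsed (authorship removed) and verified at
  species rank, independently of the genus/species columns.
* **Row numbers** are 1-based over retained data rows — what a reviewer sees
  in a spreadsheet minus the header. Skipped blank lines are counted but do
  not shift the numbering of retained rows.
* **Deduplication key** is the raw cell string, not the normalized form, so
  the suggestion table shows exactly what the data says; `Animalia` and
  `animalia` are separate entries (the latter exact-matches anyway under
  case folding).
* **Homonyms** (same canonical name, same rank, different ids) are retained;
  exact lookup returns all and the deterministic candidate order
  (similarity, distance, name, taxon id) breaks ties.
* **Fix-phase column mapping** is re-derived from the suggestion file's Type
  column by matching slot names to the original header case-insensitively;
  `-r` overrides.

## The synthetic generator

`fixtures` grows a hierarchical checklist of pronounceable CV-syllable
names, rejection-sampled so that names within each rank are pairwise at
least `min_pairwise_distance` edits apart (species compared as full
binomials), then samples occurrence rows from its lineages and corrupts a
seeded selection of cells with exactly one edit operation each, recording a
truth table. Corruptions never touch whitespace (so token structure is
preserved), never empty a cell, and never collide with a checklist name, so
the ground truth stays well-defined.

The separation parameter is what makes recovery *provable*: at pairwise
distance ≥ 2k+1, any ≤ k-edit corruption is strictly closer to its original
than to any other name, so the nearest neighbour is unique and the expected
recovery rate is exactly 100%. The benchmarks use `min_pairwise_distance=3`
with single-edit typos (k=1).

What the generator does **not** emulate: synonymy and accepted-name chains,
cross-kingdom homonyms, authorship-string corruption, missing higher ranks,
and the heavy-tailed name-frequency distributions of real collections.
Passing the synthetic benchmarks therefore demonstrates the correctness of
the matching and bookkeeping machinery, not real-world recall: on real data,
typos can land nearer to a *different* valid name than to their original
(dense genera differ by one letter), which is precisely why the workflow
keeps a human review step instead of auto-applying corrections.

## Problem sizes and numerical choices

The acceptance benchmarks use a 1,000-record checklist with 100 queries for
matcher/oracle agreement and a 100-row table with 500 injected typos for
recovery — sizes at which the brute-force DP oracle is still exact and the
whole suite runs in seconds while exercising every code path at realistic
rank-bucket sizes. Determinism is asserted at the byte level on written
files. Ties everywhere are broken by fixed keys (slot order, lexicographic
name, taxon id); no randomness exists outside the fixture generator, which
is fully driven by the user-supplied seed.

## Known limitations

* No live verification backend: the `--remote` flag is a documented stub;
  all matching runs against a local checklist file.
* No synonym resolution: a valid but outdated name exact-matches only if the
  checklist lists it.
* Whole-string matching: multi-word queries are compared as whole canonical
  strings, so a typo in *both* words of a binomial (2 edits total) is still
  found, but per-epithet recombination (genus transfers) is not.
* Corrections do not cascade across columns.
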