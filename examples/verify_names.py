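"""Verifying single names: exact precedence, fuzzy recovery, and config knobs.

Builds a five-record in-memory checklist and queries it with a correct
name, a one-letter typo, and a hopeless string, then shows how the
similarity threshold and the uninomial-fuzzy switch change the outcome.
"""

from taxonscrub import Checklist, Config, TaxonRecord, verify_taxon
from taxonscrub.nameparse import parse_scientific_name

entries = [("T1", "Animalia", "kingdom"), ("T2", "Plantae", "kingdom"),
           ("T3", "Uropygi", "order"), ("T4", "Thelyphonelus", "genus"),
           ("T5", "Thelyphonelus amazonicus", "species")]
records = [TaxonRecord(taxon_id=t, source_id=11, scientific_name=n,
                       canonical_name=parse_scientific_name(n).canonical, rank=r)
           for t, n, r in entries]
checklist = Checklist(records=records, source_id=11)

for query, rank in [("Animalia", "kingdom"), ("Aanimalia", "kingdom"),
                    ("Xyzzyqq", "kingdom"),
                    ("Thelyphonelus amazonicus (Butler, 1872)", "species")]:
    r = verify_taxon(query, rank, checklist, Config())
    best = (f"{r.best.record.canonical_name} (distance {r.best.edit_distance}, "
            f"similarity {r.best.similarity:.3f})") if r.best else "-"
    print(f"{query!r:45s} @{rank:8s} -> {r.match_type:7s} best: {best}")

# Raising the threshold to 1.0 makes fuzzy matching impossible: similarity
# 1.0 requires distance 0, which exact matching already covers.
strict = verify_taxon("Aanimalia", "kingdom", checklist,
                      Config(main_taxon_threshold=1.0))
print(f"\nthreshold 1.0: 'Aanimalia' -> {strict.match_type}")

# Switching off fuzzy matching for one-word names leaves typos undetected.
no_uni = verify_taxon("Aanimalia", "kingdom", checklist,
                      Config(with_uninomial_fuzzy_match=False))
print(f"withUninomialFuzzyMatch off: 'Aanimalia' -> {no_uni.match_type}")
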