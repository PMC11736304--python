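"""End-to-end check/fix cycle on the packaged vinegaroon worked example.

Builds the mini whip-scorpion dataset with three hand-inserted misspellings
("Aanimalia", "Thelyphoneluss", "Urophygi"), detects them against the mini
checklist, accepts every suggestion, and shows that the corrected table is
clean on a second pass.
"""

import dataclasses
import tempfile
from pathlib import Path

from taxonscrub import (ColumnMapping, Config, apply_corrections,
                        build_suggestions, load_checklist, read_occurrences,
                        uropygi_example)

workdir = Path(tempfile.mkdtemp(prefix="taxonscrub_example_"))
example = uropygi_example(workdir)
checklist = load_checklist(example.checklist_path, source_id=11)
table = read_occurrences(example.occurrences_path, ColumnMapping.identity())

suggestions, summary = build_suggestions(table, checklist, Config())
for line in summary.format_lines():
    print(line)
print()
for s in suggestions:
    print(f"  row(s) {', '.join(map(str, s.row_refs))}: {s.rank_type} "
          f"{s.wrong_name!r} -> {s.suggested_name!r} (taxon {s.id_source})")

# a reviewer would flip Change to "yes" in the spreadsheet; do it in code
accepted = [dataclasses.replace(s, change="yes") for s in suggestions]
corrected = apply_corrections(table, accepted)
residual, _ = build_suggestions(corrected, checklist, Config())
print(f"\nSuggestions after applying corrections: {len(residual)}")
# Three suggestion rows, one per injected typo; zero residual suggestions
# means every misspelled cell was restored to its checklist name.
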