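#!/bin/sh
# The two-phase command-line workflow: check, review, fix.
# Uses the fixtures subcommand to build a small synthetic dataset first.
set -e
DIR=$(mktemp -d)

taxonscrub fixtures --out "$DIR" --seed 5 --n-lineages 8 --n-rows 20 --error-rate 0.05

# Phase 1 (check): verify every rank column and write the suggestion table.
taxonscrub -os "$DIR/occurrences.csv" \
  -r 'kingdom, phylum, class, order, family, genus, species, scientificName' \
  -ss "$DIR/suggestions.csv" -si 11 --checklist "$DIR/checklist.csv"

# Review step: a person would open suggestions.csv and set Change to yes/no.
# Accept everything here.
python - "$DIR/suggestions.csv" <<'EOF'
import sys, pandas as pd
p = sys.argv[1]
df = pd.read_csv(p, dtype=str, keep_default_na=False)
df["Change"] = "yes"
df.to_csv(p, index=False)
EOF

# Phase 2 (fix): apply the accepted suggestions to produce the corrected table.
taxonscrub -os "$DIR/occurrences.csv" -ss "$DIR/suggestions.csv" \
  -o "$DIR/corrected.csv"

echo "Corrected table written to $DIR/corrected.csv"
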