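#!/usr/bin/env bash
# Stage-by-stage pipeline from the shell. `run-all` chains everything;
# the staged commands below show the intermediate files.
set -euo pipefail

workdir=$(mktemp -d)
cat > "$workdir/screen.yaml" <<EOF
n_features: 120
n_wells: 96
sites_per_well: 5
vehicle_fraction: 0.15
seed: 42
EOF

morphoprint simulate --config "$workdir/screen.yaml" --out "$workdir/sim"
morphoprint select-features --in "$workdir/sim" --out "$workdir/selection.csv"
morphoprint fingerprint --in "$workdir/sim" --selection "$workdir/selection.csv" \
    --out "$workdir/fingerprints.csv"
morphoprint metrics --fingerprints "$workdir/fingerprints.csv" --out "$workdir/metrics"

# or everything at once, including subprofile matching:
morphoprint run-all --config "$workdir/screen.yaml" --out "$workdir/full"

ls "$workdir/full"
head -n 3 "$workdir/full/activity.csv"
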