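#!/usr/bin/env bash
# End-to-end shell workflow: simulate a ground-truthed trajectory, measure
# the twist-angle series, summarize populations, and list contacts.
set -euo pipefail

workdir=$(mktemp -d)
trap 'rm -rf "$workdir"' EXIT

cat > "$workdir/run.yaml" <<EOF
seed: 7
output_dir: $workdir/out
simulate:
  n_atoms_N: 30
  n_atoms_C: 30
  n_frames: 500
  p_IA: 0.02
  p_AI: 0.03
  noise_sigma_A: 0.1
  global_motion: true
  seed: 7
inactive: $workdir/out/inactive.pdb
active: $workdir/out/active.pdb
trajectory: $workdir/out/trajectory.pdb
rolling_window: 51
threshold_deg: 15
selections:
  n_domain: {label: N-domain, chain: A, ranges: [[1, 30]], atoms: [CA]}
  c_domain: {label: C-domain, chain: A, ranges: [[31, 60]], atoms: [CA]}
EOF

domaintwist simulate --config "$workdir/run.yaml"
domaintwist angle --config "$workdir/run.yaml"
domaintwist populations --config "$workdir/run.yaml"
domaintwist contacts --structure "$workdir/out/inactive.pdb" --out "$workdir/out" --seed 7

echo "--- first angle rows ---"
head -n 4 "$workdir/out/angles_trajectory.csv"
echo "--- population summary ---"
cat "$workdir/out/populations.json"
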