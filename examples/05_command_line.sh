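#!/usr/bin/env bash
# The same analysis from the shell: simulate a snapshot, fit the model,
# benchmark the predictions against the simulated clones.
set -euo pipefail
out=$(mktemp -d)

msot simulate --preset four-arm --cells 400 --seed 0 --clones 20 --out "$out/sim"
msot fit --snapshot "$out/sim/embedding.csv" --roles "$out/sim/roles.csv" \
     --stages 11 --prox-iters 10 --out "$out/fit"
msot benchmark --fates "$out/fit/fate_probabilities.csv" \
     --metadata "$out/sim/clones.csv" --out "$out/metrics.json"

echo "results in $out:"
ls "$out/fit"
python -m json.tool "$out/metrics.json" | head -6
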