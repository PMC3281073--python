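#!/bin/sh
# Shell pipeline: simulate -> select -> external LOOCV.
# Every output directory receives a metadata.json that records the exact
# parameters, seed and input checksum needed to reproduce the run.
set -e
out=${1:-/tmp/randomknn-demo}

randomknn simulate --n 40 --p 200 --informative 8 --shift 1.5 --seed 1 \
    --out "$out/sim"
echo "planted features:"; cat "$out/sim/planted_features.txt"

randomknn select --input "$out/sim/dataset.tsv" --r 500 --seed 1 \
    --out "$out/sel"
echo "selected features:"; cat "$out/sel/selected_features.txt"

randomknn loocv --input "$out/sim/dataset.tsv" --r 300 --seed 1 \
    --out "$out/cv"
cat "$out/cv/loocv.json"
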