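#!/bin/sh
# End-to-end shell workflow: generate -> split -> train -> segment.
# Writes everything under ./scratch_example (safe to delete).
set -e
OUT=scratch_example
stemseg generate --n 12 --points 512 --out $OUT/data --seed 0
stemseg split --manifest $OUT/data/manifest.tsv --seed 0
stemseg train --manifest $OUT/data/manifest.tsv --out $OUT/model \
    --n-points 512 --channels 16,32,64,128,256 --epochs 5 --seed 0
CLOUD=$(ls $OUT/data/*.ply | head -1)
stemseg segment --checkpoint $OUT/model.npz --cloud "$CLOUD" \
    --out $OUT/segmented.ply
echo "wrote $OUT/segmented.ply (green = predicted stem, blue = other)"
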