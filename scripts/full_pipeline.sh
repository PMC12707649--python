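#!/bin/sh
# Optional end-to-end run with a *trained* generator instead of the toy
# family. Not part of the test suite: adversarial training at realistic
# dataset sizes is slow on CPU and needs a user-supplied image bank.
#
# Provide a directory of 64x64 single-channel PNGs of the object
# categories you want the solver to know (e.g. exported from a digit or
# fashion-item dataset), then:
#
#   sh scripts/full_pipeline.sh IMAGES_DIR OUTLINES_DIR WORKDIR
#
# IMAGES_DIR   64x64 greyscale PNGs for generator training
# OUTLINES_DIR greyscale object-outline PNGs to hide as constellations
# WORKDIR      output directory
set -eu

IMAGES_DIR=$1
OUTLINES_DIR=$2
WORKDIR=$3
SEED=${SEED:-0}

constellation train-gan --data "$IMAGES_DIR" --epochs 5 --seed "$SEED" \
    --out "$WORKDIR/gan"

constellation generate --shapes "$OUTLINES_DIR" --spacing 11 \
    --noise-ratio 0.5 --n 10 --seed "$SEED" --out "$WORKDIR/stimuli"

for png in "$WORKDIR"/stimuli/*.png; do
    id=$(basename "$png" .png)
    constellation solve --method genetic --stimulus "$png" \
        --generator "$WORKDIR/gan" --classifier none \
        --seed "$SEED" --out "$WORKDIR/runs/$id"
done

constellation eval --runs "$WORKDIR/runs" --stimuli "$WORKDIR/stimuli" \
    --out "$WORKDIR/report"
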