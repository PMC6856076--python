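#!/usr/bin/env bash
# The same workflow from the shell: simulate -> infer -> evaluate -> export.
set -euo pipefail
mkdir -p scratch/cli_demo

# 1. simulate a study-shaped dataset with known ground truth
causnet simulate --genes 10 --k-true 2 --conditions 10 --times 3 --reps 3 \
    --seed 5 --out-prefix scratch/cli_demo/sim

# 2. infer: k=2 regulators per target, 100 perturbations, weight cut 0.1
causnet infer --input scratch/cli_demo/sim.expression.tsv \
    --k 2 --perturbations 100 --seed 42 --no-virtual-shift \
    --weight-threshold 0.1 --out-prefix scratch/cli_demo/run

# 3. score the inferred network against the ground truth at weight >= 0.5
causnet evaluate --truth scratch/cli_demo/sim.edges.tsv \
    --network scratch/cli_demo/run.weighted.tsv --threshold 0.5

# 4. re-export at a stricter cut-off for visualization
causnet export --network scratch/cli_demo/run.weighted.tsv \
    --threshold 0.6 --sif scratch/cli_demo/run_strict.sif
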