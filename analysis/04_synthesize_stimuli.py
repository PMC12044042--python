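#!/usr/bin/env python
"""Synthesize artificial stimuli by activation maximization.

For every (subject, region) encoding model of the cohort, evolves
generator latent codes to maximize the model's mean predicted activation,
applies the convergence filter, and writes the retained stimuli as PNGs
with a manifest under results/stimuli/.
"""

import argparse
from pathlib import Path

import numpy as np

from amyenc.studies import build_selectivity_cohort
from amyenc.synthesis import synthesize_battery
from amyenc.synthetic import write_images_png

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--seeds-per-target", type=int, default=3)
parser.add_argument("--out", type=Path, default=Path("results/stimuli"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

models, networks, _ = build_selectivity_cohort(args.seed, distinctness=1.0)
battery = synthesize_battery(
    models,
    networks,
    n_seeds_per_target=args.seeds_per_target,
    population=16,
    generations=30,
    base_seed=args.seed,
)
n_attempted = len(models) * args.seeds_per_target
print(f"synthesis: {len(battery.results)}/{n_attempted} runs retained by the "
      f"convergence filter")

images = np.stack([r.final_image for r in battery.results])
write_images_png(images, args.out, prefix="stim")
battery.manifest.to_csv(args.out / "manifest.csv", index=False)

by_region = battery.manifest.groupby("target_region").size()
print("retained stimuli per target region:")
print(by_region.to_string())
print(f"median final objective: {battery.manifest['final_objective'].median():.3f}")
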