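#!/usr/bin/env python
"""Simulate the synthetic cohort that every later analysis step consumes.

Builds the fixed generator/extractor pair, the desk-scale parcellation
(four amygdala subregions plus visual-cortex and inferotemporal controls),
per-subject ground-truth voxel weights with distinct subregion patterns,
and one HRF-convolved movie-watching session per subject.  Also renders a
small affective image set with normative valence/arousal ratings.
Artifacts are written under results/cohort/.
"""

import argparse
from pathlib import Path

import numpy as np

from amyenc.data import ALL_REGIONS
from amyenc.studies import SELECTIVITY_REGIONS, build_selectivity_cohort
from amyenc.synthetic import make_affective_imageset, write_images_png

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results/cohort"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

models, networks, parc = build_selectivity_cohort(args.seed, distinctness=1.0)
parc.to_csv(args.out / "parcellation.csv")
networks.save(args.out / "networks.npz")

subjects = sorted({s for s, _ in models})
print(f"cohort: {len(subjects)} subjects x {len(ALL_REGIONS)} regions "
      f"({parc.n_voxels} voxels: {SELECTIVITY_REGIONS})")
for (subject, region), model in models.items():
    model.pls.save(
        args.out / f"model_{subject}_{region}.npz",
        subject=subject, region=region, n_components=model.n_components,
    )
print(f"saved {len(models)} encoding models to {args.out}")

images, ratings, feats = make_affective_imageset(64, seed=args.seed + 1)
write_images_png(images, args.out / "images")
ratings.to_csv(args.out / "ratings.csv", index=False)
feats.to_csv(args.out / "image_features.csv", index=False)
print(f"affective image set: {len(ratings)} images with standardized "
      f"valence/arousal (mean {ratings['valence'].mean():+.1e}, "
      f"SD {ratings['valence'].std(ddof=1):.3f})")
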