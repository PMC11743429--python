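"""Grad-CAM: where does a trained model look when scoring an organ?

Trains a full-image network on a synthetic cohort, then measures what
fraction of each organ's class-activation mass falls inside that organ's
tongue region, compared with the region's share of the image area.  A
well-localized model concentrates far more mass in the cue region than
its area alone would explain.
"""

import numpy as np

from organnet import (
    CohortSpec, OrganNetConfig, SceneSpec, TrainConfig, cam_region_mass,
    compute_bounds, gradcam, region_masks, train,
)
from organnet.harness import SingleBranchModel, TongueDataset
from organnet.metrics import ORGANS
from organnet.synth import generate_cohort_arrays

REGION_OF_ORGAN = {"heart": "A", "lung": "A", "liver": "B",
                   "spleen": "C", "kidney": "D"}

cohort = CohortSpec(n=800, seed=11)
images, labels, splits = generate_cohort_arrays(cohort, SceneSpec(image_size=64))
dataset = TongueDataset(images, labels, splits)

model = SingleBranchModel("full", OrganNetConfig.small(), seed=0)
train(model, dataset, TrainConfig.small(seed=0))

bounds = compute_bounds(64, 64)
masks = region_masks(bounds)
test = dataset.subset("test")
print("mean CAM mass in the organ's region vs the region's area fraction")
print("(over up to 20 positive test images per organ):")
for organ in ORGANS:
    region = REGION_OF_ORGAN[organ]
    idx = np.where(test.labels[:, ORGANS.index(organ)] == 1)[0][:20]
    masses = [cam_region_mass(gradcam(model, test.images[i], organ), bounds, region)
              for i in idx]
    print(f"  {organ:7s} region {region}: CAM mass {np.mean(masses):.3f} "
          f"vs area {masks[region].mean():.3f}")
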