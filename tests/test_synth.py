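"""Synthetic cohort generator: determinism, label-feature-region consistency,
prevalence calibration, manifest round-trips."""

import numpy as np
import pandas as pd
import pytest

from organnet.metrics import ORGANS
from organnet.model import OrganLabels
from organnet.regions import compute_bounds, region_masks
from organnet.synth import (
    CLINICAL_COHORT_SIZE, CLINICAL_UNHEALTHY_COUNTS, CohortSpec, SceneSpec,
    PREVALENCE_PRESETS, generate_cohort, render_scene, sample_labels,
)

REGION_OF_ORGAN = {"heart": "A", "lung": "A", "liver": "B",
                   "spleen": "C", "kidney": "D"}


def test_sample_labels_extremes():
    all_on = CohortSpec(n=50, prevalence={o: 1.0 for o in ORGANS}, seed=1)
    assert (sample_labels(all_on) == 1).all()
    all_off = CohortSpec(n=50, prevalence={o: 0.0 for o in ORGANS}, seed=1)
    assert (sample_labels(all_off) == 0).all()


def test_sample_labels_reproducible():
    cohort = CohortSpec(n=500, seed=9)
    assert (sample_labels(cohort) == sample_labels(cohort)).all()


def test_prevalence_calibration_large_n():
    """Empirical prevalence converges to the configured marginals (within 2%)."""
    cohort = CohortSpec(n=10_000, seed=2)
    labels = sample_labels(cohort)
    for i, organ in enumerate(ORGANS):
        assert labels[:, i].mean() == pytest.approx(
            cohort.prevalence[organ], abs=0.02)


def test_clinical_cohort_counts_within_three_sd():
    """At study scale the per-organ unhealthy counts match the emulated
    cohort's totals to within 3 binomial standard deviations."""
    cohort = CohortSpec.clinical(seed=123)
    labels = sample_labels(cohort)
    for i, organ in enumerate(ORGANS):
        expected = CLINICAL_UNHEALTHY_COUNTS[organ]
        p = expected / CLINICAL_COHORT_SIZE
        sd = np.sqrt(CLINICAL_COHORT_SIZE * p * (1 - p))
        assert abs(int(labels[:, i].sum()) - expected) <= 3 * sd


def test_render_scene_deterministic():
    spec = SceneSpec(image_size=64)
    labels = OrganLabels(1, 0, 1, 0, 1)
    s1 = render_scene(labels, spec, np.random.default_rng(5))
    s2 = render_scene(labels, spec, np.random.default_rng(5))
    assert (s1.image == s2.image).all()
    assert s1.ledger == s2.ledger


def test_all_healthy_scene_has_empty_ledger():
    spec = SceneSpec(image_size=64)
    sample = render_scene(OrganLabels(0, 0, 0, 0, 0), spec,
                          np.random.default_rng(0))
    assert sample.ledger == ()


@pytest.mark.parametrize("organ", ORGANS)
def test_single_organ_features_confined_to_its_region(organ):
    spec = SceneSpec(image_size=64)
    masks = region_masks(compute_bounds(64, 64))
    labels = OrganLabels(**{o: int(o == organ) for o in ORGANS})
    rng = np.random.default_rng(11)
    for _ in range(20):
        sample = render_scene(labels, spec, rng)
        assert len(sample.ledger) >= 1
        for feat in sample.ledger:
            assert feat.organ == organ
            r0, c0, r1, c1 = feat.bbox
            assert masks[REGION_OF_ORGAN[organ]][r0:r1, c0:c1].all()


def test_label_feature_region_consistency_bulk():
    """Ledger matches labels exactly and every bbox sits in its region."""
    spec = SceneSpec(image_size=64)
    masks = region_masks(compute_bounds(64, 64))
    rng = np.random.default_rng(21)
    for _ in range(200):
        lab = OrganLabels(*(int(v) for v in rng.integers(0, 2, 5)))
        sample = render_scene(lab, spec, rng)
        organs_with_features = {f.organ for f in sample.ledger}
        for organ in ORGANS:
            assert (getattr(lab, organ) == 1) == (organ in organs_with_features)
        for feat in sample.ledger:
            r0, c0, r1, c1 = feat.bbox
            assert masks[REGION_OF_ORGAN[feat.organ]][r0:r1, c0:c1].all()


def test_uniform_placement_control_mode():
    spec = SceneSpec(image_size=64, placement="uniform")
    sample = render_scene(OrganLabels(1, 1, 1, 1, 1), spec,
                          np.random.default_rng(3))
    assert len(sample.ledger) >= 5   # features exist but are not localized


def test_generate_cohort_roundtrip(tmp_path):
    cohort = CohortSpec(n=20, splits=(14, 2, 4), seed=8)
    spec = SceneSpec(image_size=64)
    manifest = generate_cohort(cohort, spec, tmp_path, write_ledgers=True)
    assert manifest["split"].value_counts().to_dict() == {
        "train": 14, "val": 2, "test": 4}
    on_disk = pd.read_csv(tmp_path / "manifest.csv")
    assert (on_disk[list(ORGANS)].to_numpy()
            == sample_labels(cohort)).all()
    assert (tmp_path / "tongue_00000.png").exists()
    assert (tmp_path / "tongue_00000.ledger.json").exists()


def test_generate_cohort_seed_determinism(tmp_path):
    import hashlib
    cohort = CohortSpec(n=6, splits=(4, 1, 1), seed=4)
    spec = SceneSpec(image_size=64)
    digests = []
    for sub in ("a", "b"):
        out = tmp_path / sub
        generate_cohort(cohort, spec, out)
        h = hashlib.sha256()
        for p in sorted(out.iterdir()):
            h.update(p.read_bytes())
        digests.append(h.hexdigest())
    assert digests[0] == digests[1]


def test_spec_validation():
    with pytest.raises(ValueError):
        SceneSpec(image_size=10)
    with pytest.raises(ValueError):
        SceneSpec(menus={o: () for o in ORGANS})
    with pytest.raises(ValueError):
        CohortSpec(n=10, splits=(5, 5, 5))
    with pytest.raises(ValueError):
        CohortSpec(prevalence={o: 1.5 for o in ORGANS})


def test_clinical_preset_prevalences():
    prev = PREVALENCE_PRESETS["clinical"]
    assert prev["spleen"] == pytest.approx(4616 / 4645)
    assert sum(CLINICAL_UNHEALTHY_COUNTS.values()) == 2103 + 2739 + 2938 + 4616 + 3111
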