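"""Synthetic labeled tongue images with region-localized unhealthy features.

The study-style cohort this module emulates is a set of pre-segmented tongue
photographs, each annotated with five binary organ statuses (heart, lung,
liver, spleen, kidney; 1 = unhealthy).  Because such clinical data are
private, the generator renders a pink elliptical tongue on a dark background
and, for every organ labeled unhealthy, plants at least one TCM-style feature
(spots, cracks, toothmarks, fur patches, body-color shifts) strictly inside
that organ's tongue region as produced by :mod:`organnet.regions`:

* heart  -> spots / reddened body in the lower half of the tip band (A);
* lung   -> spots / fur patches in the upper half of the tip band (A);
* liver  -> toothmarks / spots on the lateral margins (B);
* spleen -> cracks / fur patches in the center (C);
* kidney -> cracks / fur patches at the root (D).

Organs labeled healthy receive no feature in their region, so the planted
signal is perfectly region-localized (a property real tongues only
approximate).  Every placement is recorded in a ledger of
``(feature kind, organ, bounding box)`` entries, which makes the
label-feature-region consistency checkable sample by sample.

Cohort label vectors are drawn independently per organ from configurable
marginal prevalences.  The ``"clinical"`` preset uses the unhealthy-sample
marginals of a 4,645-participant tongue-diagnosis cohort (heart 2,103,
lung 2,739, liver 2,938, spleen 4,616, kidney 3,111 unhealthy) with
train/val/test splits of 3,455 / 295 / 895.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .images import save_rgb
from .metrics import ORGANS
from .model import OrganLabels
from .regions import compute_bounds

__all__ = [
    "FeatureKind", "FeaturePlacement", "SceneSpec", "CohortSpec",
    "LabeledSample", "sample_labels", "render_scene", "generate_cohort",
    "CLINICAL_COHORT_SIZE", "CLINICAL_UNHEALTHY_COUNTS", "CLINICAL_SPLITS",
    "PREVALENCE_PRESETS", "DEFAULT_MENUS",
]

# Marginals of the emulated clinical cohort (unhealthy counts per organ).
CLINICAL_COHORT_SIZE = 4645
CLINICAL_UNHEALTHY_COUNTS = {
    "heart": 2103, "lung": 2739, "liver": 2938, "spleen": 4616, "kidney": 3111,
}
CLINICAL_SPLITS = (3455, 295, 895)  # train / val / test

PREVALENCE_PRESETS = {
    "clinical": {o: c / CLINICAL_COHORT_SIZE
                 for o, c in CLINICAL_UNHEALTHY_COUNTS.items()},
    "balanced": {o: 0.5 for o in ORGANS},
}

FEATURE_KINDS = ("spot", "crack", "toothmark", "fur_patch", "pale_body", "red_body")

# Which feature kinds may indicate each organ (reduced, renderable menu).
DEFAULT_MENUS: dict[str, tuple[str, ...]] = {
    "heart": ("spot", "red_body"),
    "lung": ("spot", "fur_patch"),
    "liver": ("toothmark", "spot"),
    "spleen": ("crack", "fur_patch"),
    "kidney": ("crack", "fur_patch"),
}

SPLIT_NAMES = ("train", "val", "test")


class GenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class FeatureKind:
    """A renderable unhealthy-tongue feature."""

    name: str
    count_range: tuple[int, int] = (2, 4)
    size_frac: tuple[float, float] = (0.02, 0.05)  # of image side

    def __post_init__(self) -> None:
        if self.name not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.name!r}")


@dataclass(frozen=True)
class FeaturePlacement:
    kind: str
    organ: str
    bbox: tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open


@dataclass(frozen=True)
class SceneSpec:
    """Recipe for one synthetic tongue scene."""

    image_size: int = 64
    background: tuple[int, int, int] = (38, 40, 58)
    tongue_color: tuple[int, int, int] = (198, 128, 138)
    color_jitter: float = 12.0          # per-channel uniform jitter, 8-bit units
    ellipse_row_frac: tuple[float, float] = (0.42, 0.47)  # semi-axis / size
    ellipse_col_frac: tuple[float, float] = (0.30, 0.36)
    noise_std: float = 4.0              # Gaussian pixel noise, 8-bit units
    menus: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_MENUS))
    placement: str = "region"           # "region" (localized) or "uniform"

    def __post_init__(self) -> None:
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if self.placement not in ("region", "uniform"):
            raise ValueError("placement must be 'region' or 'uniform'")
        for organ in ORGANS:
            if not self.menus.get(organ):
                raise ValueError(f"feature menu for {organ} must be non-empty")


@dataclass(frozen=True)
class CohortSpec:
    """Cohort recipe: size, per-organ marginals, splits, seed."""

    n: int = 2000
    prevalence: dict[str, float] = field(
        default_factory=lambda: dict(PREVALENCE_PRESETS["clinical"]))
    splits: tuple[int, int, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for organ in ORGANS:
            p = self.prevalence.get(organ)
            if p is None or not (0.0 <= p <= 1.0):
                raise ValueError(f"prevalence for {organ} must lie in [0, 1]")
        if self.splits is not None and sum(self.splits) != self.n:
            raise ValueError(f"splits {self.splits} do not sum to n={self.n}")

    @property
    def effective_splits(self) -> tuple[int, int, int]:
        """Configured splits, or study-proportioned defaults (~75/6/19%)."""
        if self.splits is not None:
            return self.splits
        fr = np.array(CLINICAL_SPLITS) / CLINICAL_COHORT_SIZE
        val = int(round(self.n * fr[1]))
        test = int(round(self.n * fr[2]))
        return (self.n - val - test, val, test)

    @classmethod
    def clinical(cls, seed: int = 0) -> "CohortSpec":
        """Study-scale preset: 4,645 samples at the clinical marginals."""
        return cls(n=CLINICAL_COHORT_SIZE, splits=CLINICAL_SPLITS, seed=seed)


@dataclass(frozen=True)
class LabeledSample:
    image: np.ndarray            # HxWx3 uint8
    labels: OrganLabels
    ledger: tuple[FeaturePlacement, ...]


def sample_labels(cohort: CohortSpec,
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw ``n x 5`` binary label vectors, organs independent Bernoulli."""
    rng = np.random.default_rng(cohort.seed) if rng is None else rng
    prev = np.array([cohort.prevalence[o] for o in ORGANS])
    return (rng.random((cohort.n, len(ORGANS))) < prev).astype(np.int64)


# ---------------------------------------------------------------------------
# rendering


def _organ_box(organ: str, bounds, placement: str) -> tuple[list[tuple[int, int, int, int]], bool]:
    """Candidate placement boxes (row0, col0, row1, col1) for an organ.

    Returns the boxes plus a flag saying whether ellipse-interior rejection
    sampling should be attempted (margins stick out of the tongue body).
    """
    h, w = bounds.height, bounds.width
    if placement == "uniform":
        # anywhere on the tongue body (control mode: breaks localization)
        return [(2, 2, h - 2, w - 2)], True
    if organ == "heart":  # lower half of the tip band
        half = bounds.r_tip + (h - bounds.r_tip) // 2
        return [(half, w // 4, h, 3 * w // 4)], True
    if organ == "lung":   # upper half of the tip band
        half = bounds.r_tip + (h - bounds.r_tip) // 2
        return [(bounds.r_tip, w // 4, half, 3 * w // 4)], True
    if organ == "liver":  # either margin strip, rows above the tip band
        r0, r1 = bounds.r_mid // 2, bounds.r_tip
        return [(r0, 0, r1, bounds.c_left),
                (r0, bounds.c_right, r1, w)], False
    if organ == "spleen":
        return [(bounds.r_mid, bounds.c_left, bounds.r_tip, bounds.c_right)], True
    if organ == "kidney":
        return [(bounds.r_mid // 3, bounds.c_left, bounds.r_mid, bounds.c_right)], True
    raise ValueError(f"unknown organ {organ!r}")


def _sample_center(box: tuple[int, int, int, int], margin: int | tuple[int, int],
                   ellipse, reject: bool, rng: np.random.Generator
                   ) -> tuple[int, int]:
    m_r, m_c = (margin, margin) if isinstance(margin, int) else margin
    r0, c0, r1, c1 = box
    r_lo, r_hi = r0 + m_r, r1 - m_r
    c_lo, c_hi = c0 + m_c, c1 - m_c
    if r_hi <= r_lo or c_hi <= c_lo:
        raise GenerationError(
            f"region box {box} too small for a feature of half-size {margin}")
    cy, cx, ar, ac = ellipse
    for _ in range(60):
        r = int(rng.integers(r_lo, r_hi))
        c = int(rng.integers(c_lo, c_hi))
        if not reject:
            return r, c
        if ((r - cy) / ar) ** 2 + ((c - cx) / ac) ** 2 <= 0.85:
            return r, c
    return r, c  # fall back to the last in-box draw


def _fit_radius(box: tuple[int, int, int, int], radius: float,
                aspect: float = 1.0) -> float:
    """Clamp a feature radius so its margin leaves room for a center in box."""
    r0, c0, r1, c1 = box
    max_r = (r1 - r0 - 3) / 2.0
    max_c = (c1 - c0 - 3) / (2.0 * aspect)
    fitted = min(radius, max_r, max_c)
    if fitted < 0.5:
        raise GenerationError(f"region box {box} too small for any feature")
    return fitted


def _disk_mask(shape: tuple[int, int], center: tuple[int, int], radius: float
               ) -> np.ndarray:
    rr = np.arange(shape[0])[:, None]
    cc = np.arange(shape[1])[None, :]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2


def _blend(img: np.ndarray, mask: np.ndarray, color, alpha: float) -> None:
    img[mask] = (1.0 - alpha) * img[mask] + alpha * np.asarray(color, dtype=np.float64)


def _bbox_of(points: list[tuple[int, int]], pad: int, box) -> tuple[int, int, int, int]:
    rs = [p[0] for p in points]
    cs = [p[1] for p in points]
    r0, c0, r1, c1 = box
    return (max(min(rs) - pad, r0), max(min(cs) - pad, c0),
            min(max(rs) + pad + 1, r1), min(max(cs) + pad + 1, c1))


def _render_spot(img, box, ellipse, reject, rng, size) -> tuple[int, int, int, int]:
    n_spots = int(rng.integers(3, 7))
    radius = _fit_radius(box, max(1.5, size * float(rng.uniform(0.03, 0.05))))
    margin = int(radius) + 1
    pts = []
    for _ in range(n_spots):
        r, c = _sample_center(box, margin, ellipse, reject, rng)
        color = rng.uniform((90, 10, 30), (150, 40, 80))
        _blend(img, _disk_mask(img.shape[:2], (r, c), radius), color, 0.95)
        pts.append((r, c))
    return _bbox_of(pts, margin, box)


def _render_crack(img, box, ellipse, reject, rng, size) -> tuple[int, int, int, int]:
    margin = 3
    r, c = _sample_center(box, margin + 2, ellipse, reject, rng)
    length = max(6, int((box[2] - box[0]) * 0.9))
    color = np.array([70.0, 22.0, 32.0])
    pts = [(r, c)]
    for _ in range(length):
        r = int(np.clip(r + rng.integers(0, 2), box[0] + 1, box[2] - 2))
        c = int(np.clip(c + rng.integers(-1, 2), box[1] + 2, box[3] - 3))
        pts.append((r, c))
    for (pr, pc) in pts:
        for dc in (-1, 0, 1):
            img[pr, pc + dc] = 0.1 * img[pr, pc + dc] + 0.9 * color
    return _bbox_of(pts, 2, box)


def _render_toothmark(img, box, ellipse, reject, rng, size) -> tuple[int, int, int, int]:
    n_marks = int(rng.integers(2, 4))
    radius = _fit_radius(box, max(2.0, size * float(rng.uniform(0.03, 0.05))))
    margin = int(radius) + 1
    color = np.array([240.0, 205.0, 215.0])  # pale scalloped indentation
    pts = []
    for _ in range(n_marks):
        r, c = _sample_center(box, margin, ellipse, reject, rng)
        _blend(img, _disk_mask(img.shape[:2], (r, c), radius), color, 0.9)
        pts.append((r, c))
    return _bbox_of(pts, margin, box)


def _render_fur_patch(img, box, ellipse, reject, rng, size) -> tuple[int, int, int, int]:
    radius = _fit_radius(box, max(2.5, size * float(rng.uniform(0.06, 0.10))),
                         aspect=1.4)
    margin = (int(radius) + 1, int(radius * 1.4) + 1)
    r, c = _sample_center(box, margin, ellipse, reject, rng)
    color = rng.uniform((225, 220, 180), (248, 244, 215))
    rr = np.arange(img.shape[0])[:, None]
    cc = np.arange(img.shape[1])[None, :]
    mask = (((rr - r) / radius) ** 2 + ((cc - c) / (radius * 1.4)) ** 2) <= 1.0
    _blend(img, mask, color, 0.9)
    return _bbox_of([(r, c)], int(np.ceil(radius * 1.4)) + 1, box)


def _render_body_tint(img, box, ellipse, reject, rng, size, color
                      ) -> tuple[int, int, int, int]:
    radius = _fit_radius(box, max(2.5, size * float(rng.uniform(0.06, 0.10))))
    margin = int(radius) + 1
    r, c = _sample_center(box, margin, ellipse, reject, rng)
    _blend(img, _disk_mask(img.shape[:2], (r, c), radius), color, 0.8)
    return _bbox_of([(r, c)], margin, box)


def _render_feature(kind: str, img, box, ellipse, reject, rng, size):
    if kind == "spot":
        return _render_spot(img, box, ellipse, reject, rng, size)
    if kind == "crack":
        return _render_crack(img, box, ellipse, reject, rng, size)
    if kind == "toothmark":
        return _render_toothmark(img, box, ellipse, reject, rng, size)
    if kind == "fur_patch":
        return _render_fur_patch(img, box, ellipse, reject, rng, size)
    if kind == "red_body":
        return _render_body_tint(img, box, ellipse, reject, rng, size, (205, 60, 70))
    if kind == "pale_body":
        return _render_body_tint(img, box, ellipse, reject, rng, size, (238, 212, 218))
    raise ValueError(f"unknown feature kind {kind!r}")


def render_scene(labels: OrganLabels, spec: SceneSpec,
                 rng: np.random.Generator) -> LabeledSample:
    """Render one tongue with features planted per the unhealthy labels."""
    s = spec.image_size
    bounds = compute_bounds(s, s)
    img = np.empty((s, s, 3), dtype=np.float64)
    img[...] = np.asarray(spec.background, dtype=np.float64)

    # tongue body: vertically elongated ellipse, slight color jitter
    cy = s * float(rng.uniform(0.50, 0.54))
    cx = s * float(rng.uniform(0.48, 0.52))
    ar = s * float(rng.uniform(*spec.ellipse_row_frac))
    ac = s * float(rng.uniform(*spec.ellipse_col_frac))
    base = np.asarray(spec.tongue_color, dtype=np.float64) + rng.uniform(
        -spec.color_jitter, spec.color_jitter, 3)
    rr = np.arange(s)[:, None]
    cc = np.arange(s)[None, :]
    body = ((rr - cy) / ar) ** 2 + ((cc - cx) / ac) ** 2 <= 1.0
    img[body] = base
    # faint central coating, a normal tongue trait
    coat = ((rr - cy) / (ar * 0.75)) ** 2 + ((cc - cx) / (ac * 0.6)) ** 2 <= 1.0
    _blend(img, coat, base * 0.92 + np.array([18.0, 22.0, 18.0]), 0.35)

    ellipse = (cy, cx, ar, ac)
    ledger: list[FeaturePlacement] = []
    for organ in ORGANS:
        if getattr(labels, organ) != 1:
            continue
        boxes, reject = _organ_box(organ, bounds, spec.placement)
        menu = spec.menus[organ]
        n_feat = int(rng.integers(1, 3))
        for _ in range(n_feat):
            kind = menu[int(rng.integers(0, len(menu)))]
            box = boxes[int(rng.integers(0, len(boxes)))]
            bbox = _render_feature(kind, img, box, ellipse, reject, rng, s)
            ledger.append(FeaturePlacement(kind=kind, organ=organ, bbox=bbox))

    if spec.noise_std > 0:
        img += rng.normal(0.0, spec.noise_std, img.shape)
    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return LabeledSample(image=image, labels=labels, ledger=tuple(ledger))


def generate_cohort(cohort: CohortSpec, spec: SceneSpec, out_dir: str | Path,
                    write_ledgers: bool = False) -> pd.DataFrame:
    """Render a full cohort to ``out_dir`` (PNGs + CSV manifest).

    The manifest has columns ``filename,heart,lung,liver,spleen,kidney,split``
    and is written to ``out_dir/manifest.csv``.  Split assignment is
    sequential: the first ``n_train`` samples are ``train``, then ``val``,
    then ``test``.  Returns the manifest as a DataFrame.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cohort.seed)
    labels = sample_labels(cohort, rng)
    n_train, n_val, n_test = cohort.effective_splits
    if n_train + n_val + n_test != cohort.n:
        raise ValueError("split counts must sum to n")
    split_col = (["train"] * n_train + ["val"] * n_val + ["test"] * n_test)

    rows = []
    for i in range(cohort.n):
        sample = render_scene(OrganLabels.from_array(labels[i]), spec, rng)
        fname = f"tongue_{i:05d}.png"
        save_rgb(sample.image, out / fname)
        if write_ledgers:
            payload = [{"kind": f.kind, "organ": f.organ, "bbox": list(f.bbox)}
                       for f in sample.ledger]
            (out / f"tongue_{i:05d}.ledger.json").write_text(json.dumps(payload))
        rows.append({"filename": fname,
                     **{o: int(labels[i, j]) for j, o in enumerate(ORGANS)},
                     "split": split_col[i]})
    manifest = pd.DataFrame(rows, columns=["filename", *ORGANS, "split"])
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def generate_cohort_arrays(cohort: CohortSpec, spec: SceneSpec
                           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """In-memory cohort: (images uint8 (n,S,S,3), labels (n,5), split names)."""
    rng = np.random.default_rng(cohort.seed)
    labels = sample_labels(cohort, rng)
    n_train, n_val, n_test = cohort.effective_splits
    splits = np.array(["train"] * n_train + ["val"] * n_val + ["test"] * n_test)
    images = np.empty((cohort.n, spec.image_size, spec.image_size, 3), dtype=np.uint8)
    for i in range(cohort.n):
        images[i] = render_scene(OrganLabels.from_array(labels[i]), spec, rng).image
    return images, labels, splits
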