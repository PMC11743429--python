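"""Training, evaluation, ablation, and Grad-CAM inspection.

Training jointly supervises all ten head outputs (five full-path, five
region-path) with the asymmetric loss; average-voting fusion is applied only
at inference.  Horizontal-flip augmentation is applied to the *source image*
conceptually before partitioning; because every region crop flips into the
mirrored crop of the flipped image (with the two margin strips swapping
places inside the concatenated B crop), this is implemented as a width flip
of each precomputed branch input.

The ablation protocol trains, under one shared configuration: a full-image
baseline (one backbone, four heads), the four single-region networks, and
the fused OrganNet, then evaluates each on the test split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .images import load_rgb, resize_rgb, to_float
from .losses import ASLConfig, asl_grad, _asl_elementwise
from .metrics import MetricsReport, ORGANS, build_report
from .model import (
    BRANCHES, ORGANS_OF_REGION, REGION_OF_ORGAN, Branch, OrganNet,
    OrganNetConfig,
)
from .regions import RegionBounds, partition, region_masks

__all__ = [
    "TrainConfig", "TongueDataset", "CAMMap", "AblationTable",
    "SingleBranchModel", "train", "evaluate", "run_ablation",
    "gradcam", "cam_region_mass", "prepare_branch_inputs",
]

ABLATION_ROWS = ("full_image", "region_A", "region_B", "region_C",
                 "region_D", "organnet")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (AdamW with decoupled weight decay)."""

    learning_rate: float = 5e-4
    batch_size: int = 64
    epochs: int = 10
    weight_decay: float = 1e-2
    augment_hflip: bool = True
    input_size: int = 224
    seed: int = 0
    loss: ASLConfig = field(default_factory=ASLConfig)

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning rate must be >= 0")
        if self.batch_size < 1 or self.epochs < 0:
            raise ValueError("batch_size >= 1 and epochs >= 0 required")

    @classmethod
    def small(cls, **kw) -> "TrainConfig":
        """CPU test-scale preset: 64x64 inputs, short schedule, higher LR.

        The small backbone trains for only a few hundred optimizer steps at
        desk scale, so the preset uses a larger learning rate than the
        study-scale default.
        """
        kw.setdefault("input_size", 64)
        kw.setdefault("epochs", 8)
        kw.setdefault("learning_rate", 2e-3)
        return cls(**kw)


@dataclass
class TongueDataset:
    """In-memory image cohort with labels and split assignment."""

    images: np.ndarray                 # (n, H, W, 3) uint8
    labels: np.ndarray                 # (n, 5) binary
    splits: np.ndarray                 # (n,) of {"train","val","test"}

    def __post_init__(self) -> None:
        if len(self.images) != len(self.labels) or len(self.images) != len(self.splits):
            raise ValueError("images, labels and splits must have equal length")
        if len(self.images) == 0:
            raise ValueError("dataset is empty")
        if self.labels.ndim != 2 or self.labels.shape[1] != len(ORGANS):
            raise ValueError("labels must be an n x 5 matrix")

    def __len__(self) -> int:
        return len(self.images)

    def subset(self, split: str) -> "TongueDataset":
        mask = self.splits == split
        if not mask.any():
            raise ValueError(f"no samples in split {split!r}")
        return TongueDataset(self.images[mask], self.labels[mask], self.splits[mask])

    @classmethod
    def from_directory(cls, directory: str | Path) -> "TongueDataset":
        """Load PNG/JPEG images listed in ``directory/manifest.csv``."""
        directory = Path(directory)
        manifest = pd.read_csv(directory / "manifest.csv")
        images = np.stack([load_rgb(directory / f) for f in manifest["filename"]])
        labels = manifest[list(ORGANS)].to_numpy(dtype=np.int64)
        return cls(images, labels, manifest["split"].to_numpy())


def prepare_branch_inputs(images: np.ndarray, input_size: int,
                          branches: tuple[str, ...] = BRANCHES
                          ) -> dict[str, np.ndarray]:
    """Partition + resize every image into the requested branch input tensors."""
    out = {b: np.empty((len(images), 3, input_size, input_size), dtype=np.float32)
           for b in branches}
    need_parts = any(b != "full" for b in branches)
    for i, img in enumerate(images):
        crops = {"full": img}
        if need_parts:
            parts = partition(img)
            crops.update({"A": parts.region_A, "B": parts.region_B,
                          "C": parts.region_C, "D": parts.region_D})
        for b in branches:
            arr = to_float(resize_rgb(crops[b], (input_size, input_size)))
            out[b][i] = arr.transpose(2, 0, 1)
    return out


class SingleBranchModel:
    """One backbone + head(s): the full-image baseline or a region network.

    ``branch_name`` is ``"full"`` (predicts all five organs through four
    heads) or a region letter (predicts that region's organs only).  Scores
    are thresholded directly — no fusion.
    """

    def __init__(self, branch_name: str, config: OrganNetConfig,
                 seed: int = 0) -> None:
        if branch_name not in BRANCHES:
            raise ValueError(f"unknown branch {branch_name!r}")
        self.config = config
        self.branch_name = branch_name
        rng = np.random.default_rng(seed)
        self.branches = {branch_name: Branch(branch_name, config, rng)}

    @property
    def organs(self) -> tuple[str, ...]:
        if self.branch_name == "full":
            return ORGANS
        return ORGANS_OF_REGION[self.branch_name]

    def params(self) -> list[nn.Param]:
        return self.branches[self.branch_name].params()

    def train(self, mode: bool = True) -> None:
        self.branches[self.branch_name].train(mode)

    def eval(self) -> None:
        self.train(False)


def _organ_columns(labels: np.ndarray) -> dict[str, np.ndarray]:
    return {o: labels[:, i] for i, o in enumerate(ORGANS)}


def _branch_loss_and_grads(branch: Branch, x: np.ndarray, labels: np.ndarray,
                           loss_cfg: ASLConfig) -> float:
    """Forward + backward one branch on one batch; returns summed head loss."""
    logits = branch.forward_train(x)
    cols = _organ_columns(labels)
    n = x.shape[0]
    dlogits = {}
    total = 0.0
    for region, z in logits.items():
        y = np.stack([cols[o] for o in ORGANS_OF_REGION[region]], axis=1)
        p = nn.sigmoid(z)
        total += float(_asl_elementwise(p, y.astype(np.float64), loss_cfg).sum()) / n
        dp = asl_grad(p, y, loss_cfg)
        dlogits[region] = ((dp * p * (1.0 - p)) / n).astype(np.float32)
    branch.backward(dlogits)
    return total


def train(model: OrganNet | SingleBranchModel, dataset: TongueDataset,
          config: TrainConfig) -> list[float]:
    """Optimize the asymmetric loss over all of the model's head outputs.

    Returns the per-epoch mean training loss (sum over heads, mean over
    samples).  Fully seeded: same data/config/seed gives identical histories.
    """
    train_split = dataset.subset("train") if "train" in dataset.splits else dataset
    inputs = prepare_branch_inputs(train_split.images, config.input_size,
                                   branches=tuple(model.branches))
    labels = train_split.labels
    n = len(train_split)
    rng = np.random.default_rng(config.seed)
    params = model.params()
    opt = nn.AdamW(params, lr=config.learning_rate,
                   weight_decay=config.weight_decay)
    model.train(True)
    history: list[float] = []
    branch_names = list(model.branches)
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            flip = (rng.random(len(idx)) < 0.5) if config.augment_hflip else None
            opt.zero_grad()
            batch_loss = 0.0
            for bname in branch_names:
                x = inputs[bname][idx]
                if flip is not None and flip.any():
                    x = x.copy()
                    x[flip] = x[flip][..., ::-1]
                batch_loss += _branch_loss_and_grads(
                    model.branches[bname], x, labels[idx], config.loss)
            opt.step()
            epoch_loss += batch_loss
            n_batches += 1
        history.append(epoch_loss / max(n_batches, 1))
    model.eval()
    return history


def _batched_probs(model: OrganNet | SingleBranchModel,
                   inputs: dict[str, np.ndarray], n: int,
                   batch_size: int = 256) -> dict[str, np.ndarray]:
    """Per-organ fused (OrganNet) or direct (single-branch) probabilities."""
    model.eval()
    probs = {o: np.empty(n) for o in ORGANS}
    covered = model.organs if isinstance(model, SingleBranchModel) else ORGANS
    for start in range(0, n, batch_size):
        sl = slice(start, min(start + batch_size, n))
        if isinstance(model, SingleBranchModel):
            branch = model.branches[model.branch_name]
            logits = branch.forward_train(inputs[model.branch_name][sl])
            for region, z in logits.items():
                for j, organ in enumerate(ORGANS_OF_REGION[region]):
                    probs[organ][sl] = nn.sigmoid(z[:, j])
        else:
            full_logits = model.branches["full"].forward_train(inputs["full"][sl])
            for region in ("A", "B", "C", "D"):
                z_region = model.branches[region].forward_train(inputs[region][sl])[region]
                z_full = full_logits[region]
                for j, organ in enumerate(ORGANS_OF_REGION[region]):
                    p_pair = (nn.sigmoid(z_full[:, j]) + nn.sigmoid(z_region[:, j])) / 2.0
                    probs[organ][sl] = p_pair
    return {o: probs[o] for o in covered}


def evaluate(model: OrganNet | SingleBranchModel, dataset: TongueDataset,
             threshold: float = 0.5) -> MetricsReport:
    """Forward + fuse + predict every sample; per-organ confusion metrics."""
    size = model.config.input_size
    inputs = prepare_branch_inputs(dataset.images, size,
                                   branches=tuple(model.branches))
    probs = _batched_probs(model, inputs, len(dataset))
    organs = tuple(probs)
    pred = np.stack([probs[o] > threshold for o in organs], axis=1).astype(np.int64)
    organ_idx = [ORGANS.index(o) for o in organs]
    truth = dataset.labels[:, organ_idx]
    return build_report(pred, truth, organs=organs)


@dataclass
class AblationTable:
    """Per-organ accuracy and F1 for the six ablation configurations.

    Rows: full-image baseline, the four region networks, and OrganNet.
    Cells are NaN where a network does not predict that organ.
    """

    accuracy: pd.DataFrame
    f1: pd.DataFrame
    histories: dict[str, list[float]] = field(default_factory=dict)

    def macro_f1(self, row: str) -> float:
        return float(self.f1.loc[row].dropna().mean())


def run_ablation(dataset: TongueDataset, train_config: TrainConfig,
                 model_config: OrganNetConfig) -> AblationTable:
    """Train baseline, four region nets, and OrganNet; evaluate on test."""
    test = dataset.subset("test")
    acc = pd.DataFrame(np.nan, index=list(ABLATION_ROWS), columns=list(ORGANS))
    f1s = pd.DataFrame(np.nan, index=list(ABLATION_ROWS), columns=list(ORGANS))
    histories: dict[str, list[float]] = {}
    specs: list[tuple[str, object]] = [
        ("full_image", lambda: SingleBranchModel("full", model_config,
                                                 seed=train_config.seed)),
        *[(f"region_{r}", (lambda r=r: SingleBranchModel(r, model_config,
                                                         seed=train_config.seed)))
          for r in ("A", "B", "C", "D")],
        ("organnet", lambda: OrganNet(model_config, seed=train_config.seed)),
    ]
    for row, make in specs:
        model = make()
        histories[row] = train(model, dataset, train_config)
        report = evaluate(model, test, threshold=model_config.threshold)
        for organ in report.counts:
            acc.loc[row, organ] = report.metric(organ, "accuracy")
            f1s.loc[row, organ] = report.metric(organ, "f1")
    return AblationTable(accuracy=acc, f1=f1s, histories=histories)


# ---------------------------------------------------------------------------
# Grad-CAM


@dataclass(frozen=True)
class CAMMap:
    """A class-activation heatmap aligned to an input pixel grid."""

    heatmap: np.ndarray   # H x W floats in [0, 1]
    organ: str
    branch: str

    def __post_init__(self) -> None:
        hm = self.heatmap
        if hm.min() < 0.0 or hm.max() > 1.0:
            raise ValueError("heatmap values must lie in [0, 1]")


def _upsample_map(cam: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    from PIL import Image
    img = Image.fromarray(cam.astype(np.float32), mode="F")
    return np.asarray(img.resize((shape[1], shape[0]), Image.BILINEAR),
                      dtype=np.float64)


def gradcam(model: OrganNet | SingleBranchModel, image: np.ndarray,
            organ: str, branch: str = "full") -> CAMMap:
    """Gradient-weighted class activation map for one organ's score.

    Gradients of the organ's pre-threshold score are taken with respect to
    the branch's last convolutional feature maps; maps are weighted by their
    spatially averaged gradients, rectified, normalized to a maximum of 1
    (an identically-zero map is returned as-is), and upsampled — to the
    original image grid for the full branch, to the branch input grid for a
    region branch.
    """
    if organ not in ORGANS:
        raise ValueError(f"unknown organ {organ!r}")
    if branch != "full" and organ not in ORGANS_OF_REGION.get(branch, ()):
        raise ValueError(f"branch {branch!r} does not predict {organ!r}")
    if branch not in model.branches:
        raise ValueError(f"model has no branch {branch!r}")
    model.eval()
    size = model.config.input_size
    parts = partition(image)
    crops = {"full": image, "A": parts.region_A, "B": parts.region_B,
             "C": parts.region_C, "D": parts.region_D}
    x = to_float(resize_rgb(crops[branch], (size, size))).transpose(2, 0, 1)[None]
    br = model.branches[branch]
    br.forward_train(x.astype(np.float32))
    region = REGION_OF_ORGAN[organ] if branch == "full" else branch
    unit = ORGANS_OF_REGION[region].index(organ)
    dfeats = br.feats_grad_for(region, unit)          # (1, C)
    fmaps = br.last_fmaps                             # (1, C, h, w)
    _, c, h, w = fmaps.shape
    alpha = dfeats[0] / (h * w)                       # spatially averaged grads
    cam = np.maximum((alpha[:, None, None] * fmaps[0]).sum(axis=0), 0.0)
    peak = cam.max()
    if peak > 0:
        cam = cam / peak
    target_shape = image.shape[:2] if branch == "full" else (size, size)
    heat = np.clip(_upsample_map(cam, target_shape), 0.0, 1.0)
    if peak > 0 and heat.max() > 0:
        heat = heat / heat.max()
    return CAMMap(heatmap=heat, organ=organ, branch=branch)


def cam_region_mass(cam: CAMMap | np.ndarray, bounds: RegionBounds,
                    region: str) -> float:
    """Fraction of total heatmap mass inside one region (0 for a zero map)."""
    heat = cam.heatmap if isinstance(cam, CAMMap) else np.asarray(cam)
    if heat.shape != (bounds.height, bounds.width):
        raise ValueError(
            f"heatmap shape {heat.shape} does not match bounds "
            f"{(bounds.height, bounds.width)}")
    total = heat.sum()
    if total == 0:
        return 0.0
    mask = region_masks(bounds)[region]
    return float(heat[mask].sum() / total)
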