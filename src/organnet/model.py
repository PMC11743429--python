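"""Five-branch OrganNet: per-organ score pairs fused by average voting.

The model mirrors the TCM reading of the tongue.  One backbone sees the full
tongue image and feeds four MLP heads (tip head -> heart + lung, margin head
-> liver, center head -> spleen, root head -> kidney).  Four additional
backbones each see one region crop and feed a single head for that region's
organ(s).  No parameters are shared between blocks.  Every scalar output
passes through a logistic squashing, so each organ ends up with a
(full-path, region-path) probability pair; the final per-organ score is their
arithmetic mean (average voting over N = 2 paths) and the decision rule is
the strict threshold ``score > 0.5``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .images import resize_rgb, to_float
from .regions import partition

__all__ = [
    "ORGANS", "BRANCHES", "REGION_OF_ORGAN", "ORGANS_OF_REGION",
    "OrganNetConfig", "OrganLabels", "ScorePair", "OrganScores",
    "Branch", "OrganNet", "build_organnet", "forward", "fuse", "predict",
    "save_checkpoint", "load_checkpoint",
]

ORGANS = ("heart", "lung", "liver", "spleen", "kidney")
REGION_OF_ORGAN = {"heart": "A", "lung": "A", "liver": "B", "spleen": "C", "kidney": "D"}
ORGANS_OF_REGION = {"A": ("heart", "lung"), "B": ("liver",), "C": ("spleen",), "D": ("kidney",)}
BRANCHES = ("full", "A", "B", "C", "D")

CHECKPOINT_VERSION = 1


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class OrganNetConfig:
    """Architecture configuration.

    ``backbone_name`` selects the convolutional feature extractor used by all
    five branches: ``"resnet101"`` (the default, a 101-layer bottleneck
    residual network), ``"resnet50"``, or ``"small"`` — a three-conv CPU-scale
    backbone intended for 64x64 inputs and fast experiments/tests.
    """

    backbone_name: str = "resnet101"
    input_size: int = 224
    head_hidden_dims: tuple[int, ...] = (64,)
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.input_size < 32:
            raise ConfigurationError("input_size must be >= 32")
        if not (0.0 < self.threshold < 1.0):
            raise ConfigurationError("threshold must lie in (0, 1)")
        if self.backbone_name not in _BACKBONES:
            raise ConfigurationError(
                f"unknown backbone {self.backbone_name!r}; "
                f"available: {sorted(_BACKBONES)}"
            )

    @classmethod
    def small(cls, **kw) -> "OrganNetConfig":
        """CPU test-scale preset: small backbone on 64x64 inputs."""
        kw.setdefault("backbone_name", "small")
        kw.setdefault("input_size", 64)
        kw.setdefault("head_hidden_dims", (32,))
        return cls(**kw)


@dataclass(frozen=True)
class OrganLabels:
    """Binary status per organ in canonical order; 0 healthy, 1 unhealthy."""

    heart: int
    lung: int
    liver: int
    spleen: int
    kidney: int

    def __post_init__(self) -> None:
        for organ in ORGANS:
            if getattr(self, organ) not in (0, 1):
                raise ValueError(f"{organ} label must be 0 or 1")

    @classmethod
    def from_array(cls, arr) -> "OrganLabels":
        arr = np.asarray(arr).ravel()
        return cls(*(int(v) for v in arr))

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, o) for o in ORGANS], dtype=np.int64)


@dataclass(frozen=True)
class ScorePair:
    """Per-organ probabilities from the full-image path and the region path."""

    full_path: float
    region_path: float

    def __post_init__(self) -> None:
        for v in (self.full_path, self.region_path):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"score {v} outside [0, 1]")


@dataclass(frozen=True)
class OrganScores:
    """Fused per-organ probabilities in canonical order."""

    fused: tuple[float, float, float, float, float]

    def __post_init__(self) -> None:
        for v in self.fused:
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"fused score {v} outside [0, 1]")


def fuse(pair: ScorePair) -> float:
    """Average voting over the two prediction paths (N = 2)."""
    return (pair.full_path + pair.region_path) / 2.0


def predict(scores: OrganScores, threshold: float = 0.5) -> OrganLabels:
    """Strict decision rule: unhealthy iff fused score > threshold."""
    return OrganLabels(*(int(s > threshold) for s in scores.fused))


# ---------------------------------------------------------------------------
# backbones


def _small_backbone(rng: np.random.Generator) -> tuple[nn.Sequential, int]:
    stack = nn.Sequential(
        nn.Conv2d(3, 8, 3, stride=2, pad=1, rng=rng), nn.ReLU(),
        nn.Conv2d(8, 16, 3, stride=2, pad=1, rng=rng), nn.ReLU(),
        nn.Conv2d(16, 32, 3, stride=2, pad=1, rng=rng), nn.ReLU(),
    )
    return stack, 32


def _resnet_backbone(depths: tuple[int, ...], rng: np.random.Generator
                     ) -> tuple[nn.Sequential, int]:
    layers: list[nn.Layer] = [
        nn.Conv2d(3, 64, 7, stride=2, pad=3, rng=rng, bias=False),
        nn.BatchNorm2d(64), nn.ReLU(), nn.MaxPool2d(3, 2, 1),
    ]
    c_in = 64
    for stage, blocks in enumerate(depths):
        c_mid = 64 * 2 ** stage
        c_out = c_mid * 4
        for b in range(blocks):
            stride = 2 if (stage > 0 and b == 0) else 1
            layers.append(nn.Bottleneck(c_in, c_mid, c_out, stride=stride, rng=rng))
            c_in = c_out
    return nn.Sequential(*layers), c_in


_BACKBONES = {
    "small": _small_backbone,
    "resnet50": lambda rng: _resnet_backbone((3, 4, 6, 3), rng),
    "resnet101": lambda rng: _resnet_backbone((3, 4, 23, 3), rng),
}


def _build_head(d_in: int, hidden: tuple[int, ...], d_out: int,
                rng: np.random.Generator) -> nn.Sequential:
    layers: list[nn.Layer] = []
    cur = d_in
    for h in hidden:
        layers += [nn.Linear(cur, h, rng=rng), nn.ReLU()]
        cur = h
    layers.append(nn.Linear(cur, d_out, rng=rng))
    return nn.Sequential(*layers)


class Branch:
    """One backbone plus its head(s).

    The ``full`` branch owns four heads (one per region); a region branch
    owns a single head for its own region.  ``forward_train`` caches
    activations so ``backward`` can push logit gradients through the heads,
    the global average pool, and the conv stack.
    """

    def __init__(self, name: str, config: OrganNetConfig,
                 rng: np.random.Generator) -> None:
        self.name = name
        self.stack, feat_dim = _BACKBONES[config.backbone_name](rng)
        self.gap = nn.GlobalAvgPool()
        regions = ("A", "B", "C", "D") if name == "full" else (name,)
        self.heads = {
            r: _build_head(feat_dim, config.head_hidden_dims,
                           len(ORGANS_OF_REGION[r]), rng)
            for r in regions
        }
        self.feat_dim = feat_dim
        self._fmaps: np.ndarray | None = None

    def params(self) -> list[nn.Param]:
        ps = self.stack.params()
        for r in sorted(self.heads):
            ps += self.heads[r].params()
        return ps

    def train(self, mode: bool = True) -> None:
        self.stack.train(mode)
        for head in self.heads.values():
            head.train(mode)

    def forward_train(self, x: np.ndarray) -> dict[str, np.ndarray]:
        """Run a batch, returning per-region logit matrices (N, n_organs)."""
        fmaps = self.stack.forward(x)
        self._fmaps = fmaps
        feats = self.gap.forward(fmaps)
        return {r: head.forward(feats) for r, head in self.heads.items()}

    def backward(self, dlogits: dict[str, np.ndarray]) -> None:
        dfeats = None
        for r, head in self.heads.items():
            d = head.backward(dlogits[r])
            dfeats = d if dfeats is None else dfeats + d
        self.stack.backward(self.gap.backward(dfeats))

    @property
    def last_fmaps(self) -> np.ndarray:
        """Last convolutional feature maps cached by the previous forward."""
        if self._fmaps is None:
            raise RuntimeError("run a forward pass first")
        return self._fmaps

    def feats_grad_for(self, region: str, unit: int) -> np.ndarray:
        """d(logit)/d(pooled features) for one head output unit.

        Recomputes the head backward with a one-hot upstream gradient; the
        parameter gradients this touches are zeroed again afterwards.
        """
        head = self.heads[region]
        n = self._fmaps.shape[0]
        onehot = np.zeros((n, len(ORGANS_OF_REGION[region])), dtype=np.float32)
        onehot[:, unit] = 1.0
        dfeats = head.backward(onehot)
        for p in head.params():
            p.zero_grad()
        return dfeats


class OrganNet:
    """The full five-branch model (see module docstring)."""

    def __init__(self, config: OrganNetConfig, seed: int = 0) -> None:
        self.config = config
        rng = np.random.default_rng(seed)
        self.branches = {name: Branch(name, config, rng) for name in BRANCHES}

    def params(self) -> list[nn.Param]:
        return [p for name in BRANCHES for p in self.branches[name].params()]

    def train(self, mode: bool = True) -> None:
        for br in self.branches.values():
            br.train(mode)

    def eval(self) -> None:
        self.train(False)

    # -- inference ---------------------------------------------------------

    def branch_inputs(self, image: np.ndarray) -> dict[str, np.ndarray]:
        """Partition + resize one image into the five branch input tensors."""
        size = self.config.input_size
        parts = partition(image)
        crops = {"full": image, "A": parts.region_A, "B": parts.region_B,
                 "C": parts.region_C, "D": parts.region_D}
        out = {}
        for name, crop in crops.items():
            arr = to_float(resize_rgb(crop, (size, size)))
            out[name] = arr.transpose(2, 0, 1)[None].astype(np.float32)
        return out

    def score_pairs(self, inputs: dict[str, np.ndarray]) -> list[ScorePair]:
        """Per-organ (full-path, region-path) probabilities for a batch of 1."""
        full_logits = self.branches["full"].forward_train(inputs["full"])
        region_logits = {r: self.branches[r].forward_train(inputs[r])[r]
                         for r in ("A", "B", "C", "D")}
        pairs = []
        for organ in ORGANS:
            region = REGION_OF_ORGAN[organ]
            unit = ORGANS_OF_REGION[region].index(organ)
            p_full = float(nn.sigmoid(full_logits[region][0, unit]))
            p_region = float(nn.sigmoid(region_logits[region][0, unit]))
            pairs.append(ScorePair(p_full, p_region))
        return pairs


def build_organnet(config: OrganNetConfig | None = None, seed: int = 0) -> OrganNet:
    """Construct an OrganNet with disjoint per-branch parameter sets."""
    return OrganNet(config or OrganNetConfig(), seed=seed)


def forward(model: OrganNet, image: np.ndarray) -> list[ScorePair]:
    """Partition ``image``, run all five branches, return 5 score pairs."""
    model.eval()
    return model.score_pairs(model.branch_inputs(image))


# ---------------------------------------------------------------------------
# checkpoints


def _iter_bn(layer: nn.Layer):
    if isinstance(layer, nn.BatchNorm2d):
        yield layer
    if isinstance(layer, nn.Sequential):
        for sub in layer.layers:
            yield from _iter_bn(sub)
    if isinstance(layer, nn.Bottleneck):
        yield from _iter_bn(layer.main)
        if layer.proj is not None:
            yield from _iter_bn(layer.proj)


def _model_buffers(model: OrganNet) -> list[np.ndarray]:
    bufs = []
    for name in BRANCHES:
        for bn in _iter_bn(model.branches[name].stack):
            bufs += [bn.running_mean, bn.running_var]
    return bufs


def save_checkpoint(model: OrganNet, path: str | Path) -> None:
    """Single-file versioned checkpoint (npz with a JSON header)."""
    cfg = model.config
    header = {
        "version": CHECKPOINT_VERSION,
        "backbone_name": cfg.backbone_name,
        "input_size": cfg.input_size,
        "head_hidden_dims": list(cfg.head_hidden_dims),
        "threshold": cfg.threshold,
    }
    arrays = {f"param_{i}": p.data for i, p in enumerate(model.params())}
    arrays.update({f"buffer_{i}": b for i, b in enumerate(_model_buffers(model))})
    np.savez(path, header=json.dumps(header), **arrays)


def load_checkpoint(path: str | Path) -> OrganNet:
    with np.load(path, allow_pickle=False) as data:
        header = json.loads(str(data["header"]))
        if header["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {header['version']}")
        config = OrganNetConfig(
            backbone_name=header["backbone_name"],
            input_size=header["input_size"],
            head_hidden_dims=tuple(header["head_hidden_dims"]),
            threshold=header["threshold"],
        )
        model = OrganNet(config)
        for i, p in enumerate(model.params()):
            p.data = data[f"param_{i}"].astype(np.float32)
            p.grad = np.zeros_like(p.data)
        bufs = _model_buffers(model)
        for i, b in enumerate(bufs):
            b[...] = data[f"buffer_{i}"]
    return model
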