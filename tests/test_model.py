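"""OrganNet structure, fusion, decision rule, routing, checkpoints."""

import numpy as np
import pytest

from organnet.model import (
    ORGANS, OrganLabels, OrganNet, OrganNetConfig, OrganScores, ScorePair,
    build_organnet, forward, fuse, load_checkpoint, predict, save_checkpoint,
)
from organnet.model import ConfigurationError
import organnet.nn as nn


@pytest.fixture(scope="module")
def small_net():
    return build_organnet(OrganNetConfig.small(), seed=0)


@pytest.fixture(scope="module")
def tongue_image():
    from organnet.synth import SceneSpec, render_scene
    sample = render_scene(OrganLabels(1, 0, 1, 0, 1), SceneSpec(image_size=64),
                          np.random.default_rng(4))
    return sample.image


def test_config_validation():
    with pytest.raises(ConfigurationError):
        OrganNetConfig(backbone_name="alexnet")
    with pytest.raises(ConfigurationError):
        OrganNetConfig(input_size=16)
    with pytest.raises(ConfigurationError):
        OrganNetConfig(threshold=1.0)


def test_parameter_sets_disjoint(small_net):
    """No weight sharing between any two blocks (backbones or heads)."""
    ids_by_branch = {name: {id(p) for p in br.params()}
                     for name, br in small_net.branches.items()}
    names = list(ids_by_branch)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            assert not (ids_by_branch[a] & ids_by_branch[b])
    full = small_net.branches["full"]
    head_ids = [{id(p) for p in h.params()} for h in full.heads.values()]
    for i, a in enumerate(head_ids):
        for b in head_ids[i + 1:]:
            assert not (a & b)


def test_head_output_counts(small_net):
    """5 full-path + 5 region-path scalar outputs across all heads."""
    def head_outputs(branch):
        return sum(h.layers[-1].b.data.shape[0] for h in branch.heads.values())
    total = sum(head_outputs(br) for br in small_net.branches.values())
    assert total == 10
    assert head_outputs(small_net.branches["full"]) == 5
    assert head_outputs(small_net.branches["A"]) == 2


def test_build_deterministic():
    m1 = build_organnet(OrganNetConfig.small(), seed=3)
    m2 = build_organnet(OrganNetConfig.small(), seed=3)
    for p1, p2 in zip(m1.params(), m2.params()):
        assert (p1.data == p2.data).all()


def test_forward_returns_five_probability_pairs(small_net, tongue_image):
    pairs = forward(small_net, tongue_image)
    assert len(pairs) == 5
    for pair in pairs:
        assert 0.0 <= pair.full_path <= 1.0
        assert 0.0 <= pair.region_path <= 1.0


def test_forward_deterministic(small_net, tongue_image):
    p1 = forward(small_net, tongue_image)
    p2 = forward(small_net, tongue_image.copy())
    assert p1 == p2


def test_zeroed_final_layers_give_half(tongue_image):
    model = build_organnet(OrganNetConfig.small(), seed=0)
    for br in model.branches.values():
        for head in br.heads.values():
            last = head.layers[-1]
            last.w.data[...] = 0.0
            last.b.data[...] = 0.0
    pairs = forward(model, tongue_image)
    for pair in pairs:
        assert pair.full_path == pytest.approx(0.5)
        assert pair.region_path == pytest.approx(0.5)


def test_fuse_examples_and_properties():
    assert fuse(ScorePair(0.6, 0.8)) == pytest.approx(0.7)
    assert fuse(ScorePair(0.0, 1.0)) == pytest.approx(0.5)
    for p in (0.0, 0.3, 1.0):
        assert fuse(ScorePair(p, p)) == p
    a, b = 0.21, 0.77
    assert fuse(ScorePair(a, b)) == fuse(ScorePair(b, a))
    assert min(a, b) <= fuse(ScorePair(a, b)) <= max(a, b)
    with pytest.raises(ValueError):
        ScorePair(1.2, 0.5)


def test_predict_strict_threshold():
    scores = OrganScores((0.7, 0.4, 0.5, 0.51, 0.0))
    assert predict(scores, 0.5).as_array().tolist() == [1, 0, 0, 1, 0]
    assert predict(OrganScores((1.0,) * 5)).as_array().tolist() == [1] * 5
    assert predict(OrganScores((0.1, 0.2, 0.3, 0.4, 0.5)), 0.0).as_array().tolist() == [1] * 5


def test_region_routing(small_net, tongue_image):
    """Perturbing one region's crop moves only that region's organ scores."""
    inputs = small_net.branch_inputs(tongue_image)
    small_net.eval()
    base = small_net.score_pairs(inputs)
    for region, affected in (("C", ["spleen"]), ("B", ["liver"]),
                             ("D", ["kidney"]), ("A", ["heart", "lung"])):
        perturbed = {k: v.copy() for k, v in inputs.items()}
        perturbed[region] = np.clip(perturbed[region] + 0.25, 0, 1)
        got = small_net.score_pairs(perturbed)
        for i, organ in enumerate(ORGANS):
            assert got[i].full_path == pytest.approx(base[i].full_path)
            if organ in affected:
                assert got[i].region_path != pytest.approx(base[i].region_path)
            else:
                assert got[i].region_path == pytest.approx(base[i].region_path)


def test_labels_validation():
    with pytest.raises(ValueError):
        OrganLabels(2, 0, 0, 0, 0)
    labels = OrganLabels.from_array(np.array([1, 0, 1, 0, 1]))
    assert labels.as_array().tolist() == [1, 0, 1, 0, 1]


def test_checkpoint_roundtrip(tmp_path, tongue_image):
    model = build_organnet(OrganNetConfig.small(), seed=9)
    before = forward(model, tongue_image)
    path = tmp_path / "model.npz"
    save_checkpoint(model, path)
    restored = load_checkpoint(path)
    assert restored.config == model.config
    after = forward(restored, tongue_image)
    for a, b in zip(before, after):
        assert a.full_path == pytest.approx(b.full_path, abs=1e-6)
        assert a.region_path == pytest.approx(b.region_path, abs=1e-6)


def test_resnet_backbone_is_constructible():
    """The residual backbone builds with bottleneck stages and disjoint params."""
    from organnet.model import _resnet_backbone
    rng = np.random.default_rng(0)
    stack, feat_dim = _resnet_backbone((1, 1, 1, 1), rng)  # depth-scaled variant
    assert feat_dim == 2048
    x = rng.random((1, 3, 64, 64)).astype(np.float32)
    stack.train(False)
    out = stack.forward(x)
    assert out.shape[1] == 2048
    n_bottlenecks = sum(isinstance(l, nn.Bottleneck) for l in stack.layers)
    assert n_bottlenecks == 4
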