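"""Network architecture, Jaccard loss, gradients, and training behaviour."""

import numpy as np
import pytest

from epiwatershed.metrics import iou
from epiwatershed.nn.model import (
    ModelSpec,
    TrainedModel,
    build_model,
    jaccard_loss,
    jaccard_loss_grad,
    tiny_spec,
)
from epiwatershed.nn.train import TrainConfig, train
from epiwatershed.targets import TargetStack


def micro_spec(seed=0):
    return ModelSpec(
        encoder="tiny", input_tile=32, width_multiplier=0.0625, rng_seed=seed
    )


def test_forward_shape_and_range():
    m = build_model(tiny_spec(64, rng_seed=0))
    out = m.predict(np.random.default_rng(0).random((64, 64)))
    assert out.shape == (7, 64, 64)
    assert out.min() >= 0 and out.max() <= 1


def test_paper_scale_spec_shape():
    spec = ModelSpec(encoder="vgg16_style", input_tile=256)
    assert spec.stage_widths == (64, 128, 256, 512, 512)
    assert spec.input_tile % 32 == 0


def test_tile_not_divisible_by_32_rejected():
    with pytest.raises(ValueError, match="32"):
        ModelSpec(input_tile=100)
    with pytest.raises(ValueError):
        ModelSpec(out_channels=5)


def test_same_seed_identical_initial_predictions():
    x = np.random.default_rng(1).random((32, 32))
    a = build_model(micro_spec(3)).predict(x)
    b = build_model(micro_spec(3)).predict(x)
    c = build_model(micro_spec(4)).predict(x)
    assert np.array_equal(a, b)
    assert not np.array_equal(a, c)


# ------------------------------------------------------------------- loss
def test_jaccard_loss_identity_and_disjoint():
    y = (np.random.default_rng(0).random((1, 7, 16, 16)) > 0.5).astype(float)
    assert jaccard_loss(y, y, eps=1.0) < 1e-6
    assert jaccard_loss(y, 1 - y, eps=1e-9) > 0.999


def test_jaccard_loss_hand_computed_value():
    """100 positives, uniform 0.5 prediction on a 100-px channel:
    J = 50/(100+50-50) = 0.5, per-channel contribution 0.5."""
    y = np.zeros((1, 7, 10, 10))
    y[0, 0] = 1.0  # channel 0 fully positive: 100 px
    p = np.zeros((1, 7, 10, 10))
    p[0, 0] = 0.5
    eps = 1e-12
    loss = jaccard_loss(y, p, eps=eps)
    # channel 0 scores J=0.5; empty channels score ~1 (eps/eps)
    assert loss == pytest.approx(1 - (0.5 + 6 * 1.0) / 7, abs=1e-6)


def test_jaccard_loss_matches_metrics_iou_on_binary():
    rng = np.random.default_rng(5)
    for _ in range(100):
        y = rng.random((1, 1, 12, 12)) > 0.5
        p = rng.random((1, 1, 12, 12)) > 0.5
        if not (y.any() or p.any()):
            continue
        loss = jaccard_loss(y.astype(float), p.astype(float), eps=1e-12)
        assert loss == pytest.approx(1 - iou(y[0, 0], p[0, 0]), abs=1e-9)


def test_loss_gradient_matches_finite_differences():
    rng = np.random.default_rng(6)
    y = (rng.random((1, 7, 8, 8)) > 0.6).astype(float)
    p = rng.random((1, 7, 8, 8))
    g = jaccard_loss_grad(y, p, eps=1.0)
    eps = 1e-5
    for idx in [(0, 0, 2, 3), (0, 3, 5, 5), (0, 6, 0, 0)]:
        p1 = p.copy(); p1[idx] += eps
        p2 = p.copy(); p2[idx] -= eps
        num = (jaccard_loss(y, p1) - jaccard_loss(y, p2)) / (2 * eps)
        assert g[idx] == pytest.approx(num, rel=1e-4, abs=1e-9)


def test_model_gradient_check_directional():
    """Directional finite difference along the analytic gradient agrees."""
    m = build_model(micro_spec())
    rng = np.random.default_rng(1)
    x = rng.random((2, 1, 32, 32)).astype(np.float32)
    y = (rng.random((2, 7, 32, 32)) > 0.7).astype(np.float32)
    p = m.forward(x, train=True)
    m.backward(jaccard_loss_grad(y, p))
    name, val, grad = next(iter(m.parameters()))
    d = (grad / (np.linalg.norm(grad) + 1e-12)).astype(np.float32)
    analytic = float((grad * d).sum())
    eps = 1e-4
    orig = val.copy()
    val[...] = orig + eps * d
    lp = jaccard_loss(y, m.forward(x, train=True))
    val[...] = orig - eps * d
    lm = jaccard_loss(y, m.forward(x, train=True))
    val[...] = orig
    numeric = (lp - lm) / (2 * eps)
    assert numeric == pytest.approx(analytic, rel=0.05)


# --------------------------------------------------------------- training
def make_toy_dataset(n=6, tile=32, seed=0):
    """Trivially learnable task: boundary where the image is bright."""
    rng = np.random.default_rng(seed)
    data = []
    for _ in range(n):
        img = np.zeros((tile, tile))
        col = int(rng.integers(4, tile - 4))
        img[:, col] = 1.0
        ch = np.zeros((7, tile, tile))
        ch[0, :, col] = 1.0
        ch[1] = ch[0]
        ch[2] = ch[0]
        ch[3] = 1 - ch[1]
        ch[4] = 1 - ch[2]
        ch[5, tile // 2, (col + tile // 2) % tile] = 1.0
        ch[6] = 1 - ch[5]
        data.append((img, TargetStack(ch)))
    return data


def test_training_descends_and_is_deterministic():
    data = make_toy_dataset()
    cfg = TrainConfig(epochs=12, batch_size=3, phase_split_epoch=6,
                      lr_phase1=1e-2, lr_phase2=1e-3, rng_seed=0)
    m1 = build_model(micro_spec())
    train(m1, data, cfg)
    losses1 = [h["loss"] for h in m1.history]
    assert losses1[-1] < losses1[0]
    m2 = build_model(micro_spec())
    train(m2, data, cfg)
    assert losses1 == [h["loss"] for h in m2.history]


def test_lr_schedule_recorded_in_history():
    data = make_toy_dataset(n=3)
    cfg = TrainConfig(epochs=6, batch_size=3, phase_split_epoch=3,
                      lr_phase1=1e-3, lr_phase2=1e-4, rng_seed=0)
    m = build_model(micro_spec())
    train(m, data, cfg)
    lrs = [h["lr"] for h in m.history]
    assert lrs == [1e-3] * 3 + [1e-4] * 3


def test_empty_dataset_rejected():
    with pytest.raises(ValueError, match="empty"):
        train(build_model(micro_spec()), [], TrainConfig(epochs=1, phase_split_epoch=1))


def test_checkpoint_round_trip(tmp_path):
    data = make_toy_dataset(n=3)
    m = build_model(micro_spec())
    train(m, data, TrainConfig(epochs=2, batch_size=3, phase_split_epoch=1, rng_seed=0))
    path = tmp_path / "ckpt.npz"
    m.save(path)
    m2 = TrainedModel.load(path)
    x = np.random.default_rng(0).random((32, 32))
    assert np.array_equal(m.predict(x), m2.predict(x))
    assert m2.history == m.history
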