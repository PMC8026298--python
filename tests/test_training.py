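"""Training loop, loss, and learning-rate schedule contracts."""

import numpy as np
import pytest

from vesselseg import training as T
from vesselseg.autodiff import Tensor
from vesselseg.network import NetworkConfig, build_network
from vesselseg.phantoms import PhantomConfig, generate_dataset


# -- poly schedule ------------------------------------------------------------

def test_poly_lr_boundary_and_midpoint_closed_form():
    cfg = T.TrainConfig(lr0=1e-3, max_epochs=200, power=0.9)
    assert T.poly_lr(0, cfg) == pytest.approx(1e-3, abs=1e-15)
    assert T.poly_lr(200, cfg) == pytest.approx(0.0, abs=1e-15)
    assert T.poly_lr(100, cfg) == pytest.approx(1e-3 * 0.5 ** 0.9, abs=1e-15)


def test_poly_lr_monotone_nonincreasing():
    cfg = T.TrainConfig(lr0=1e-3, max_epochs=50, power=0.9)
    vals = [T.poly_lr(e, cfg) for e in range(51)]
    assert all(a >= b for a, b in zip(vals, vals[1:]))


def test_poly_lr_rejects_out_of_range():
    cfg = T.TrainConfig(max_epochs=10)
    with pytest.raises(ValueError):
        T.poly_lr(11, cfg)
    with pytest.raises(ValueError):
        T.poly_lr(-1, cfg)


def test_poly_lr_literal_parenthesization_flag():
    cfg = T.TrainConfig(lr0=1e-3, max_epochs=200, power=0.9, literal_schedule=True)
    expect = 1e-3 * (1.0 - (5 - 1.0 / 200) ** 0.9)
    assert T.poly_lr(5, cfg) == pytest.approx(expect, abs=1e-18)


# -- weighted cross-entropy ---------------------------------------------------

def _uniform_logits(shape):
    return np.zeros(shape, dtype=np.float64)


def test_uniform_logits_unit_weights_give_ln2():
    logits = _uniform_logits((2, 2, 4, 4))
    mask = (np.arange(32).reshape(2, 4, 4) % 2).astype(np.int64)
    loss = T.weighted_cross_entropy(logits, mask, (1.0, 1.0))
    assert loss.item() == pytest.approx(np.log(2.0), abs=1e-12)


def test_perfect_logits_drive_loss_to_zero():
    mask = (np.random.default_rng(0).random((1, 8, 8)) > 0.5).astype(np.int64)
    logits = np.zeros((1, 2, 8, 8))
    logits[0, 1] = 30.0 * mask[0]
    logits[0, 0] = 30.0 * (1 - mask[0])
    loss = T.weighted_cross_entropy(logits, mask, (1.0, 1.0))
    assert loss.item() < 1e-3


def test_weighted_ce_matches_hand_computation():
    """2x2 toy with printed logits and class weights (2, 1)."""
    logits = np.array([[[[1.0, -0.5], [0.2, 0.0]],
                        [[0.0, 0.5], [-0.2, 0.3]]]])
    mask = np.array([[[0, 1], [1, 0]]])
    weights = (2.0, 1.0)
    expect = 0.0
    for i in range(2):
        for j in range(2):
            z = logits[0, :, i, j]
            p = np.exp(z) / np.exp(z).sum()
            c = mask[0, i, j]
            expect += -weights[c] * np.log(p[c])
    expect /= 4.0
    loss = T.weighted_cross_entropy(logits, mask, weights)
    assert loss.item() == pytest.approx(expect, abs=1e-12)


def test_unit_weights_equal_unweighted(rng):
    logits = rng.standard_normal((2, 2, 5, 5))
    mask = (rng.random((2, 5, 5)) > 0.5).astype(np.int64)
    a = T.weighted_cross_entropy(logits, mask, (1.0, 1.0)).item()
    # plain cross-entropy reference
    z = logits - logits.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    ref = -np.mean(np.take_along_axis(logp, mask[:, None], axis=1))
    assert abs(a - ref) < 1e-12


def test_nonbinary_mask_rejected():
    with pytest.raises(ValueError, match="0/1"):
        T.weighted_cross_entropy(np.zeros((1, 2, 2, 2)), np.full((1, 2, 2), 2))


def test_inverse_frequency_weights():
    masks = [np.array([[1, 0, 0, 0]])]          # 25% foreground
    w_bg, w_fg = T.inverse_frequency_weights(masks)
    assert w_bg == pytest.approx(4 / (2 * 3))
    assert w_fg == pytest.approx(4 / (2 * 1))


# -- train loop ---------------------------------------------------------------

@pytest.fixture(scope="module")
def tiny_data():
    return generate_dataset(
        PhantomConfig(image_size=(32, 32), width_range=(1, 6)), 10, seed=3)


def test_zero_learning_rate_leaves_parameters_unchanged(tiny_data):
    net = build_network(NetworkConfig(depth=2, base_channels=4), seed=0)
    before = {k: v.data.copy() for k, v in net.named_parameters()}
    cfg = T.TrainConfig(lr0=0.0, max_epochs=2, batch_size=4, seed=0)
    net, _ = T.train(net, tiny_data, cfg)
    for k, p in net.named_parameters():
        np.testing.assert_array_equal(p.data, before[k])


def test_short_training_reduces_loss_and_logs_every_epoch(tiny_data):
    net = build_network(NetworkConfig(depth=2, base_channels=8), seed=1)
    cfg = T.TrainConfig(max_epochs=5, batch_size=4, seed=1)
    net, log = T.train(net, tiny_data, cfg)
    assert len(log.records) == 5
    assert log.records[-1].train_loss < log.records[0].train_loss
    assert all(np.isfinite(r.val_dsc) for r in log.records)
    csv = log.to_csv()
    assert csv.splitlines()[0] == "epoch,lr,train_loss,val_dsc"
    assert len(csv.splitlines()) == 6


def test_training_is_deterministic(tiny_data):
    cfg = T.TrainConfig(max_epochs=2, batch_size=4, seed=9)
    runs = []
    for _ in range(2):
        net = build_network(NetworkConfig(depth=2, base_channels=4), seed=9)
        net, log = T.train(net, tiny_data, cfg)
        runs.append((log.to_csv(), {k: v.data.copy() for k, v in net.named_parameters()}))
    assert runs[0][0] == runs[1][0]
    for k in runs[0][1]:
        np.testing.assert_array_equal(runs[0][1][k], runs[1][1][k])


def test_split_is_deterministic_and_disjoint():
    tr, va = T.split_train_val(20, 0.2, seed=4)
    tr2, va2 = T.split_train_val(20, 0.2, seed=4)
    np.testing.assert_array_equal(tr, tr2)
    np.testing.assert_array_equal(va, va2)
    assert len(va) == 4 and len(tr) == 16
    assert set(tr) | set(va) == set(range(20))
    assert not set(tr) & set(va)


def test_empty_dataset_rejected():
    net = build_network(NetworkConfig(depth=2, base_channels=4), seed=0)
    with pytest.raises(ValueError, match="empty"):
        T.train(net, [], T.TrainConfig(max_epochs=1))


@pytest.mark.parametrize("bad", [
    dict(lr0=-1.0), dict(beta1=1.0), dict(power=0.0), dict(class_weights=(0.0, 1.0)),
])
def test_invalid_train_configs_rejected(bad):
    with pytest.raises(ValueError):
        T.TrainConfig(**bad)


def test_online_augmentation_trains_and_is_deterministic(tiny_data):
    from vesselseg.pipeline import AugmentationConfig
    aug = AugmentationConfig(rotation_degrees_range=(-10, 10),
                             affine_scale_range=(0.95, 1.05),
                             vertical_flip_prob=0.5)
    cfg = T.TrainConfig(max_epochs=2, batch_size=4, seed=6)
    logs = []
    for _ in range(2):
        net = build_network(NetworkConfig(depth=2, base_channels=4), seed=6)
        net, log = T.train(net, tiny_data, cfg, augment_config=aug)
        logs.append(log.to_csv())
    assert logs[0] == logs[1]
    # augmentation changes the optimization trajectory
    net = build_network(NetworkConfig(depth=2, base_channels=4), seed=6)
    _, plain = T.train(net, tiny_data, cfg)
    assert plain.to_csv() != logs[0]
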