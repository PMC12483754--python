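"""Shallow ConvNet: shapes, determinism, training, LOOCV bookkeeping."""

import dataclasses

import numpy as np
import pytest

from eeglrp import NetSpec, RunConfig, build_model
from eeglrp.net import (
    CohortMetrics,
    Standardizer,
    TrainedModel,
    loocv,
    predict_subject,
    softmax,
    split_train_val,
    train,
)
from eeglrp.preprocessing import SegmentSet


def test_default_config_echoes_reference_hyperparameters():
    config = RunConfig()
    assert config.learning_rate == 0.001
    assert config.dropout == 0.5
    assert config.batch_size == 2
    assert config.epochs == 200
    assert config.val_fraction == 0.2  # 4:1 train:validation


def test_forward_shape_contract_full_geometry():
    """62 channels x 36000 samples (180 s at 200 Hz) -> two finite scores."""
    model = build_model(62, 36000, NetSpec(), seed=0)
    x = np.random.default_rng(0).standard_normal((1, 62, 36000)).astype(np.float32)
    logits = model.logits(x)
    assert logits.shape == (1, 2)
    assert np.all(np.isfinite(logits))


def test_forward_adapts_to_few_channels():
    model = build_model(5, 2000, NetSpec(), seed=0)
    logits = model.logits(np.zeros((1, 5, 2000), dtype=np.float32))
    assert logits.shape == (1, 2)


def test_same_seed_same_parameters():
    a = build_model(8, 500, NetSpec(4, 13, 4, 100, 50), seed=3)
    b = build_model(8, 500, NetSpec(4, 13, 4, 100, 50), seed=3)
    for k in a.params:
        np.testing.assert_array_equal(a.params[k], b.params[k])


def test_pool_exceeding_features_reports_shapes():
    with pytest.raises(ValueError, match="pool length"):
        build_model(4, 100, NetSpec(4, 25, 4, 200, 15), seed=0)


def test_toy_blobs_reach_full_training_accuracy(tiny_net):
    """Constant-channel renderings of two separated blobs train to 100%."""
    rng = np.random.default_rng(0)
    spec = dataclasses.replace(tiny_net, dropout=0.0, pool_length=188, pool_stride=188)

    def render(mu):
        point = mu + 0.1 * rng.standard_normal(2)
        return np.repeat(point, [1, 1])[:, None] * np.ones((2, 200), dtype=np.float32)

    examples = [(render(np.array([2.0, -2.0])), 0) for _ in range(8)] + [
        (render(np.array([-2.0, 2.0])), 1) for _ in range(8)
    ]
    model = build_model(2, 200, spec, seed=1)
    config = RunConfig(epochs=30, net=spec, seed=1)
    model, log, _ = train(model, examples[2:], examples[:2], config, seed=1)
    assert log[-1].train_acc == 1.0


def test_training_rejects_single_class(tiny_net):
    x = np.zeros((2, 200), dtype=np.float32)
    spec = dataclasses.replace(tiny_net, pool_length=188, pool_stride=188)
    model = build_model(2, 200, spec, seed=0)
    with pytest.raises(ValueError, match="both classes"):
        train(model, [(x, 0), (x, 0)], [(x, 0)], RunConfig(epochs=1, net=spec), seed=0)


def test_split_matches_reference_fold_geometry():
    """80 remainder subjects split 4:1 into 64 train / 16 validation."""
    ids = [f"s{i:02d}" for i in range(80)]
    labels = [i % 2 for i in range(80)]
    tr, va = split_train_val(ids, labels, val_fraction=0.2, seed=1)
    assert len(tr) == 64 and len(va) == 16
    assert set(tr) | set(va) == set(ids)
    assert not set(tr) & set(va)


class _FixedProbs(TrainedModel):
    """Test double returning scripted probabilities per call."""

    def __init__(self, probs):
        self._probs = list(probs)
        self._i = 0

    def predict_proba(self, x):
        p = self._probs[self._i % len(self._probs)]
        self._i += 1
        return np.asarray(p)


def seg_set(n_segments):
    seg = np.zeros((2, 10))
    return SegmentSet("s", 1, tuple(seg for _ in range(n_segments)), 0.1, 100.0)


def test_predict_subject_averages_segment_probabilities():
    label, probs = predict_subject(_FixedProbs([(0.9, 0.1), (0.2, 0.8)]), seg_set(2))
    np.testing.assert_allclose(probs, [0.55, 0.45])
    assert label == 0


def test_predict_subject_single_segment_is_argmax():
    label, probs = predict_subject(_FixedProbs([(0.3, 0.7)]), seg_set(1))
    assert label == 1
    np.testing.assert_allclose(probs, [0.3, 0.7])


def test_predict_subject_constant_segments_match_single():
    l1, p1 = predict_subject(_FixedProbs([(0.3, 0.7)]), seg_set(1))
    l3, p3 = predict_subject(_FixedProbs([(0.3, 0.7)] * 3), seg_set(3))
    assert l1 == l3
    np.testing.assert_allclose(p1, p3)


def test_loocv_structure_and_leakage(tiny_loocv):
    folds = tiny_loocv["folds"]
    sets = tiny_loocv["sets"]
    assert len(folds) == len(sets)
    assert {f.test_subject_id for f in folds} == {s.subject_id for s in sets}
    for f in folds:
        rest = set(f.train_subject_ids) | set(f.val_subject_ids)
        assert f.test_subject_id not in rest
        assert len(rest) == len(sets) - 1
        # 4:1 split of the 11-subject remainder
        assert len(f.val_subject_ids) == 3
        assert len(f.train_subject_ids) == 8


def test_metrics_recomputable_from_folds(tiny_loocv):
    metrics = tiny_loocv["metrics"]
    folds = tiny_loocv["folds"]
    again = CohortMetrics.from_folds(folds)
    assert again == metrics
    n = metrics.tp + metrics.tn + metrics.fp + metrics.fn
    assert n == len(folds)
    assert metrics.accuracy == pytest.approx(100.0 * (metrics.tp + metrics.tn) / n)


def test_loocv_invariant_to_subject_order(tiny_cohort, tiny_net, small_montage):
    from eeglrp.preprocessing import segment

    _, recs = tiny_cohort
    sets = [segment(r, 10.0) for r in recs]
    config = RunConfig(epochs=2, net=tiny_net, seed=5)
    _, m1 = loocv(sets, small_montage, config)
    _, m2 = loocv(sets[::-1], small_montage, config)
    assert m1 == m2


def test_loocv_needs_three_per_class(tiny_net, small_montage, tiny_cohort):
    from eeglrp.preprocessing import segment

    _, recs = tiny_cohort
    sets = [segment(r, 10.0) for r in recs[:4] + recs[-2:]]  # 4 vs 2
    with pytest.raises(ValueError, match="3 subjects"):
        loocv(sets, small_montage, RunConfig(epochs=1, net=tiny_net))


def test_standardizer_uses_training_statistics_only():
    rng = np.random.default_rng(0)
    a = rng.standard_normal((3, 100)) * 5 + 2
    scaler = Standardizer.fit([(a, 0)])
    z = scaler.transform(a)
    np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-5)
    np.testing.assert_allclose(z.std(axis=1), 1.0, atol=1e-4)
    other = rng.standard_normal((3, 50))
    z2 = scaler.transform(other)
    expected = (other - a.mean(axis=1, keepdims=True)) / a.std(axis=1, keepdims=True)
    np.testing.assert_allclose(z2, expected, atol=1e-4)


@pytest.mark.parametrize("activation", ["relu", "square_log"])
def test_backward_matches_numerical_gradient(activation):
    """Analytic gradients agree with central differences (both variants)."""
    spec = NetSpec(
        n_temporal_filters=2,
        temporal_kernel=5,
        n_spatial_filters=2,
        pool_length=8,
        pool_stride=4,
        dropout=0.0,
        activation=activation,
    )
    model = build_model(3, 40, spec, seed=7)
    model.params = {k: v.astype(np.float64) for k, v in model.params.items()}
    rng = np.random.default_rng(7)
    x = rng.standard_normal((2, 3, 40))
    y = np.array([1, 0])

    def loss():
        probs = softmax(model.forward(x)["logits"])
        return float(-np.log(probs[np.arange(2), y]).mean())

    cache = model.forward(x)
    probs = softmax(cache["logits"])
    grads = model.backward(cache, (probs - np.eye(2)[y]) / 2)
    for key, grad in grads.items():
        numeric = np.zeros_like(model.params[key])
        it = np.nditer(model.params[key], flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            model.params[key][i] += 1e-6
            up = loss()
            model.params[key][i] -= 2e-6
            down = loss()
            model.params[key][i] += 1e-6
            numeric[i] = (up - down) / 2e-6
        scale = np.abs(numeric).max() + 1e-9
        assert np.abs(numeric - grad).max() / scale < 1e-5, key


def test_softmax_probabilities_sum_to_one():
    p = softmax(np.array([[3.0, -1.0], [0.0, 0.0]]))
    np.testing.assert_allclose(p.sum(axis=1), 1.0)
    assert np.all(p >= 0)
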