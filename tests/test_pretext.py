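"""Temporal-shuffling task: label rule, contrastive features, loss, training."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dyadbrain.embedder import EmbedderConfig
from dyadbrain.pretext import (
    InsufficientDataError,
    OptimizerConfig,
    PretextHead,
    SamplerConfig,
    TripletSample,
    contrast_ts,
    sample_triplets,
    train_pretext,
    ts_loss,
)
from dyadbrain.types import EpochArray


def _epochs(n=40, c=2, t=101, seed=0):
    rng = np.random.default_rng(seed)
    return EpochArray(rng.standard_normal((n, c, t)), 100.0, 1.0)


class TestSampler:
    def test_label_rule_matches_interval_membership(self):
        """Every emitted label equals a brute-force check of the probe
        against the open anchor interval."""
        ep = _epochs(60)
        for mode in ("far", "near"):
            cfg = SamplerConfig(tau_pos=10, tau_neg=3, n_triplets=500,
                                negative_mode=mode, seed=4)
            for t in sample_triplets(ep, cfg):
                expected = 1 if t.e < t.e_prime < t.e_dprime else -1
                assert t.y == expected

    def test_anchor_constraints(self):
        cfg = SamplerConfig(tau_pos=10, n_triplets=300, seed=1)
        for t in sample_triplets(_epochs(60), cfg):
            assert 2 <= t.e_dprime - t.e <= 10

    def test_class_balance_within_one(self):
        for n in (10, 11, 99):
            cfg = SamplerConfig(n_triplets=n, seed=2)
            ys = [t.y for t in sample_triplets(_epochs(50), cfg)]
            assert abs(ys.count(1) - ys.count(-1)) <= 1

    def test_far_negatives_outside_negative_context(self):
        cfg = SamplerConfig(tau_pos=5, tau_neg=3, n_triplets=300, seed=3)
        for t in sample_triplets(_epochs(60), cfg):
            if t.y == -1:
                assert t.e_prime < t.e - 3 or t.e_prime > t.e_dprime + 3

    def test_near_negatives_within_negative_context(self):
        cfg = SamplerConfig(tau_pos=5, tau_neg=3, n_triplets=300,
                            negative_mode="near", seed=3)
        for t in sample_triplets(_epochs(60), cfg):
            if t.y == -1:
                gap = min(abs(t.e_prime - t.e), abs(t.e_prime - t.e_dprime))
                assert 1 <= gap <= 3
                assert not (t.e < t.e_prime < t.e_dprime)

    def test_one_epoch_context_yields_only_shuffled(self):
        """tau_pos=1 leaves no interior slot: the ordered class cannot be
        constructed, so the sample set is single-class and visibly
        imbalanced."""
        cfg = SamplerConfig(tau_pos=1, tau_neg=3, n_triplets=100, seed=5)
        triplets = sample_triplets(_epochs(60), cfg)
        assert len(triplets) == 100
        assert all(t.y == -1 for t in triplets)
        assert all(t.e_dprime - t.e == 1 for t in triplets)

    def test_zero_triplets(self):
        assert sample_triplets(_epochs(50), SamplerConfig(n_triplets=0)) == []

    def test_insufficient_epochs(self):
        with pytest.raises(InsufficientDataError):
            sample_triplets(_epochs(8), SamplerConfig(tau_pos=10, n_triplets=5))

    def test_seeded_determinism(self):
        cfg = SamplerConfig(n_triplets=50, seed=9)
        a = sample_triplets(_epochs(50), cfg)
        b = sample_triplets(_epochs(50), cfg)
        assert a == b

    def test_triplet_invariants_enforced(self):
        with pytest.raises(ValueError):
            TripletSample(0, 5, 3, 2, 1)  # anchors out of order
        with pytest.raises(ValueError):
            TripletSample(0, 1, 2, 3, 0)  # label not in {-1, +1}


class TestContrast:
    def test_identical_embeddings_zero(self):
        z = np.ones(100)
        out = contrast_ts(z, z, z)
        assert out.shape == (200,)
        assert np.all(out == 0)

    def test_output_dimension_is_2d(self):
        rng = np.random.default_rng(0)
        z = rng.standard_normal((3, 100))
        assert contrast_ts(z[0], z[1], z[2]).shape == (200,)

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError):
            contrast_ts(np.ones(3), np.ones(4), np.ones(3))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(1, 20), st.integers(0, 2**31 - 1))
    def test_matches_elementwise_oracle(self, d, seed):
        rng = np.random.default_rng(seed)
        a, b, c = rng.standard_normal((3, d))
        got = contrast_ts(a, b, c)
        expected = np.array([abs(a[i] - b[i]) for i in range(d)]
                            + [abs(b[i] - c[i]) for i in range(d)])
        assert np.array_equal(got, expected)


class TestLoss:
    def test_zero_head_gives_ln2(self):
        rng = np.random.default_rng(0)
        g = rng.standard_normal((17, 10))
        y = rng.choice([-1.0, 1.0], 17)
        loss, *_ = ts_loss(y, g, PretextHead.zeros(5))
        assert abs(loss - np.log(2)) < 1e-12

    def test_large_margins_drive_loss_to_zero(self):
        y = np.array([1.0, -1.0])
        g = np.array([[1.0], [-1.0]])
        head = PretextHead(w=np.array([1e4]), w0=0.0)
        loss, *_ = ts_loss(y, g.repeat(1, axis=1), head)
        assert loss < 1e-10

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(3)
        g = rng.standard_normal((9, 6))
        y = rng.choice([-1.0, 1.0], 9)
        head = PretextHead(w=rng.standard_normal(6), w0=0.3)
        loss, dw, dw0, dg = ts_loss(y, g, head)
        expected = np.mean(
            [np.log1p(np.exp(-y[i] * (g[i] @ head.w + head.w0))) for i in range(9)]
        )
        assert abs(loss - expected) < 1e-12

    def test_order_invariance(self):
        rng = np.random.default_rng(4)
        g = rng.standard_normal((20, 4))
        y = rng.choice([-1.0, 1.0], 20)
        head = PretextHead(w=rng.standard_normal(4), w0=-0.1)
        perm = rng.permutation(20)
        assert ts_loss(y, g, head)[0] == pytest.approx(ts_loss(y[perm], g[perm], head)[0], abs=1e-14)

    def test_empty_sample_set_errors(self):
        with pytest.raises(ValueError):
            ts_loss(np.empty(0), np.empty((0, 4)), PretextHead.zeros(2))


def test_joint_gradient_matches_finite_differences():
    """Analytic gradients of the full pretext loss (through g_TS and the
    embedder) agree with central finite differences on a tiny model."""
    from dyadbrain.embedder import build_embedder
    from dyadbrain.pretext import _forward_batch, _HeadAdapter

    cfg = EmbedderConfig(n_channels=2, n_times=25, n_temporal_filters=3,
                         k_time=5, pool_len=5, pool_stride=3, D=4, dropout=0.0)
    model = build_embedder(cfg, seed=0)
    rng = np.random.default_rng(1)
    xs = rng.standard_normal((6, 3, 2, 25))
    ys = rng.choice([-1.0, 1.0], 6)
    head = PretextHead(w=rng.standard_normal(8) * 0.3, w0=0.1)

    def loss_at(flat_model, w, w0):
        # train mode (batch statistics) to match the differentiated path;
        # dropout is zero so the forward map is deterministic
        model.net.set_flat(flat_model)
        h = PretextHead(w=w, w0=w0)
        loss, _, _ = _forward_batch(model, h, xs, ys, train=True)
        return loss

    flat0 = model.net.get_flat()
    model.net.set_flat(flat0)
    loss, acc, dhead = _forward_batch(model, head, xs, ys, train=True)
    g_model = model.net.get_grad_flat()
    eps = 1e-6
    fd_model = np.empty_like(flat0)
    for i in range(flat0.size):
        up, dn = flat0.copy(), flat0.copy()
        up[i] += eps
        dn[i] -= eps
        fd_model[i] = (loss_at(up, head.w, head.w0) - loss_at(dn, head.w, head.w0)) / (2 * eps)
    assert np.linalg.norm(g_model - fd_model) / np.linalg.norm(fd_model) <= 1e-4

    fd_head = np.empty(9)
    for i in range(8):
        up, dn = head.w.copy(), head.w.copy()
        up[i] += eps
        dn[i] -= eps
        fd_head[i] = (loss_at(flat0, up, head.w0) - loss_at(flat0, dn, head.w0)) / (2 * eps)
    fd_head[8] = (loss_at(flat0, head.w, head.w0 + eps) - loss_at(flat0, head.w, head.w0 - eps)) / (2 * eps)
    assert np.linalg.norm(dhead - fd_head) / np.linalg.norm(fd_head) <= 1e-4


class TestTraining:
    @staticmethod
    def _tiny_run(seed=5):
        rng = np.random.default_rng(7)
        eps = [EpochArray(rng.standard_normal((30, 2, 25)), 24.0, 1.0) for _ in range(2)]
        cfg = EmbedderConfig(n_channels=2, n_times=25, n_temporal_filters=3,
                             k_time=5, pool_len=5, pool_stride=3, D=4, dropout=0.2)
        return train_pretext(
            eps,
            cfg,
            SamplerConfig(tau_pos=5, n_triplets=40, seed=seed),
            OptimizerConfig(n_iterations=12, batch_size=16, seed=seed),
        )

    def test_rerun_reproduces_history(self):
        _, _, h1 = self._tiny_run()
        _, _, h2 = self._tiny_run()
        assert h1["train_loss"] == h2["train_loss"]
        assert h1["val_acc"] == h2["val_acc"]

    def test_history_structure(self):
        model, head, hist = self._tiny_run()
        assert len(hist["train_loss"]) == 12
        assert hist["class_balance"][0] + hist["class_balance"][1] == hist["n_triplets"]
        assert head.w.shape == (8,)

    def test_no_epoch_sets_errors(self):
        with pytest.raises(InsufficientDataError):
            train_pretext([], EmbedderConfig())
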