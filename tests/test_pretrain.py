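"""View-pair construction, the NT-Xent loss against a brute-force oracle,
augmentation contracts and checkpoint round trips."""

import numpy as np
import pytest

from fundusnet.imutils import nchw, resize, to_float
from fundusnet.models import build_encoder, build_projection_head
from fundusnet.pretrain import (
    AugmentationPolicy,
    desk_pretrain_config,
    embed,
    load_checkpoint,
    make_view_pair,
    nt_xent_loss,
    nt_xent_loss_and_grad,
    pretrain,
    regular_augment,
    save_checkpoint,
)


def nt_xent_oracle(z, pair_index, tau):
    """Independent double-loop implementation of the contrastive loss."""
    z = np.asarray(z, float)
    u = z / np.linalg.norm(z, axis=1, keepdims=True)
    n2 = len(u)
    total = 0.0
    for i in range(n2):
        num = np.exp(u[i] @ u[pair_index[i]] / tau)
        den = sum(np.exp(u[i] @ u[k] / tau) for k in range(n2) if k != i)
        total += -np.log(num / den)
    return total / n2


IDENTITY_POLICY = dict(
    nst_probability=0.0, rotation_max_deg=0.0, jitter_strength=0.0,
    color_jitter_probability=0.0, blur_probability=0.0, crop_scale=(1.0, 1.0),
    hflip_probability=0.0, vflip_probability=0.0, output_size=32,
)


class TestRegularAugment:
    def test_identity_policy_returns_resized_input(self, dataset, rng):
        from fundusnet.imutils import load_image
        img = load_image(dataset.records[0].path)
        out = regular_augment(img, AugmentationPolicy(**IDENTITY_POLICY), rng)
        assert np.allclose(out, resize(to_float(img), 32), atol=1e-6)

    def test_deterministic_under_rng_state(self, dataset):
        from fundusnet.imutils import load_image
        img = load_image(dataset.records[1].path)
        pol = AugmentationPolicy(output_size=32)
        a = regular_augment(img, pol, np.random.default_rng(5))
        b = regular_augment(img, pol, np.random.default_rng(5))
        assert np.array_equal(a, b)

    def test_rotation_draws_respect_bound(self, rng):
        img = rng.random((32, 32, 3)).astype(np.float32)
        pol = AugmentationPolicy(output_size=32)
        log = []
        for _ in range(1000):
            regular_augment(img, pol, rng, log=log)
        rotations = [d["rotation_deg"] for d in log]
        assert len(rotations) == 1000
        assert min(rotations) >= -30.0 and max(rotations) <= 30.0

    def test_probability_bounds_validated(self):
        with pytest.raises(ValueError):
            AugmentationPolicy(nst_probability=1.2)


class TestMakeViewPair:
    def test_zero_probability_never_stylizes(self, dataset, rng):
        pol = AugmentationPolicy(nst_probability=0.0, output_size=32)
        log = []
        make_view_pair(dataset.records[0], pol, None, rng, log=log)
        assert [d["stylized"] for d in log] == [False, False]

    def test_certain_probability_uses_cached_variant(self, dataset,
                                                     stylized_cache, rng):
        pol = AugmentationPolicy(nst_probability=1.0, output_size=32)
        log = []
        make_view_pair(dataset.records[0], pol, stylized_cache, rng, log=log)
        assert [d["stylized"] for d in log] == [True, True]

    def test_missing_cache_entry_names_image(self, dataset, rng):
        pol = AugmentationPolicy(nst_probability=1.0, output_size=32)
        with pytest.raises(KeyError, match=dataset.records[0].image_id):
            make_view_pair(dataset.records[0], pol, None, rng)


class TestEmbed:
    def test_shapes_and_projection_dim(self, rng):
        enc = build_encoder("small", rng)
        head = build_projection_head(32, rng)
        views = rng.random((8, 3, 32, 32)).astype(np.float32)
        batch = embed(views, enc, head)
        assert batch.z.shape == (8, 128)
        assert batch.h.shape == (8, 32)

    def test_duplicate_views_embed_identically(self, rng):
        enc = build_encoder("small", rng)
        head = build_projection_head(32, rng)
        v = rng.random((1, 3, 32, 32)).astype(np.float32)
        views = np.concatenate([v, v], axis=0)
        batch = embed(views, enc, head)
        assert np.array_equal(batch.h[0], batch.h[1])

    def test_pair_index_is_involution(self, rng):
        enc = build_encoder("small", rng)
        head = build_projection_head(32, rng)
        batch = embed(rng.random((12, 3, 32, 32)).astype(np.float32), enc, head)
        p = batch.pair_index
        assert np.array_equal(p[p], np.arange(12))
        assert np.all(p != np.arange(12))


class TestNtXent:
    def test_single_pair_no_negatives_is_zero(self, rng):
        z = rng.standard_normal((2, 16))
        assert nt_xent_loss(z, np.array([1, 0]), tau=0.5) == pytest.approx(0.0)

    def test_orthogonal_pairs_closed_form(self):
        z = np.array([[1, 0], [1, 0], [0, 1], [0, 1]], dtype=float)
        loss = nt_xent_loss(z, np.array([1, 0, 3, 2]), tau=0.5)
        expected = -np.log(np.e ** 2 / (np.e ** 2 + 2))
        assert loss == pytest.approx(expected, abs=1e-9)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 17))
            z = rng.standard_normal((2 * n, int(rng.integers(3, 12))))
            pair = np.arange(2 * n) ^ 1
            ours = nt_xent_loss(z, pair, tau=0.5)
            assert ours == pytest.approx(nt_xent_oracle(z, pair, 0.5), abs=1e-6)

    def test_gradient_matches_finite_differences(self, rng):
        z = rng.standard_normal((8, 6))
        pair = np.arange(8) ^ 1
        _, g = nt_xent_loss_and_grad(z, pair, 0.5)
        eps = 1e-6
        for idx in [(0, 0), (3, 2), (7, 5)]:
            zp, zm = z.copy(), z.copy()
            zp[idx] += eps
            zm[idx] -= eps
            fd = (nt_xent_loss(zp, pair, 0.5) - nt_xent_loss(zm, pair, 0.5)) / (2 * eps)
            assert g[idx] == pytest.approx(fd, rel=1e-4, abs=1e-8)

    def test_alignment_monotonicity(self):
        """Pulling a positive pair together strictly decreases the loss
        while negatives stay fixed."""
        base = np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, 0.5], [0.3, -1.0]])
        pair = np.array([1, 0, 3, 2])
        losses = []
        for w in (0.0, 0.4, 0.8):
            z = base.copy()
            z[1] = (1 - w) * base[1] + w * base[0]
            losses.append(nt_xent_loss(z, pair, 0.5))
        assert losses[0] > losses[1] > losses[2]

    def test_row_scale_invariance(self, rng):
        z = rng.standard_normal((10, 7))
        pair = np.arange(10) ^ 1
        ref = nt_xent_loss(z, pair, 0.5)
        z[3] *= 42.0
        assert nt_xent_loss(z, pair, 0.5) == pytest.approx(ref, abs=1e-12)

    def test_scale_invariance_property(self):
        from hypothesis import given, settings, strategies as st

        @settings(derandomize=True, max_examples=40, deadline=None)
        @given(row=st.integers(0, 9), scale=st.floats(1e-3, 1e3),
               seed=st.integers(0, 50))
        def check(row, scale, seed):
            z = np.random.default_rng(seed).standard_normal((10, 7))
            pair = np.arange(10) ^ 1
            ref = nt_xent_loss(z, pair, 0.5)
            z[row] *= scale
            assert nt_xent_loss(z, pair, 0.5) == pytest.approx(ref, abs=1e-9)

        check()

    def test_zero_norm_row_reported(self):
        z = np.array([[1.0, 0.0], [0.0, 0.0]])
        with pytest.raises(FloatingPointError, match=r"\[1\]"):
            nt_xent_loss(z, np.array([1, 0]), 0.5)


class TestPretrain:
    def test_zero_epochs_returns_initialization(self, dataset):
        cfg = desk_pretrain_config(batch_size=8, epochs=0,
                                   policy=AugmentationPolicy(**IDENTITY_POLICY))
        ck = pretrain(dataset, None, cfg, seed=3)
        assert ck.epoch == 0 and ck.loss_trace == []
        from fundusnet.pretrain import init_models
        init, _, _ = init_models("small", 3)
        assert all(np.array_equal(v, init.named_params()[k])
                   for k, v in ck.encoder_arrays.items())

    def test_batch_larger_than_dataset_rejected(self, dataset):
        cfg = desk_pretrain_config(batch_size=1024)
        with pytest.raises(ValueError, match="batch_size"):
            pretrain(dataset, None, cfg, seed=0)

    def test_checkpoint_round_trip_bit_identical_forward(self, dataset,
                                                         tmp_path, rng):
        pol = AugmentationPolicy(nst_probability=0.0, output_size=32)
        cfg = desk_pretrain_config(batch_size=8, epochs=1, policy=pol)
        ck = pretrain(dataset, None, cfg, seed=5)
        save_checkpoint(ck, tmp_path / "ck")
        back = load_checkpoint(tmp_path / "ck")
        enc_a = build_encoder("small", rng)
        enc_a.set_params(ck.encoder_arrays)
        enc_b = build_encoder("small", np.random.default_rng(999))
        enc_b.set_params(back.encoder_arrays)
        x = rng.random((4, 3, 32, 32)).astype(np.float32)
        assert np.array_equal(enc_a.forward(x), enc_b.forward(x))
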