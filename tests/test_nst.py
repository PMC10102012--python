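"""AdaIN algebra (exact, decoder-independent), coder training contracts,
stylization determinism and the pre-synthesized variant cache."""

import hashlib
import json
from pathlib import Path

import numpy as np
import pytest

from fundusnet.imutils import load_image, luminance, nchw, resize, to_float
from fundusnet.nst import (
    CoderConfig,
    adain,
    channel_stats,
    load_cache,
    load_coder,
    precompute_stylized,
    save_coder,
    stylize,
    train_coder,
)
from fundusnet.synthgen import SynthParams, generate_fundus, generate_style_bank


class TestChannelStats:
    def test_hand_example_population_std(self):
        cs = channel_stats(np.array([[[1.0, 2.0, 3.0]]]))
        assert cs.mu[0] == pytest.approx(2.0)
        assert cs.sigma[0] == pytest.approx(np.sqrt(2.0 / 3.0), abs=1e-12)

    def test_constant_channel_has_zero_sigma(self):
        cs = channel_stats(np.full((2, 3, 3), 5.0))
        assert np.all(cs.sigma == 0.0)

    def test_channels_are_independent(self, rng):
        fm = rng.standard_normal((3, 4, 5))
        cs = channel_stats(fm)
        for c in range(3):
            assert cs.mu[c] == pytest.approx(fm[c].mean())
            assert cs.sigma[c] == pytest.approx(fm[c].std())

    def test_empty_spatial_extent_rejected(self):
        with pytest.raises(ValueError):
            channel_stats(np.empty((3, 0, 4)))


class TestAdain:
    def test_hand_example_sigma_ratio_two(self):
        content = np.array([[[1.0, 2.0, 3.0]]])
        style = np.array([[[8.0, 10.0, 12.0]]])
        assert np.allclose(adain(content, style, 1.0), style)

    def test_style_equal_content_is_identity(self, rng):
        x = rng.standard_normal((2, 3, 3))
        assert np.allclose(adain(x, x, 1.0), x, atol=1e-12)

    def test_alpha_zero_is_exact_identity(self, rng):
        x, y = rng.standard_normal((2, 4, 4)), rng.standard_normal((2, 5, 5))
        assert np.array_equal(adain(x, y, 0.0), x)

    def test_alpha_one_aligns_statistics(self, rng):
        for _ in range(100):
            c = int(rng.integers(1, 6))
            x = rng.standard_normal((c, int(rng.integers(2, 8)), 5))
            y = rng.standard_normal((c, 4, int(rng.integers(2, 8))))
            out, ys = channel_stats(adain(x, y, 1.0)), channel_stats(y)
            assert np.allclose(out.mu, ys.mu, atol=1e-6)
            assert np.allclose(out.sigma, ys.sigma, atol=1e-6)

    def test_statistics_idempotent(self, rng):
        x, y = rng.standard_normal((3, 6, 6)), rng.standard_normal((3, 6, 6))
        once = adain(x, y, 1.0)
        assert np.allclose(adain(once, y, 1.0), once, atol=1e-6)

    def test_channel_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="channel"):
            adain(rng.standard_normal((2, 3, 3)), rng.standard_normal((3, 3, 3)))

    def test_zero_variance_channel_warns(self):
        with pytest.warns(UserWarning, match="constant"):
            adain(np.full((1, 2, 2), 3.0), np.ones((1, 2, 2)) * [[1.0, 2.0]], 1.0)


class TestCoder:
    def test_too_few_images_rejected(self, style_bank):
        with pytest.raises(ValueError, match="64"):
            train_coder(style_bank[:10])

    def test_converges_below_ceiling(self, coder):
        assert coder.holdout_error < coder.config.error_ceiling
        assert coder.loss_trace[-1] < coder.loss_trace[0]

    def test_training_is_deterministic(self, style_bank, synth_params):
        imgs = [generate_fundus(synth_params, i % 5, 900 + i).image
                for i in range(60)] + style_bank
        cfg = CoderConfig(epochs=3, error_ceiling=1.0)  # determinism only
        digests = []
        for _ in range(2):
            spec = train_coder(imgs, cfg, seed=5)
            h = hashlib.sha256()
            for k in sorted(spec.encoder.named_params()):
                h.update(spec.encoder.named_params()[k].tobytes())
            digests.append(h.hexdigest())
        assert digests[0] == digests[1]

    def test_archive_round_trip(self, coder, tmp_path, rng):
        save_coder(coder, tmp_path / "coder")
        back = load_coder(tmp_path / "coder")
        x = rng.random((1, 3, 32, 32)).astype(np.float32)
        assert np.array_equal(coder.encoder.forward(x), back.encoder.forward(x))


class TestStylize:
    def test_alpha_zero_equals_plain_reconstruction(self, coder, synth_params):
        content = generate_fundus(synth_params, 2, seed=1).image
        out = stylize(content, np.zeros((32, 32, 3), np.uint8), 0.0, coder)
        cw = nchw(resize(to_float(content), coder.config.content_size))
        recon = coder.decoder.forward(coder.encoder.forward(cw[None]))[0]
        from fundusnet.imutils import hwc, to_uint8
        expected = to_uint8(resize(hwc(recon), content.shape[0]))
        assert np.array_equal(out, expected)

    def test_alpha_one_aligns_encoded_statistics(self, coder, synth_params,
                                                 style_bank):
        """At the AdaIN layer the transformed features carry the style's
        channel statistics exactly, regardless of decoder quality."""
        content = generate_fundus(synth_params, 2, seed=1).image
        style = style_bank[3]
        cw = nchw(resize(to_float(content), coder.config.content_size))
        sw = nchw(resize(to_float(style), coder.config.style_size))
        f_c = coder.encoder.forward(cw[None])[0]
        f_s = coder.encoder.forward(sw[None])[0]
        t = adain(f_c, f_s, 1.0)
        ts, ss = channel_stats(t), channel_stats(f_s)
        assert np.allclose(ts.mu, ss.mu, atol=1e-5)
        assert np.allclose(ts.sigma, ss.sigma, atol=1e-5)

    def test_deterministic_bytes(self, coder, synth_params, style_bank):
        content = generate_fundus(synth_params, 3, seed=2).image
        a = stylize(content, style_bank[0], 1.0, coder)
        b = stylize(content, style_bank[0], 1.0, coder)
        assert np.array_equal(a, b)


class TestPrecompute:
    def test_counts_and_index(self, stylized_cache, dataset):
        assert len(stylized_cache) == 2 * len(dataset)
        assert len(stylized_cache.variants(dataset.records[0].image_id)) == 2

    def test_same_seed_same_style_assignment(self, dataset, style_bank, coder,
                                             tmp_path):
        few = dataset.subset(range(4))
        c1 = precompute_stylized(few, style_bank, 2, 1.0, coder,
                                 tmp_path / "a", seed=9)
        c2 = precompute_stylized(few, style_bank, 2, 1.0, coder,
                                 tmp_path / "b", seed=9)
        assert c1.index["style_id"].tolist() == c2.index["style_id"].tolist()

    def test_variants_differ_from_source(self, stylized_cache, dataset):
        rec = dataset.records[0]
        src = load_image(rec.path)
        var = load_image(stylized_cache.variants(rec.image_id)[0])
        assert np.abs(var - src).mean() > 0.0

    def test_empty_style_bank_rejected(self, dataset, coder, tmp_path):
        with pytest.raises(ValueError, match="empty"):
            precompute_stylized(dataset, [], 1, 1.0, coder, tmp_path, 0)

    def test_cache_round_trip(self, stylized_cache, tmp_path):
        stylized_cache.save(tmp_path / "idx.csv")
        back = load_cache(tmp_path / "idx.csv")
        assert back.index["variant_path"].tolist() == \
            stylized_cache.index["variant_path"].tolist()


def test_stylization_preserves_lesion_contrast(dataset, stylized_cache):
    """Style transfer changes texture but preserves semantic content: the
    lesion region keeps its dark/bright sign against its surround in at
    least 90% of lesions."""
    total = preserved = 0
    for rec in dataset:
        objects = json.loads(Path(rec.path).with_suffix(".json").read_text()
                             )["objects"]
        lesions = [o for o in objects if o["kind"] == "lesion"]
        if not lesions:
            continue
        content = luminance(load_image(rec.path))
        styled = luminance(load_image(stylized_cache.variants(rec.image_id)[0]))
        size = content.shape[0]
        yy, xx = np.mgrid[0:size, 0:size]
        for o in lesions:
            inside = (xx - o["x"]) ** 2 + (yy - o["y"]) ** 2 <= o["r"] ** 2
            ring = ((xx - o["x"]) ** 2 + (yy - o["y"]) ** 2
                    <= (o["r"] + 3) ** 2) & ~inside
            if inside.sum() < 1 or ring.sum() < 1:
                continue
            sign_c = np.sign(content[inside].mean() - content[ring].mean())
            sign_s = np.sign(styled[inside].mean() - styled[ring].mean())
            total += 1
            preserved += sign_c == sign_s
    assert total > 50
    assert preserved / total >= 0.9
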