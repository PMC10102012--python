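"""Style transfer by adaptive instance normalization (AdaIN).

Content and style images are encoded into a convolutional feature space;
the AdaIN layer re-scales each content channel so its spatial mean and
standard deviation match the style channel's, and a decoder renders the
re-styled features back to an image.  The AdaIN algebra itself is exact:

    t = sigma(style) * (content - mu(content)) / sigma(content) + mu(style)
    output features = alpha * t + (1 - alpha) * content

with the stylization coefficient alpha blending between full style (1.0)
and the untouched content features (0.0).

The feature space comes from a small convolutional autoencoder trained by
pixel reconstruction on synthetic fundus and style images — a desk-scale
coder whose quality affects the rendered image only; the statistic
alignment at the AdaIN layer holds regardless of the decoder.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import Manifest
from .imutils import load_image, nchw, hwc, resize, save_image, to_float, to_uint8
from .nn import Adam, AvgPool2d, Conv2d, ReLU, Sequential, Sigmoid, UpsampleNearest

__all__ = [
    "TrainingError",
    "ChannelStats",
    "CoderConfig",
    "CoderSpec",
    "StylizedCache",
    "channel_stats",
    "adain",
    "train_coder",
    "stylize",
    "precompute_stylized",
    "load_cache",
]

#: variance floor substituted for degenerate (constant) content channels
SIGMA_EPS = 1e-5


class TrainingError(RuntimeError):
    pass


@dataclasses.dataclass
class ChannelStats:
    mu: np.ndarray
    sigma: np.ndarray


def channel_stats(fm: np.ndarray) -> ChannelStats:
    """Per-channel spatial mean and population standard deviation of a
    (C, H, W) feature map."""
    fm = np.asarray(fm)
    if fm.ndim != 3 or fm.shape[1] * fm.shape[2] == 0:
        raise ValueError("feature map must be (C, H, W) with spatial extent")
    flat = fm.reshape(fm.shape[0], -1)
    return ChannelStats(mu=flat.mean(axis=1), sigma=flat.std(axis=1))


def adain(content: np.ndarray, style: np.ndarray, alpha: float = 1.0) -> np.ndarray:
    """Align content channel statistics to the style's, blended by alpha."""
    if content.shape[0] != style.shape[0]:
        raise ValueError(
            f"channel mismatch: content {content.shape[0]} vs style {style.shape[0]}"
        )
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if alpha == 0.0:
        return content.copy()
    cs, ss = channel_stats(content), channel_stats(style)
    sigma_c = cs.sigma.copy()
    if np.any(sigma_c == 0):
        warnings.warn("constant content channel(s); substituting sigma=eps")
        sigma_c[sigma_c == 0] = SIGMA_EPS
    t = (
        ss.sigma[:, None, None]
        * (content - cs.mu[:, None, None])
        / sigma_c[:, None, None]
        + ss.mu[:, None, None]
    )
    return alpha * t + (1.0 - alpha) * content


# ---------------------------------------------------------------------------
# Coder (autoencoder feature space)
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class CoderConfig:
    work_size: int = 32          # training-patch side
    content_size: int = 64       # content working size during stylization
    style_size: int = 32         # style working size during stylization
    channels: tuple[int, int] = (12, 24)
    epochs: int = 35
    batch_size: int = 16
    lr: float = 3e-3
    holdout_fraction: float = 0.2
    error_ceiling: float = 0.010  # held-out per-pixel MSE


@dataclasses.dataclass
class CoderSpec:
    encoder: Sequential
    decoder: Sequential
    config: CoderConfig
    loss_trace: list[float]
    holdout_error: float

    @property
    def trained(self) -> bool:
        return len(self.loss_trace) > 0


def _build_coder(cfg: CoderConfig, rng: np.random.Generator) -> tuple[Sequential, Sequential]:
    c1, c2 = cfg.channels
    enc = Sequential([
        Conv2d(3, c1, 3, "enc1", rng), ReLU(), AvgPool2d(),
        Conv2d(c1, c2, 3, "enc2", rng), ReLU(),
    ])
    dec = Sequential([
        Conv2d(c2, c1, 3, "dec1", rng), ReLU(), UpsampleNearest(),
        Conv2d(c1, 3, 3, "dec2", rng), Sigmoid(),
    ])
    return enc, dec


def train_coder(images: list[np.ndarray], config: CoderConfig | None = None,
                seed: int = 0) -> CoderSpec:
    """Train the autoencoder by reconstruction MSE on a mixed image pool.

    ``images`` should mix fundus renderings and style textures so the
    feature space covers both input domains.  Raises
    :class:`TrainingError` if the held-out reconstruction error stays above
    the configured ceiling.
    """
    cfg = config or CoderConfig()
    if len(images) < 64:
        raise ValueError(f"need >= 64 training images, got {len(images)}")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 23])))
    enc, dec = _build_coder(cfg, rng)
    model = Sequential([enc, dec])

    x = np.stack([nchw(resize(to_float(im), cfg.work_size)) for im in images])
    n_hold = max(1, int(round(cfg.holdout_fraction * len(x))))
    perm = rng.permutation(len(x))
    x_hold, x_train = x[perm[:n_hold]], x[perm[n_hold:]]

    opt = Adam(model, lr=cfg.lr)
    trace: list[float] = []
    for _ in range(cfg.epochs):
        order = rng.permutation(len(x_train))
        losses = []
        for start in range(0, len(x_train), cfg.batch_size):
            xb = x_train[order[start:start + cfg.batch_size]]
            model.zero_grad()
            out = model.forward(xb)
            diff = out - xb
            losses.append(float(np.mean(diff ** 2)))
            model.backward((2.0 * diff / diff.size).astype(np.float32))
            opt.step()
        trace.append(float(np.mean(losses)))
    hold_out = model.forward(x_hold)
    hold_err = float(np.mean((hold_out - x_hold) ** 2))
    if hold_err > cfg.error_ceiling:
        raise TrainingError(
            f"coder did not converge: held-out MSE {hold_err:.5f} > "
            f"ceiling {cfg.error_ceiling}; loss trace {trace}"
        )
    return CoderSpec(enc, dec, cfg, trace, hold_err)


def save_coder(spec: CoderSpec, path: str | Path) -> None:
    path = Path(path)
    arrays = {f"enc::{k}": v for k, v in spec.encoder.named_params().items()}
    arrays.update({f"dec::{k}": v for k, v in spec.decoder.named_params().items()})
    np.savez(path.with_suffix(".npz"), **arrays)
    meta = dataclasses.asdict(spec.config)
    meta.update({"loss_trace": spec.loss_trace, "holdout_error": spec.holdout_error})
    path.with_suffix(".json").write_text(json.dumps(meta))


def load_coder(path: str | Path) -> CoderSpec:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    trace = meta.pop("loss_trace")
    err = meta.pop("holdout_error")
    meta["channels"] = tuple(meta["channels"])
    cfg = CoderConfig(**meta)
    enc, dec = _build_coder(cfg, np.random.default_rng(0))
    with np.load(path.with_suffix(".npz")) as arch:
        enc.set_params({k[5:]: arch[k] for k in arch.files if k.startswith("enc::")})
        dec.set_params({k[5:]: arch[k] for k in arch.files if k.startswith("dec::")})
    return CoderSpec(enc, dec, cfg, trace, err)


# ---------------------------------------------------------------------------
# Stylization
# ---------------------------------------------------------------------------


def stylize(content_image: np.ndarray, style_image: np.ndarray, alpha: float,
            coder: CoderSpec) -> np.ndarray:
    """Encode both images, align statistics via AdaIN, decode.

    Content is processed at ``coder.config.content_size`` and the style at
    the smaller ``style_size`` (preserving the content's global layout while
    borrowing coarse style statistics), then resized back to the content's
    original side.  Returns uint8 RGB.
    """
    if not coder.trained:
        raise RuntimeError("coder has not been trained")
    content = to_float(content_image)
    orig_size = content.shape[0]
    cw = nchw(resize(content, coder.config.content_size))
    sw = nchw(resize(to_float(style_image), coder.config.style_size))
    f_c = coder.encoder.forward(cw[None])[0]
    f_s = coder.encoder.forward(sw[None])[0]
    f_t = adain(f_c, f_s, alpha)
    out = coder.decoder.forward(f_t[None].astype(np.float32))[0]
    return to_uint8(resize(hwc(out), orig_size))


@dataclasses.dataclass
class StylizedCache:
    """Index of pre-synthesized stylized variants, keyed by image_id."""

    index: pd.DataFrame  # columns: image_id, variant_path, style_id, alpha

    def variants(self, image_id: str) -> list[str]:
        rows = self.index[self.index["image_id"] == image_id]
        if rows.empty:
            raise KeyError(f"no stylized variants cached for {image_id}")
        return rows["variant_path"].tolist()

    def __len__(self) -> int:
        return len(self.index)

    def save(self, path: str | Path) -> None:
        self.index.to_csv(path, index=False)


def load_cache(path: str | Path) -> StylizedCache:
    df = pd.read_csv(path, dtype={"image_id": str, "variant_path": str})
    return StylizedCache(df)


def precompute_stylized(
    manifest: Manifest,
    style_bank: list[np.ndarray],
    variants_per_image: int,
    alpha: float,
    coder: CoderSpec,
    out_dir: str | Path,
    seed: int,
) -> StylizedCache:
    """Pre-synthesize stylized variants for every record (styles drawn
    without replacement within an image, independently across images)."""
    if variants_per_image < 1:
        raise ValueError("variants_per_image must be >= 1")
    if len(style_bank) == 0:
        raise ValueError("style bank is empty")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, rec in enumerate(manifest):
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, i, 3])))
        replace = variants_per_image > len(style_bank)
        picks = rng.choice(len(style_bank), size=variants_per_image, replace=replace)
        content = load_image(rec.path)
        for j, sid in enumerate(picks):
            var = stylize(content, style_bank[int(sid)], alpha, coder)
            vpath = out_dir / f"{rec.image_id}_v{j}.png"
            save_image(var, vpath)
            rows.append({"image_id": rec.image_id, "variant_path": str(vpath),
                         "style_id": int(sid), "alpha": alpha})
    cache = StylizedCache(pd.DataFrame(rows))
    cache.save(out_dir / "stylized_index.csv")
    return cache
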