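"""SimCLR-style contrastive pretraining with style-transfer augmentation.

Each source image yields two independently augmented views; the encoder
and a 2-layer projection head map views to 128-dim embeddings z, and the
normalized temperature-scaled cross-entropy (NT-Xent) loss pulls the two
views of one image together against all other views in the batch:

    loss_{i,j} = -log  exp(sim(z_i, z_j)/tau)
                       -----------------------------------
                       sum_{k != i} exp(sim(z_i, z_k)/tau)

averaged over all 2N ordered positive pairs, with sim the cosine
similarity.  With probability ``nst_probability`` (0.70) a view starts
from a pre-synthesized stylized variant of the source instead of the
original, then passes through the regular augmentation chain
(crop-with-resize, flips, rotation up to 30 degrees, color jitter of
strength 0.5, Gaussian blur).  Optimization uses LARS, the layer-wise
trust-ratio method for large-batch stability.
"""

from __future__ import annotations

import dataclasses
import json
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy import ndimage

from .datasets import ImageRecord, Manifest
from .imutils import load_image, nchw, resize, to_float
from .models import build_encoder, build_projection_head, encoder_h_dim
from .nn import LARS, Sequential
from .nst import StylizedCache

__all__ = [
    "AugmentationPolicy",
    "ViewPair",
    "EmbeddingBatch",
    "PretrainConfig",
    "Checkpoint",
    "regular_augment",
    "make_view_pair",
    "embed",
    "nt_xent_loss",
    "nt_xent_loss_and_grad",
    "pretrain",
    "save_checkpoint",
    "load_checkpoint",
    "desk_pretrain_config",
]


@dataclasses.dataclass
class AugmentationPolicy:
    nst_probability: float = 0.70
    rotation_max_deg: float = 30.0
    jitter_strength: float = 0.5
    color_jitter_probability: float = 0.8
    blur_probability: float = 0.5
    blur_sigma: tuple[float, float] = (0.1, 1.0)
    crop_scale: tuple[float, float] = (0.7, 1.0)
    hflip_probability: float = 0.5
    vflip_probability: float = 0.5
    output_size: int = 224

    def __post_init__(self) -> None:
        for p in (self.nst_probability, self.color_jitter_probability,
                  self.blur_probability, self.hflip_probability,
                  self.vflip_probability):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.output_size <= 0:
            raise ValueError("output_size must be positive")


@dataclasses.dataclass
class ViewPair:
    view_i: np.ndarray
    view_j: np.ndarray
    image_id: str


@dataclasses.dataclass
class EmbeddingBatch:
    h: np.ndarray            # (2N, h_dim) pooled encoder outputs
    z: np.ndarray            # (2N, 128) projected embeddings
    pair_index: np.ndarray   # partner view of each row; an involution

    def __post_init__(self) -> None:
        p = self.pair_index
        if not (np.all(p[p] == np.arange(len(p))) and np.all(p != np.arange(len(p)))):
            raise ValueError("pair_index must be a fixed-point-free involution")


def regular_augment(
    image: np.ndarray,
    policy: AugmentationPolicy,
    rng: np.random.Generator,
    log: list | None = None,
) -> np.ndarray:
    """Crop-with-resize, flips, rotation, color jitter, blur, final resize.

    Deterministic given the rng state; draw records can be captured via
    ``log`` for auditing.
    """
    img = to_float(image)
    h, w = img.shape[:2]
    draws: dict[str, float] = {}

    scale = float(rng.uniform(*policy.crop_scale))
    side = max(1, int(round(scale * min(h, w))))
    top = int(rng.integers(0, h - side + 1))
    left = int(rng.integers(0, w - side + 1))
    img = img[top:top + side, left:left + side]
    draws["crop_scale"] = scale

    if rng.uniform() < policy.hflip_probability:
        img = img[:, ::-1]
        draws["hflip"] = 1.0
    if rng.uniform() < policy.vflip_probability:
        img = img[::-1, :]
        draws["vflip"] = 1.0

    angle = float(rng.uniform(-policy.rotation_max_deg, policy.rotation_max_deg))
    draws["rotation_deg"] = angle
    if angle != 0.0:
        img = ndimage.rotate(img, angle, reshape=False, order=1, mode="constant")

    if rng.uniform() < policy.color_jitter_probability:
        s = policy.jitter_strength
        bright = 1.0 + float(rng.uniform(-0.8 * s, 0.8 * s))
        contrast = 1.0 + float(rng.uniform(-0.8 * s, 0.8 * s))
        chan = 1.0 + rng.uniform(-s, s, size=3)
        mean = img.mean()
        img = (mean + (img * bright - mean) * contrast) * chan[None, None, :]
        draws["jitter_brightness"] = bright

    if rng.uniform() < policy.blur_probability:
        sigma = float(rng.uniform(*policy.blur_sigma))
        img = ndimage.gaussian_filter(img, sigma=(sigma, sigma, 0))
        draws["blur_sigma"] = sigma

    img = np.clip(img, 0.0, 1.0)
    if img.shape[0] != policy.output_size:
        img = resize(img, policy.output_size)
    if log is not None:
        log.append(draws)
    return img.astype(np.float32)


@lru_cache(maxsize=4096)
def _cached_image(path: str) -> np.ndarray:
    arr = load_image(path)
    arr.setflags(write=False)
    return arr


def make_view_pair(
    record: ImageRecord,
    policy: AugmentationPolicy,
    cache: StylizedCache | None,
    rng: np.random.Generator,
    log: list | None = None,
) -> ViewPair:
    """Two independent views: each starts from a stylized variant with
    probability ``nst_probability``, else the original, then is regularly
    augmented."""
    views = []
    for _ in range(2):
        use_nst = rng.uniform() < policy.nst_probability
        if use_nst:
            if cache is None:
                raise KeyError(
                    f"nst_probability > 0 but no stylized cache for {record.image_id}"
                )
            variants = cache.variants(record.image_id)
            src = _cached_image(variants[int(rng.integers(len(variants)))])
        else:
            src = _cached_image(record.path)
        if log is not None:
            log.append({"image_id": record.image_id, "stylized": use_nst})
        views.append(regular_augment(src, policy, rng))
    return ViewPair(views[0], views[1], record.image_id)


# ---------------------------------------------------------------------------
# Embedding and loss
# ---------------------------------------------------------------------------


def embed(views: np.ndarray, encoder: Sequential, head: Sequential) -> EmbeddingBatch:
    """Forward a (2N, 3, H, W) view stack; rows 2i and 2i+1 are partners."""
    n2 = views.shape[0]
    if n2 % 2:
        raise ValueError("view stack must contain an even number of rows")
    h = encoder.forward(views.astype(np.float32))
    z = head.forward(h)
    pair = np.arange(n2) ^ 1
    return EmbeddingBatch(h=h, z=z, pair_index=pair)


def nt_xent_loss(z: np.ndarray, pair_index: np.ndarray, tau: float = 0.5) -> float:
    """Mean NT-Xent loss over the 2N ordered positive pairs."""
    loss, _ = nt_xent_loss_and_grad(z, pair_index, tau)
    return loss


def nt_xent_loss_and_grad(
    z: np.ndarray, pair_index: np.ndarray, tau: float = 0.5
) -> tuple[float, np.ndarray]:
    """Loss plus its gradient with respect to the (unnormalized) z rows."""
    if tau <= 0:
        raise ValueError("temperature must be positive")
    z = np.asarray(z, dtype=np.float64)
    n2 = z.shape[0]
    if n2 < 2:
        raise ValueError("need at least one positive pair (2 rows)")
    norms = np.linalg.norm(z, axis=1)
    bad = np.flatnonzero(norms == 0)
    if bad.size:
        raise FloatingPointError(
            f"zero-norm embedding rows {bad.tolist()}: cosine similarity undefined"
        )
    u = z / norms[:, None]
    s = (u @ u.T) / tau
    np.fill_diagonal(s, -np.inf)
    m = s.max(axis=1, keepdims=True)
    exp = np.exp(s - m)
    denom = exp.sum(axis=1)
    logprob = s[np.arange(n2), pair_index] - (m[:, 0] + np.log(denom))
    loss = float(-logprob.mean())

    p = exp / denom[:, None]          # softmax over k != i (diagonal is 0)
    p[np.arange(n2), pair_index] -= 1.0
    ds = p / n2
    du = ((ds + ds.T) @ u) / tau
    dz = (du - u * (u * du).sum(axis=1, keepdims=True)) / norms[:, None]
    return loss, dz.astype(np.float32)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class PretrainConfig:
    batch_size: int = 2048
    tau: float = 0.5
    epochs: int = 100
    learning_rate: float = 0.3
    weight_decay: float = 1e-5
    momentum: float = 0.9
    trust_coefficient: float = 0.001
    encoder_name: str = "small"
    saturation_tol: float = 1e-3
    saturation_window: int = 10
    policy: AugmentationPolicy = dataclasses.field(default_factory=AugmentationPolicy)

    def __post_init__(self) -> None:
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2 for a nonzero negative set")
        if self.tau <= 0:
            raise ValueError("temperature must be positive")


def desk_pretrain_config(**overrides) -> PretrainConfig:
    """CPU-scale preset: 32 px views, small encoder, batch 32."""
    policy = overrides.pop("policy", AugmentationPolicy(output_size=32))
    # lower base_lr than the large-batch default: biases are exempt from
    # trust-ratio scaling, so base_lr alone sets their step size; the larger
    # trust coefficient keeps weight steps near 0.1% of the layer norm.
    # Saturation stopping is disabled: at this scale the loss sits on a
    # plateau for tens of epochs before view-matching features emerge, and
    # a plateau detector would stop training right there.
    base = dict(
        batch_size=32, epochs=50, learning_rate=0.01, trust_coefficient=0.1,
        saturation_tol=-1.0, saturation_window=8, policy=policy,
    )
    base.update(overrides)
    return PretrainConfig(**base)


@dataclasses.dataclass
class Checkpoint:
    encoder_arrays: dict[str, np.ndarray]
    head_arrays: dict[str, np.ndarray]
    config: dict
    epoch: int
    loss_trace: list[float]


def init_models(encoder_name: str, seed: int):
    """Seeded encoder + projection head plus the training data RNG."""
    ss = np.random.SeedSequence([seed, 41])
    init_rng, data_rng = (np.random.Generator(np.random.PCG64(c))
                          for c in ss.spawn(2))
    encoder = build_encoder(encoder_name, init_rng)
    head = build_projection_head(encoder_h_dim(encoder_name), init_rng)
    return encoder, head, data_rng


class _Composite:
    """Exposes encoder + head parameters as one optimizer target."""

    def __init__(self, encoder: Sequential, head: Sequential) -> None:
        self.encoder, self.head = encoder, head

    def named_params(self):
        return {**{f"encoder::{k}": v for k, v in self.encoder.named_params().items()},
                **{f"head::{k}": v for k, v in self.head.named_params().items()}}

    def named_grads(self):
        return {**{f"encoder::{k}": v for k, v in self.encoder.named_grads().items()},
                **{f"head::{k}": v for k, v in self.head.named_grads().items()}}

    def set_params(self, arrays):
        self.encoder.set_params(
            {k[9:]: v for k, v in arrays.items() if k.startswith("encoder::")})
        self.head.set_params(
            {k[6:]: v for k, v in arrays.items() if k.startswith("head::")})


def pretrain(
    manifest: Manifest,
    cache: StylizedCache | None,
    config: PretrainConfig,
    seed: int,
) -> Checkpoint:
    """Run contrastive pretraining; stops at ``epochs`` or when the loss
    saturates (relative improvement over the saturation window below
    ``saturation_tol``)."""
    if len(manifest) == 0:
        raise ValueError("manifest is empty")
    if config.batch_size > len(manifest):
        raise ValueError("batch_size exceeds dataset size")
    encoder, head, data_rng = init_models(config.encoder_name, seed)
    model = _Composite(encoder, head)
    opt = LARS(model, base_lr=config.learning_rate,
               weight_decay=config.weight_decay,
               trust_coefficient=config.trust_coefficient,
               momentum=config.momentum)

    trace: list[float] = []
    records = list(manifest)
    epoch = 0
    for epoch in range(1, config.epochs + 1):
        order = data_rng.permutation(len(records))
        losses = []
        for start in range(0, len(records), config.batch_size):
            idx = order[start:start + config.batch_size]
            if len(idx) < 2:
                continue
            views = []
            for i in idx:
                pair = make_view_pair(records[i], config.policy, cache, data_rng)
                views.append(nchw(pair.view_i))
                views.append(nchw(pair.view_j))
            batch = np.stack(views)
            encoder.zero_grad()
            head.zero_grad()
            emb = embed(batch, encoder, head)
            loss, dz = nt_xent_loss_and_grad(emb.z, emb.pair_index, config.tau)
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}: {trace}")
            dh = head.backward(dz)
            encoder.backward(dh)
            opt.step()
            losses.append(loss)
        trace.append(float(np.mean(losses)))
        w = config.saturation_window
        if len(trace) > w:
            prev, cur = trace[-w - 1], trace[-1]
            if (prev - cur) / max(abs(prev), 1e-12) < config.saturation_tol:
                break

    cfg = dataclasses.asdict(config)
    cfg["policy"] = dataclasses.asdict(config.policy)
    return Checkpoint(
        encoder_arrays={k: v.copy() for k, v in encoder.named_params().items()},
        head_arrays={k: v.copy() for k, v in head.named_params().items()},
        config=cfg,
        epoch=epoch if config.epochs else 0,
        loss_trace=trace,
    )


def save_checkpoint(ckpt: Checkpoint, path: str | Path) -> None:
    path = Path(path)
    arrays = {f"encoder::{k}": v for k, v in ckpt.encoder_arrays.items()}
    arrays.update({f"head::{k}": v for k, v in ckpt.head_arrays.items()})
    np.savez(path.with_suffix(".npz"), **arrays)
    path.with_suffix(".json").write_text(
        json.dumps({"config": ckpt.config, "epoch": ckpt.epoch,
                    "loss_trace": ckpt.loss_trace})
    )


def load_checkpoint(path: str | Path) -> Checkpoint:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    with np.load(path.with_suffix(".npz")) as arch:
        enc = {k[9:]: arch[k].copy() for k in arch.files if k.startswith("encoder::")}
        head = {k[6:]: arch[k].copy() for k in arch.files if k.startswith("head::")}
    return Checkpoint(enc, head, meta["config"], meta["epoch"], meta["loss_trace"])
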