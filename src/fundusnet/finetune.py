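"""Supervised fine-tuning for referable vs non-referable DR.

The pretrained encoder's weights are transferred one-to-one (the
projection head is discarded — transfer happens at the h representation,
before the head), a fresh two-logit classification head is attached, and
the whole network is trained with cross-entropy and Adam under on-the-fly
augmentation (rotation up to 30 degrees, horizontal flips, color
distortion).  Model selection keeps the epoch with the best validation
AUC.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .datasets import Manifest, subsample_label_fraction
from .evaluate import roc_auc
from .imutils import nchw, resize
from .models import build_classifier_head, build_encoder, encoder_h_dim
from .nn import Adam, Sequential
from .pretrain import AugmentationPolicy, Checkpoint, _cached_image, regular_augment

__all__ = [
    "FinetuneConfig",
    "ClassifierModel",
    "TransferError",
    "build_classifier",
    "transfer_weights",
    "finetune",
    "predict",
    "hyperparameter_search",
    "label_fraction_experiment",
    "desk_finetune_config",
]


class TransferError(RuntimeError):
    pass


def _finetune_policy(output_size: int = 224) -> AugmentationPolicy:
    # rotations, horizontal flips and color distortion only
    return AugmentationPolicy(
        nst_probability=0.0, vflip_probability=0.0, blur_probability=0.0,
        crop_scale=(1.0, 1.0), output_size=output_size,
    )


@dataclasses.dataclass
class FinetuneConfig:
    batch_size: int = 256
    learning_rate: float = 1e-3
    weight_decay: float = 1e-4
    epochs: int = 10
    lr_grid: tuple[float, ...] = (1e-6, 1e-5, 1e-4, 1e-3, 1e-2)
    wd_grid: tuple[float, ...] = (1e-5, 1e-4, 1e-3)
    label_fraction: float = 1.0
    train_encoder: bool = True   # False = linear probe on frozen features
    policy: AugmentationPolicy = dataclasses.field(default_factory=_finetune_policy)

    def __post_init__(self) -> None:
        if not self.lr_grid or not self.wd_grid:
            raise ValueError("hyperparameter grids must be non-empty")
        if not 0.0 < self.label_fraction <= 1.0:
            raise ValueError("label_fraction must lie in (0, 1]")


def desk_finetune_config(**overrides) -> FinetuneConfig:
    base = dict(batch_size=16, epochs=8, learning_rate=3e-3,
                policy=_finetune_policy(output_size=32))
    base.update(overrides)
    return FinetuneConfig(**base)


@dataclasses.dataclass
class ClassifierModel:
    encoder: Sequential
    head: Sequential
    encoder_name: str
    image_size: int
    provenance: str = "random"   # random | fundusnet | external-init

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.head.forward(self.encoder.forward(x))

    def copy(self) -> "ClassifierModel":
        clone = build_classifier(self.encoder_name, seed=0,
                                 image_size=self.image_size)
        clone.encoder.set_params({k: v.copy() for k, v in
                                  self.encoder.named_params().items()})
        clone.head.set_params({k: v.copy() for k, v in
                               self.head.named_params().items()})
        clone.provenance = self.provenance
        return clone


def build_classifier(encoder_name: str, seed: int, image_size: int = 224,
                     provenance: str = "random") -> ClassifierModel:
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 71])))
    encoder = build_encoder(encoder_name, rng)
    head = build_classifier_head(encoder_h_dim(encoder_name), rng)
    return ClassifierModel(encoder, head, encoder_name, image_size, provenance)


def transfer_weights(checkpoint: Checkpoint, model: ClassifierModel) -> ClassifierModel:
    """Copy every encoder layer bit-exactly; the projection head is not
    carried over and the classification head keeps its fresh init."""
    ckpt_encoder = checkpoint.config.get("encoder_name")
    if ckpt_encoder is not None and ckpt_encoder != model.encoder_name:
        raise TransferError(
            f"checkpoint encoder '{ckpt_encoder}' does not match model "
            f"encoder '{model.encoder_name}'"
        )
    own = model.encoder.named_params()
    theirs = checkpoint.encoder_arrays
    if set(own) != set(theirs):
        raise TransferError(
            f"encoder layer names differ: only in model "
            f"{sorted(set(own) - set(theirs))}, only in checkpoint "
            f"{sorted(set(theirs) - set(own))}"
        )
    bad_shapes = [k for k in own if own[k].shape != theirs[k].shape]
    if bad_shapes:
        raise TransferError(f"encoder layer shapes differ: {bad_shapes}")
    model.encoder.set_params({k: v.copy() for k, v in
                              checkpoint.encoder_arrays.items()})
    model.provenance = "fundusnet"
    return model


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def _load_batch(records, policy, rng) -> np.ndarray:
    return np.stack([nchw(regular_augment(_cached_image(r.path), policy, rng))
                     for r in records])


def _softmax(logits: np.ndarray) -> np.ndarray:
    e = np.exp(logits - logits.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def finetune(
    train_manifest: Manifest,
    val_manifest: Manifest,
    init: ClassifierModel,
    config: FinetuneConfig,
    seed: int,
) -> tuple[ClassifierModel, pd.DataFrame]:
    """Train with cross-entropy/Adam; return the epoch with best validation
    AUC plus the full history (epoch, train_loss, val_auc)."""
    if len(train_manifest) == 0 or len(val_manifest) == 0:
        raise ValueError("manifests must be non-empty")
    overlap = {r.image_id for r in train_manifest} & {r.image_id for r in val_manifest}
    if overlap:
        raise ValueError(f"train/validation manifests overlap: {sorted(overlap)[:5]}")
    model = init.copy()
    if config.epochs == 0:
        return model, pd.DataFrame(columns=["epoch", "train_loss", "val_auc"])
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 83])))
    opt = Adam(model.head if not config.train_encoder else _FullModel(model),
               lr=config.learning_rate, weight_decay=config.weight_decay)

    records = list(train_manifest)
    y = train_manifest.labels.astype(int)
    rows, best_auc, best_arrays = [], -np.inf, None
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(records))
        losses = []
        for start in range(0, len(records), config.batch_size):
            idx = order[start:start + config.batch_size]
            xb = _load_batch([records[i] for i in idx], config.policy, rng)
            yb = y[idx]
            model.encoder.zero_grad()
            model.head.zero_grad()
            logits = model.forward(xb)
            p = _softmax(logits)
            eps = 1e-12
            losses.append(float(-np.mean(np.log(p[np.arange(len(yb)), yb] + eps))))
            dlogits = p.copy()
            dlogits[np.arange(len(yb)), yb] -= 1.0
            dlogits /= len(yb)
            dh = model.head.backward(dlogits.astype(np.float32))
            if config.train_encoder:
                model.encoder.backward(dh)
            opt.step()
        val_auc = roc_auc(predict(model, val_manifest), val_manifest.labels).auc
        rows.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                     "val_auc": val_auc})
        if val_auc > best_auc:
            best_auc = val_auc
            best_arrays = (
                {k: v.copy() for k, v in model.encoder.named_params().items()},
                {k: v.copy() for k, v in model.head.named_params().items()},
            )
    if best_arrays is not None:
        model.encoder.set_params(best_arrays[0])
        model.head.set_params(best_arrays[1])
    return model, pd.DataFrame(rows)


class _FullModel:
    def __init__(self, model: ClassifierModel) -> None:
        self.model = model

    def named_params(self):
        return {**{f"enc::{k}": v for k, v in self.model.encoder.named_params().items()},
                **{f"cls::{k}": v for k, v in self.model.head.named_params().items()}}

    def named_grads(self):
        return {**{f"enc::{k}": v for k, v in self.model.encoder.named_grads().items()},
                **{f"cls::{k}": v for k, v in self.model.head.named_grads().items()}}


def predict(model: ClassifierModel, manifest: Manifest,
            batch_size: int = 64) -> np.ndarray:
    """Referable probability per record, order-aligned with the manifest."""
    scores = []
    records = list(manifest)
    for start in range(0, len(records), batch_size):
        chunk = records[start:start + batch_size]
        xs = []
        for r in chunk:
            try:
                img = _cached_image(r.path)
            except OSError as exc:
                raise OSError(f"cannot read image for record {r.image_id}: {exc}")
            xs.append(nchw(resize(img, model.image_size)))
        logits = model.forward(np.stack(xs))
        scores.extend(_softmax(logits)[:, 1].tolist())
    return np.asarray(scores)


# ---------------------------------------------------------------------------
# Experiments
# ---------------------------------------------------------------------------


def hyperparameter_search(
    folds: list[tuple[Manifest, Manifest]],
    init: ClassifierModel,
    config: FinetuneConfig,
    seed: int = 0,
) -> tuple[tuple[float, float], pd.DataFrame]:
    """Grid search over (learning rate, weight decay) by mean CV AUC.

    Ties break toward the smaller learning rate, then smaller weight decay.
    """
    rows = []
    for lr in config.lr_grid:
        for wd in config.wd_grid:
            cfg = dataclasses.replace(config, learning_rate=lr, weight_decay=wd)
            for f, (tr, va) in enumerate(folds):
                _, hist = finetune(tr, va, init, cfg, seed=seed + f)
                auc = float(hist["val_auc"].max()) if len(hist) else 0.5
                rows.append({"lr": lr, "wd": wd, "fold": f, "val_auc": auc})
    table = pd.DataFrame(rows)
    means = table.groupby(["lr", "wd"])["val_auc"].mean().reset_index()
    means = means.sort_values(["val_auc", "lr", "wd"],
                              ascending=[False, True, True],
                              kind="mergesort")
    best = means.iloc[0]
    return (float(best["lr"]), float(best["wd"])), table


def label_fraction_experiment(
    manifest: Manifest,
    fractions: list[float],
    seeds: list[int],
    pretrain_checkpoint: Checkpoint,
    config: FinetuneConfig,
    val_manifest: Manifest,
    test_manifest: Manifest,
) -> pd.DataFrame:
    """Label-efficiency curve: for each fraction x seed x init in
    {fundusnet, random}, subsample the labeled training set, fine-tune,
    and score AUC on the fixed held-out test manifest."""
    enc_name = pretrain_checkpoint.config.get("encoder_name", "small")
    img_size = config.policy.output_size
    rows = []
    for frac in fractions:
        for seed in seeds:
            sub = subsample_label_fraction(manifest, frac, seed)
            for provenance in ("fundusnet", "random"):
                model = build_classifier(enc_name, seed=seed, image_size=img_size)
                if provenance == "fundusnet":
                    model = transfer_weights(pretrain_checkpoint, model)
                trained, _ = finetune(sub, val_manifest, model, config, seed)
                auc = roc_auc(predict(trained, test_manifest),
                              test_manifest.labels).auc
                rows.append({"fraction": frac, "seed": seed,
                             "init": provenance, "auc": auc})
    return pd.DataFrame(rows)
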