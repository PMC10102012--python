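"""Desk-scale end-to-end benchmark on the synthetic fundus dataset.

The benchmark reproduces the structure of the label-efficiency study at
CPU scale: generate a texture-confounded synthetic cohort, pretrain the
encoder contrastively (with and without style-transfer augmentation),
fine-tune on a 10% label fraction against a random-init control, and
score held-out AUC.  The expected ordering — stylized pretraining beats
random initialization at low label fractions, and is at least as good as
pretraining without style transfer — is the qualitative twin of the
full-scale findings.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import Manifest, subsample_label_fraction
from .evaluate import roc_auc
from .finetune import (
    build_classifier,
    desk_finetune_config,
    finetune,
    predict,
    transfer_weights,
)
from .nst import CoderConfig, precompute_stylized, train_coder
from .pretrain import desk_pretrain_config, pretrain
from .synthgen import SynthParams, generate_dataset, generate_fundus, generate_style_bank

__all__ = ["BenchmarkResult", "run_desk_benchmark", "stratified_partition"]

#: EyePACS-like class imbalance (roughly 4.4 non-referable per referable)
GRADE_DISTRIBUTION = (0.55, 0.26, 0.11, 0.05, 0.03)


def stratified_partition(manifest: Manifest, sizes: list[int], seed: int) -> list[Manifest]:
    """Disjoint stratified-by-referable partition into len(sizes) manifests."""
    if sum(sizes) > len(manifest):
        raise ValueError("partition sizes exceed manifest")
    y = manifest.labels
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 29])))
    pools = {c: list(rng.permutation(np.flatnonzero(y == c))) for c in (False, True)}
    frac_pos = y.mean()
    parts = []
    for size in sizes:
        n_pos = min(int(round(size * frac_pos)), len(pools[True]))
        n_neg = min(size - n_pos, len(pools[False]))
        take = [pools[True].pop() for _ in range(n_pos)]
        take += [pools[False].pop() for _ in range(n_neg)]
        take += [pools[True].pop() for _ in range(size - len(take))]
        parts.append(manifest.subset(sorted(int(i) for i in take)))
    return parts


@dataclasses.dataclass
class BenchmarkResult:
    per_seed: pd.DataFrame   # seed, init, auc
    mean_auc: dict[str, float]

    def mean(self, init: str) -> float:
        return self.mean_auc[init]


def _run_one_seed(work: Path, seed: int, n_images: int, image_size: int,
                  label_fraction: float, pretrain_epochs: int,
                  finetune_epochs: int) -> dict[str, float]:
    params = SynthParams(image_size=image_size)
    manifest = generate_dataset(n_images, GRADE_DISTRIBUTION, params,
                                work / f"data_{seed}", seed=seed)
    n_test = max(1, n_images // 5)
    n_val = max(1, int(n_images * 0.15))
    n_pool = len(manifest) - n_test - n_val
    pool, val, test = stratified_partition(manifest, [n_pool, n_val, n_test], seed)

    bank = generate_style_bank(24, image_size, seed=seed + 1)
    coder_pool = [generate_fundus(params, i % 5, 10_000 + seed * 100 + i).image
                  for i in range(96)] + bank
    coder = train_coder(coder_pool, CoderConfig(content_size=image_size,
                                                style_size=image_size), seed=seed)
    cache = precompute_stylized(pool, bank, variants_per_image=2, alpha=1.0,
                                coder=coder, out_dir=work / f"cache_{seed}",
                                seed=seed)

    results: dict[str, float] = {}
    checkpoints = {}
    for label, nst_p in (("nst", 0.70), ("no_nst", 0.0)):
        cfg = desk_pretrain_config(epochs=pretrain_epochs)
        cfg.policy.nst_probability = nst_p
        cfg.policy.output_size = image_size
        checkpoints[label] = pretrain(pool, cache if nst_p > 0 else None, cfg, seed)

    labeled = subsample_label_fraction(pool, label_fraction, seed)
    ft_cfg = desk_finetune_config(epochs=finetune_epochs)
    ft_cfg.policy.output_size = image_size
    for init_name in ("nst", "no_nst", "random"):
        model = build_classifier("small", seed=seed, image_size=image_size)
        if init_name != "random":
            model = transfer_weights(checkpoints[init_name], model)
        trained, _ = finetune(labeled, val, model, ft_cfg, seed)
        results[init_name] = roc_auc(predict(trained, test), test.labels).auc
    return results


def run_desk_benchmark(
    work_dir: str | Path,
    seeds: list[int],
    n_images: int = 600,
    image_size: int = 32,
    label_fraction: float = 0.1,
    pretrain_epochs: int = 20,
    finetune_epochs: int = 8,
) -> BenchmarkResult:
    """Run the pretrain/fine-tune contrast for each seed; returns held-out
    AUCs for the three initializations (nst, no_nst, random)."""
    work = Path(work_dir)
    work.mkdir(parents=True, exist_ok=True)
    rows = []
    for seed in seeds:
        res = _run_one_seed(work, seed, n_images, image_size, label_fraction,
                            pretrain_epochs, finetune_epochs)
        for init, auc in res.items():
            rows.append({"seed": seed, "init": init, "auc": auc})
    table = pd.DataFrame(rows)
    means = table.groupby("init")["auc"].mean().to_dict()
    return BenchmarkResult(table, means)
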