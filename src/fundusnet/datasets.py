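"""Manifests, labels, quality screening and splits.

A manifest is the ordered list of fundus images entering an experiment:
one row per image with its 0-4 diabetic-retinopathy grade (0 no DR, 1 mild,
2 moderate, 3 severe NPDR, 4 PDR), the derived binary *referable* label
(grade >= 2, i.e. moderate NPDR or worse), and an optional split tag.

Quality screening mirrors the clinical exclusion criteria — uneven
illumination, color distortion, low contrast, motion blur, missing
fovea/optic disc — as transparent image heuristics.  Each raw measure is
divided by a calibration scale so all five scores share a common [0, 1]
range and a single exclusion threshold.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import match_template
from sklearn.model_selection import StratifiedKFold

from .imutils import luminance, to_float

__all__ = [
    "SchemaError",
    "ValidationError",
    "ImageRecord",
    "Manifest",
    "QualityReport",
    "QUALITY_CRITERIA",
    "grade_to_referable",
    "load_manifest",
    "write_manifest",
    "assess_quality",
    "apply_exclusion",
    "kfold_split",
    "subsample_label_fraction",
]

MANIFEST_COLUMNS = ["image_id", "path", "dr_grade", "referable", "split"]

QUALITY_CRITERIA = (
    "uneven_illumination",
    "color_distortion",
    "low_contrast",
    "motion_blur",
    "missing_landmarks",
)


class SchemaError(ValueError):
    """Manifest CSV is missing required columns."""


class ValidationError(ValueError):
    """Manifest rows violate the label invariants."""


def grade_to_referable(grade: int) -> bool:
    """Referable DR is moderate NPDR or worse: grade >= 2 on the 0-4 scale."""
    g = int(grade)
    if g != grade or not 0 <= g <= 4:
        raise ValueError(f"dr_grade must be an integer in 0..4, got {grade!r}")
    return g >= 2


@dataclasses.dataclass
class ImageRecord:
    image_id: str
    path: str
    dr_grade: int
    referable: bool | None = None
    split: str | None = None
    quality_flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        expected = grade_to_referable(self.dr_grade)
        if self.referable is None:
            self.referable = expected
        elif bool(self.referable) != expected:
            raise ValidationError(
                f"record {self.image_id}: referable={self.referable} contradicts "
                f"dr_grade={self.dr_grade} (referable must equal grade >= 2)"
            )


@dataclasses.dataclass
class Manifest:
    records: list[ImageRecord]
    provenance: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.image_id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate image_id values: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ImageRecord]:
        return iter(self.records)

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.referable for r in self.records], dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "image_id": r.image_id,
                    "path": r.path,
                    "dr_grade": r.dr_grade,
                    "referable": bool(r.referable),
                    "split": r.split if r.split is not None else "",
                }
                for r in self.records
            ],
            columns=MANIFEST_COLUMNS,
        )

    def subset(self, indices: Sequence[int], note: str | None = None) -> "Manifest":
        prov = dict(self.provenance)
        if note:
            prov["derived"] = note
        return Manifest([self.records[i] for i in indices], prov)


def write_manifest(manifest: Manifest, path: str | Path) -> None:
    manifest.to_frame().to_csv(path, index=False)


def load_manifest(path: str | Path, check_paths: bool = True) -> Manifest:
    """Load a manifest CSV, validating grades, labels and file paths.

    Relative image paths are resolved against the CSV's directory.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"image_id": str, "path": str},
                     keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"manifest {path} missing columns: {missing}")
    bad = df.index[~df["dr_grade"].isin([0, 1, 2, 3, 4])].tolist()
    if bad:
        raise ValidationError(f"rows {bad} have dr_grade outside 0..4")
    records = []
    for i, row in df.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = path.parent / p
        referable = str(row["referable"]).strip().lower() in ("true", "1")
        records.append(
            ImageRecord(
                image_id=row["image_id"],
                path=str(p),
                dr_grade=int(row["dr_grade"]),
                referable=referable,
                split=row["split"] or None,
            )
        )
    if check_paths:
        absent = [r.image_id for r in records if not Path(r.path).exists()]
        if absent:
            raise FileNotFoundError(f"manifest paths not resolvable: {absent}")
    return Manifest(records, provenance={"source": str(path)})


# ---------------------------------------------------------------------------
# Quality screening
# ---------------------------------------------------------------------------

#: raw-measure scales putting each criterion on a common [0, 1] score axis;
#: calibrated once on clean synthetic fixtures so that artifact-free images
#: score well below the default threshold.
DEFAULT_QUALITY_SCALES = {
    "uneven_illumination": 0.60,
    "color_distortion": 0.45,
    "low_contrast": 1.00,
    "motion_blur": 1.00,
    "missing_landmarks": 1.00,
}

#: channel share (r, g, b of total intensity) of a healthy fundus photograph
_REFERENCE_CHROMATICITY = np.array([0.55, 0.30, 0.15])

DEFAULT_QUALITY_THRESHOLD = 0.80


@dataclasses.dataclass
class QualityReport:
    scores: dict[str, float]
    primary_criterion: str
    excluded: bool
    threshold: float

    def __post_init__(self) -> None:
        mx = max(self.scores.values())
        assert abs(self.scores[self.primary_criterion] - mx) < 1e-12
        assert self.excluded == (mx >= self.threshold)


def _aperture_mask(img: np.ndarray) -> np.ndarray:
    lum = luminance(img)
    mask = lum > 0.04
    if mask.sum() < 16:  # nearly black frame: fall back to everything
        mask = np.ones_like(mask)
    return mask


def assess_quality(
    image: np.ndarray,
    threshold: float = DEFAULT_QUALITY_THRESHOLD,
    scales: dict[str, float] | None = None,
) -> QualityReport:
    """Score the five exclusion criteria on an RGB fundus image.

    Raw measures: (a) range of a coarse low-pass luminance field inside the
    aperture (uneven illumination); (b) one minus the luminance
    interquartile range (low contrast); (c) one minus the variance of a
    Laplacian response (motion blur); (d) channel-mean imbalance (color
    distortion); (e) one minus the peak normalized correlation with a
    bright-disc template (missing optic disc / fovea landmarks).  Each is
    divided by its calibration scale and clipped to [0, 1].
    """
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("assess_quality expects an RGB image (H, W, 3)")
    img = to_float(image)
    scales = dict(DEFAULT_QUALITY_SCALES, **(scales or {}))
    lum = luminance(img)
    mask = _aperture_mask(img)
    size = img.shape[0]

    lp = ndimage.gaussian_filter(lum, sigma=max(2.0, size / 8.0))
    vals = lp[mask]
    raw_illum = float(np.percentile(vals, 98) - np.percentile(vals, 2))

    iqr = float(np.percentile(lum[mask], 75) - np.percentile(lum[mask], 25))
    raw_contrast = 1.0 - min(iqr / 0.18, 1.0)

    lap = ndimage.laplace(lum)
    raw_blur = 1.0 - min(float(lap[mask].var()) / 2.5e-3, 1.0)

    means = img[mask].mean(axis=0)
    share = means / (means.sum() + 1e-9)
    raw_color = float(np.abs(share - _REFERENCE_CHROMATICITY).sum() / 2.0)

    r = max(3, int(round(size * 0.09)))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    template = (yy ** 2 + xx ** 2 <= r ** 2).astype(np.float32)
    template -= template.mean()
    resp = match_template(lum.astype(np.float32), template, pad_input=True)
    raw_landmark = 1.0 - min(max(float(resp.max()), 0.0), 1.0)

    raw = {
        "uneven_illumination": raw_illum,
        "color_distortion": raw_color,
        "low_contrast": raw_contrast,
        "motion_blur": raw_blur,
        "missing_landmarks": raw_landmark,
    }
    scores = {k: float(np.clip(v / scales[k], 0.0, 1.0)) for k, v in raw.items()}
    primary = max(QUALITY_CRITERIA, key=lambda k: scores[k])
    return QualityReport(
        scores=scores,
        primary_criterion=primary,
        excluded=scores[primary] >= threshold,
        threshold=threshold,
    )


def apply_exclusion(
    manifest: Manifest, reports: Sequence[QualityReport]
) -> tuple[Manifest, dict[str, int]]:
    """Drop excluded records; count removals by primary criterion.

    An image exceeding several criteria is counted once, under the
    criterion with the highest score.
    """
    if len(reports) != len(manifest):
        raise ValueError(
            f"{len(reports)} reports for {len(manifest)} records"
        )
    keep, log = [], {c: 0 for c in QUALITY_CRITERIA}
    for i, (rec, rep) in enumerate(zip(manifest, reports)):
        if rep.excluded:
            log[rep.primary_criterion] += 1
        else:
            keep.append(i)
    kept = manifest.subset(keep, note="quality-filtered")
    for rec, rep in zip(kept, (reports[i] for i in keep)):
        rec.quality_flags = frozenset(
            k for k, v in rep.scores.items() if v >= rep.threshold
        )
    return kept, log


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------


def kfold_split(manifest: Manifest, k: int, seed: int) -> list[tuple[Manifest, Manifest]]:
    """Stratified k-fold by referable label; folds partition the manifest."""
    if k < 2:
        raise ValueError("k must be >= 2")
    y = manifest.labels.astype(int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError(
            f"each class needs >= {k} members, got counts {counts.tolist()}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for i, (tr, va) in enumerate(skf.split(np.zeros(len(y)), y)):
        folds.append(
            (manifest.subset(tr.tolist(), f"fold{i}-train"),
             manifest.subset(va.tolist(), f"fold{i}-val"))
        )
    return folds


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def subsample_label_fraction(manifest: Manifest, fraction: float, seed: int) -> Manifest:
    """Stratified label-fraction subsample, nested across fractions.

    For a fixed seed each class is permuted once and a prefix of length
    round(fraction * class size) is taken, so the 10% sample is a subset of
    the 20% sample — label-efficiency curves grow monotonically in data.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    y = manifest.labels
    chosen: list[int] = []
    for cls in (False, True):
        idx = np.flatnonzero(y == cls)
        n_take = _round_half_up(fraction * len(idx))
        if n_take < 1:
            raise ValueError(
                f"fraction {fraction} leaves class referable={cls} empty "
                f"(class size {len(idx)})"
            )
        rng = np.random.Generator(
            np.random.PCG64(np.random.SeedSequence([seed, int(cls)]))
        )
        perm = rng.permutation(len(idx))
        chosen.extend(idx[perm[:n_take]].tolist())
    chosen.sort()
    return manifest.subset(chosen, note=f"label-fraction {fraction} seed {seed}")
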