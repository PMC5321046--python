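"""Assembly of six-class tissue priors from fitted voxelwise models.

A prior request lists demographic targets (age in months, sex, field
strength); the quality covariate is always set to the best value observed in
the training cohort, since the synthetic maps should reflect the data at its
cleanest.  One prior is generated per request row and the rows are averaged
voxelwise ("matched pairs").  The six predicted class maps are clipped to
[0, 1], median-filtered, and made consistent so that every voxel's class
probabilities sum to one, with the background class absorbing the residual
mass (segmentation routines expect the six classes to sum to 100%).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy.ndimage import median_filter

from .cohort import DESIGN_COLUMNS
from .voxelwise import TISSUE_CLASSES, VoxelwiseModelSet

__all__ = [
    "PriorRequest",
    "PriorSet",
    "predict_priors",
    "clamp01",
    "enforce_class_consistency",
    "median_filter_3d",
    "build_priors",
    "covariate_difference_map",
]

logger = logging.getLogger(__name__)

_SUM_TOL = 1e-6


@dataclass(frozen=True)
class PriorRequest:
    """Demographic targets: rows of (age_months, sex, field_strength).

    ``sex`` is "M"/"F" (or 1/0) and ``field_strength`` 3.0/1.5 (or 1/0);
    every value must lie within the training range of its predictor.
    """

    rows: tuple[tuple[float, float, float], ...]

    @classmethod
    def from_demographics(cls, rows) -> "PriorRequest":
        out = []
        for age, sex, fs in rows:
            sexv = {"M": 1.0, "F": 0.0}.get(sex, None)
            if sexv is None:
                sexv = float(sex)
            fsv = {3.0: 1.0, 1.5: 0.0}.get(float(fs), None)
            if fsv is None:
                fsv = float(fs)
            out.append((float(age), sexv, fsv))
        if not out:
            raise ValueError("empty prior request")
        return cls(tuple(out))

    def design_rows(self, quality: float) -> np.ndarray:
        X = np.array([[a, s, f, quality] for a, s, f in self.rows])
        return X


@dataclass
class PriorSet:
    """Six 3D probability volumes in canonical class order, summing to 1."""

    volumes: dict[str, np.ndarray]
    affine: np.ndarray
    meta: dict

    def __post_init__(self) -> None:
        for lb in TISSUE_CLASSES:
            if lb not in self.volumes:
                raise ValueError(f"missing class {lb!r}")
        total = sum(self.volumes[lb] for lb in TISSUE_CLASSES)
        if not np.allclose(total, 1.0, atol=_SUM_TOL):
            raise ValueError("class probabilities do not sum to 1 per voxel")
        for lb, v in self.volumes.items():
            if v.min() < -1e-12 or v.max() > 1 + 1e-12:
                raise ValueError(f"class {lb!r} leaves [0, 1]")

    def save(self, path, sidecar: bool = True) -> None:
        """Write one 4D NIfTI (classes along the 4th axis, canonical order)
        plus a JSON sidecar echoing the request metadata."""
        data = np.stack([self.volumes[lb] for lb in TISSUE_CLASSES], axis=-1)
        nib.save(nib.Nifti1Image(data.astype(np.float32), self.affine), str(path))
        if sidecar:
            side = str(path).replace(".nii.gz", "").replace(".nii", "") + ".json"
            with open(side, "w") as fh:
                json.dump(self.meta, fh, indent=1, default=str)


def _check_in_range(X: np.ndarray, var_min: np.ndarray, var_max: np.ndarray) -> None:
    bad = []
    for j, name in enumerate(DESIGN_COLUMNS):
        lo, hi = var_min[j], var_max[j]
        if (X[:, j] < lo - 1e-9).any() or (X[:, j] > hi + 1e-9).any():
            bad.append(f"{name} (allowed [{lo:g}, {hi:g}])")
    if bad:
        raise ValueError("request outside the training range of: " + ", ".join(bad))


def predict_priors(models: dict[str, VoxelwiseModelSet],
                   request: PriorRequest) -> dict[str, np.ndarray]:
    """Matched-pairs prediction: one map per request row per class, averaged.

    The quality covariate is set to the maximum (best) value seen in
    training.  Raw averaged predictions are returned, before clipping,
    filtering, or consistency enforcement.  Out-of-range requests raise,
    naming the offending predictors.
    """
    labels = list(models)
    ref = models[labels[0]]
    for lb in labels[1:]:
        m = models[lb]
        if m.mask.shape != ref.mask.shape or not np.allclose(
                m.affine, ref.affine, atol=1e-4):
            raise ValueError(f"model set {lb!r} is on a different grid")
    best_q = float(ref.var_max[3])
    X = request.design_rows(best_q)
    _check_in_range(X, ref.var_min, ref.var_max)
    return {lb: models[lb].predict(X).mean(axis=0) for lb in labels}


def clamp01(volume: np.ndarray) -> np.ndarray:
    """Clip to [0, 1]; the number of clipped voxels is logged."""
    n_clip = int(np.sum((volume < 0) | (volume > 1)))
    if n_clip:
        logger.info("clamp01: clipped %d voxels", n_clip)
    return np.clip(volume, 0.0, 1.0)


def enforce_class_consistency(volumes: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Force the six class probabilities to sum to 1 at every voxel.

    The residual (1 - sum) is added to the background class; where that
    would drive background negative, background is set to 0 and the other
    five classes are rescaled proportionally.  Voxels where all classes are
    zero get background 1 (logged).
    """
    vols = {lb: np.asarray(volumes[lb], dtype=float).copy()
            for lb in TISSUE_CLASSES}
    five = sum(vols[lb] for lb in TISSUE_CLASSES[:-1])
    bg = 1.0 - five
    neg = bg < 0
    if neg.any():
        scale = np.where(neg & (five > 0), 1.0 / np.where(five > 0, five, 1.0), 1.0)
        for lb in TISSUE_CLASSES[:-1]:
            vols[lb] = vols[lb] * scale
        bg = np.where(neg, 0.0, bg)
    empty = (five == 0)
    if empty.any():
        logger.info("enforce_class_consistency: %d all-zero voxels set to "
                    "background", int(empty.sum()))
        bg = np.where(empty, 1.0, bg)
    vols["background"] = bg
    return vols


def median_filter_3d(volume: np.ndarray, radius: int = 1) -> np.ndarray:
    """3D median filter over a cubic (2*radius+1)^3 neighbourhood.

    Edges use replicate padding.  A small median filter enforces local tissue
    homogeneity without the loss of spatial specificity of Gaussian
    smoothing.
    """
    size = 2 * radius + 1
    return median_filter(np.asarray(volume, dtype=float), size=size,
                         mode="nearest")


def build_priors(models: dict[str, VoxelwiseModelSet], request: PriorRequest,
                 filter_radius: int = 1, meta: dict | None = None) -> PriorSet:
    """Full prior assembly: predict, clip, median-filter, enforce consistency."""
    raw = predict_priors(models, request)
    clipped = {lb: clamp01(v) for lb, v in raw.items()}
    if filter_radius > 0:
        clipped = {lb: median_filter_3d(v, filter_radius)
                   for lb, v in clipped.items()}
    vols = enforce_class_consistency(clipped)
    ref = models[list(models)[0]]
    info = {"request_rows": [list(r) for r in request.rows],
            "quality": "best available",
            "filter_radius": filter_radius}
    if meta:
        info.update(meta)
    return PriorSet(vols, ref.affine, info)


def covariate_difference_map(models: dict[str, VoxelwiseModelSet],
                             base_row: tuple[float, float, float],
                             varied: str, low: float, high: float,
                             threshold: float = 0.05) -> dict[str, np.ndarray]:
    """Signed per-class difference map between two covariate settings.

    ``varied`` is one of "age_months", "sex", "field_strength"; the base row
    is evaluated with that predictor at ``high`` and at ``low`` and the
    high-minus-low difference returned, with |difference| <= threshold
    zeroed (the conventional display threshold is 5% probability).
    """
    idx = {"age_months": 0, "sex": 1, "field_strength": 2}[varied]
    rows = []
    for v in (high, low):
        r = list(base_row)
        r[idx] = v
        rows.append(tuple(r))
    hi = predict_priors(models, PriorRequest((rows[0],)))
    lo = predict_priors(models, PriorRequest((rows[1],)))
    out = {}
    for lb in models:
        d = hi[lb] - lo[lb]
        d[np.abs(d) <= threshold] = 0.0
        out[lb] = d
    return out
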