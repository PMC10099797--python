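"""Summation images, mask handling, ROI statistics, SNR and tissue comparisons.

This module consumes tissue masks and affines (segmentation and
registration themselves are upstream tools); it applies them to the fitted
relaxation-time maps to produce per-tissue summaries, the echo/TR summation
images used for co-registration and SNR estimation, and the two-sample
t-tests comparing tissues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .core_model import MEGEDataset
from .fitting import FLAG_OK

__all__ = [
    "TissueMasks",
    "ROISummary",
    "sum_over_echoes",
    "resample_to_grid",
    "refine_csf_mask",
    "roi_statistics",
    "summarize_values",
    "round_time_ms",
    "estimate_snr",
    "two_sample_ttest",
]

_ROUNDING_MODES = ("none", "d2", "h1")


@dataclass
class TissueMasks:
    """Named binary masks on one grid, with a voxel-to-world affine (mm).

    The tissue masks {CSF, GM, WM} must be pairwise disjoint and the
    background mask disjoint from brain.  Extra ROI masks (ventricle,
    cistern, brain, background, ...) may be carried alongside.
    """

    masks: dict
    affine: np.ndarray = field(default=None)

    def __post_init__(self):
        self.masks = {k: np.asarray(v, dtype=bool) for k, v in self.masks.items()}
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ValueError("all masks must share one grid shape")
        tissues = [self.masks[k] for k in ("CSF", "GM", "WM") if k in self.masks]
        for i in range(len(tissues)):
            for j in range(i + 1, len(tissues)):
                if np.any(tissues[i] & tissues[j]):
                    raise ValueError("tissue masks must be pairwise disjoint")
        if "background" in self.masks and "brain" in self.masks:
            if np.any(self.masks["background"] & self.masks["brain"]):
                raise ValueError("background mask overlaps brain")
        if self.affine is None:
            self.affine = np.eye(4)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    @classmethod
    def from_phantom(cls, truth, affine=None) -> "TissueMasks":
        return cls(masks=truth.masks(), affine=affine)


@dataclass
class ROISummary:
    """Per-ROI mean and sample SD (ms) with voxel counts and the rounding
    rule that was applied to the reported values."""

    table: pd.DataFrame
    rounding: str = "none"

    def to_csv(self, path):
        self.table.to_csv(path, index=True)


def sum_over_echoes(data: MEGEDataset, over: str = "TE"):
    """Voxel-wise sum along the named axes of a MEGE dataset.

    ``over="TE"`` returns a (x, y, z, nTR) stack of echo-summed images;
    ``over="TE_and_TR"`` additionally sums over TR, giving one 3-D image.
    Linear in the input by construction.
    """
    if over == "TE":
        return data.data.sum(axis=3)
    if over == "TE_and_TR":
        return data.data.sum(axis=(3, 4))
    raise ValueError(f"unknown summation axis spec {over!r}")


def resample_to_grid(image, affine_src, affine_dst, target_shape,
                     mode: str = "nearest"):
    """Pull-resample an image from one voxel grid to another.

    For every voxel index ``v`` of the target grid the source index is
    ``affine_src^-1 @ affine_dst @ v`` (both affines map voxel indices to
    world mm, standard NIfTI semantics); the image is sampled there with
    nearest-neighbour (``mode="nearest"``, for masks) or trilinear
    (``mode="trilinear"``) interpolation.  Out-of-field voxels are 0.
    """
    image = np.asarray(image, dtype=float)
    affine_src = np.asarray(affine_src, dtype=float)
    affine_dst = np.asarray(affine_dst, dtype=float)
    if abs(np.linalg.det(affine_src)) < 1e-12:
        raise ValueError("source affine is singular")
    if abs(np.linalg.det(affine_dst)) < 1e-12:
        raise ValueError("destination affine is singular")
    if mode not in ("nearest", "trilinear"):
        raise ValueError(f"unknown resampling mode {mode!r}")
    compose = np.linalg.inv(affine_src) @ affine_dst
    out = ndimage.affine_transform(
        image, compose[:3, :3], offset=compose[:3, 3],
        output_shape=tuple(target_shape),
        order=0 if mode == "nearest" else 1,
        mode="constant", cval=0.0)
    return out


def refine_csf_mask(csf_mask, keep: int = 2):
    """Deterministic surrogate for manual CSF-mask pruning: keep the ``keep``
    largest 26-connected components (the lateral ventricles), discarding the
    cortical-surface rim.
    """
    csf_mask = np.asarray(csf_mask, dtype=bool)
    if keep < 1:
        raise ValueError("keep must be >= 1")
    if not np.any(csf_mask):
        import warnings
        warnings.warn("refining an empty CSF mask", stacklevel=2)
        return csf_mask.copy()
    labels, n = ndimage.label(csf_mask, structure=np.ones((3, 3, 3), dtype=int))
    sizes = ndimage.sum_labels(csf_mask, labels, index=np.arange(1, n + 1))
    order = np.argsort(sizes)[::-1][:keep] + 1
    return np.isin(labels, order)


def round_time_ms(value: float, rounding: str):
    """Apply the summary table's printed-precision rounding to a time in ms.

    ``"d2"`` (deuterium columns): nearest 10 ms for values >= 50 ms, nearest
    1 ms below; ``"h1"`` (proton columns): nearest 1 ms; ``"none"``: identity.
    """
    if rounding == "none":
        return float(value)
    if rounding == "d2":
        q = 10.0 if abs(value) >= 50.0 else 1.0
        return float(np.round(value / q) * q)
    if rounding == "h1":
        return float(np.round(value))
    raise ValueError(f"unknown rounding mode {rounding!r}")


def summarize_values(values, rounding: str = "none"):
    """Mean and sample SD of a list of per-visit scalars, with table rounding
    applied to the mean.  Returns (mean, sd, n)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("no values to summarise")
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    return round_time_ms(float(v.mean()), rounding), sd, int(v.size)


def roi_statistics(time_map, masks: TissueMasks, qc_flags=None,
                   rounding: str = "none", roi_names=None) -> ROISummary:
    """Mean and sample SD of a relaxation-time map over each named mask.

    Only voxels with finite values and (when ``qc_flags`` is given) flag 0
    contribute.  ``rounding`` applies the printed-precision rule to the
    reported means ("d2" for deuterium maps, "h1" for proton maps).
    """
    if rounding not in _ROUNDING_MODES:
        raise ValueError(f"unknown rounding mode {rounding!r}")
    time_map = np.asarray(time_map, dtype=float)
    valid = np.isfinite(time_map)
    if qc_flags is not None:
        valid &= np.asarray(qc_flags) == FLAG_OK
    names = roi_names if roi_names is not None else [
        n for n in ("CSF", "GM", "WM") if n in masks.masks]
    rows = []
    for name in names:
        sel = masks[name] & valid
        n = int(sel.sum())
        if n == 0:
            raise ValueError(f"mask {name!r} has no valid voxels")
        vals = time_map[sel]
        rows.append({"roi": name,
                     "mean_ms": round_time_ms(float(vals.mean()), rounding),
                     "sd_ms": float(vals.std(ddof=1)) if n > 1 else 0.0,
                     "n_voxels": n})
    return ROISummary(table=pd.DataFrame(rows).set_index("roi"),
                      rounding=rounding)


def estimate_snr(image, tissue_mask, background_mask) -> float:
    """SNR = mean(signal over tissue) / SD(signal over background).

    The background SD is used raw — no Rayleigh/Rician correction — so on
    magnitude images this matches the conventional ROI-based estimate.
    """
    image = np.asarray(image, dtype=float)
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    background_mask = np.asarray(background_mask, dtype=bool)
    if not tissue_mask.any() or not background_mask.any():
        raise ValueError("tissue and background masks must be non-empty")
    if np.any(tissue_mask & background_mask):
        raise ValueError("tissue and background masks must be disjoint")
    sd = float(image[background_mask].std(ddof=1))
    if sd == 0:
        raise ValueError("background SD is zero")
    return float(image[tissue_mask].mean()) / sd


def two_sample_ttest(group_a, group_b, variant: str = "pooled") -> dict:
    """Two-sample t-test; returns {"t", "df", "p"} (two-tailed).

    ``variant="pooled"`` is the classic equal-variance test;
    ``variant="welch"`` uses the Welch-Satterthwaite correction.  Two
    identical constant groups return t = 0, p = 1 by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    equal_var = variant == "pooled"
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            df = a.size + b.size - 2 if equal_var else float(a.size + b.size - 2)
            return {"t": 0.0, "df": float(df), "p": 1.0}
        raise ValueError("zero variance with unequal means: t undefined")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    if equal_var:
        df = float(a.size + b.size - 2)
    else:
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        df = (va + vb) ** 2 / (va ** 2 / (a.size - 1) + vb ** 2 / (b.size - 1))
    return {"t": float(res.statistic), "df": float(df), "p": float(res.pvalue)}
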