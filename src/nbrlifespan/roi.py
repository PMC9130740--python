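"""Subject-specific ROIs, spatial-extent statistics, tertiles and motion.

The subject-level ROI convention: locate the peak-response voxel of the
requested polarity inside an anatomical mask, centre a 3×3×3 cube on it
(27 voxels for interior peaks, clipped at volume boundaries), and average
statistics and timecourses over the cube.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .glm import BOLDDataset, MotionTrace

#: Fraction of the per-sign maximum beta below which voxels are treated as
#: noise when counting response extent.
EXTENT_THRESHOLD_FRAC = 0.05

#: Sphere radius (mm) converting rotations to displacements for FD.
FD_HEAD_RADIUS = 50.0

_CUBE_HALF = 1  # 3×3×3 cube


@dataclass
class ROIRecord:
    """One subject's functional ROI within an anatomical region."""

    region: str
    peak_voxel: tuple[int, int, int]
    voxels: np.ndarray  # (n, 3) int indices
    mean_z: float | None = None
    mean_beta: float | None = None
    timecourse: np.ndarray | None = None


@dataclass(frozen=True)
class ExtentMetrics:
    """PBR/NBR voxel proportions of a mask and their ratio.

    ``ratio`` is ``nan`` (undefined) when there are no NBR voxels.
    """

    pbr_proportion: float
    nbr_proportion: float
    ratio: float


def define_subject_roi(
    stat_map: np.ndarray,
    anatomical_mask: np.ndarray,
    polarity: str,
    require_polarity: bool = True,
) -> ROIRecord:
    """Cubic ROI centred on the masked extremum of the requested polarity.

    Ties go to the lowest linear index; the cube is clipped at volume
    boundaries rather than shifted.  By default a mask containing no voxel
    of the requested polarity is an error; with ``require_polarity=False``
    the polarity-directed extremum is used regardless of its sign (for
    subjects whose response is too weak to cross zero anywhere).
    """
    stat_map = np.asarray(stat_map, dtype=float)
    mask = np.asarray(anatomical_mask, dtype=bool)
    if stat_map.shape != mask.shape:
        raise ValueError("stat map and mask shapes differ")
    if not mask.any():
        raise ValueError("empty anatomical mask")
    if polarity not in ("positive", "negative"):
        raise ValueError("polarity must be 'positive' or 'negative'")
    vals = np.where(mask, stat_map, np.nan)
    signed = vals if polarity == "positive" else -vals
    if require_polarity and not np.any(np.nan_to_num(signed, nan=-np.inf) > 0):
        raise ValueError(f"no {polarity} voxel inside the mask")
    flat = np.nan_to_num(signed, nan=-np.inf).ravel()
    peak_flat = int(np.argmax(flat))  # lowest linear index on ties
    peak = np.unravel_index(peak_flat, stat_map.shape)
    ranges = [
        np.arange(max(0, p - _CUBE_HALF), min(s, p + _CUBE_HALF + 1))
        for p, s in zip(peak, stat_map.shape)
    ]
    gx, gy, gz = np.meshgrid(*ranges, indexing="ij")
    voxels = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    return ROIRecord(region="", peak_voxel=tuple(int(p) for p in peak), voxels=voxels)


def extract_roi_measures(
    roi: ROIRecord,
    z_map: np.ndarray,
    beta_map: np.ndarray,
    data: BOLDDataset | None = None,
) -> ROIRecord:
    """Fill an ROI record with mean Z, mean beta and (optionally) the mean
    BOLD timecourse over its voxel set."""
    if roi.voxels.size == 0:
        raise ValueError("empty ROI voxel set")
    idx = tuple(roi.voxels.T)
    roi.mean_z = float(np.mean(np.asarray(z_map, dtype=float)[idx]))
    roi.mean_beta = float(np.mean(np.asarray(beta_map, dtype=float)[idx]))
    if data is not None:
        roi.timecourse = data.values[idx].mean(axis=0)
    return roi


def extent_metrics(
    beta_map: np.ndarray,
    mask: np.ndarray,
    threshold_frac: float = EXTENT_THRESHOLD_FRAC,
    per_sign_max: bool = True,
) -> ExtentMetrics:
    """Proportions of mask voxels with supra-threshold positive/negative
    betas, thresholded at ``threshold_frac`` of the per-sign maximum (or of
    the global absolute maximum with ``per_sign_max=False``), and their
    PBR/NBR ratio."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    beta = np.asarray(beta_map, dtype=float)[mask]
    n = beta.size
    pos = beta[beta > 0]
    neg = -beta[beta < 0]
    if per_sign_max:
        pos_thr = threshold_frac * (pos.max() if pos.size else 0.0)
        neg_thr = threshold_frac * (neg.max() if neg.size else 0.0)
    else:
        global_max = np.abs(beta).max() if n else 0.0
        pos_thr = neg_thr = threshold_frac * global_max
    n_pbr = int(np.sum(pos > pos_thr)) if threshold_frac > 0 else pos.size
    n_nbr = int(np.sum(neg > neg_thr)) if threshold_frac > 0 else neg.size
    pbr_prop = n_pbr / n
    nbr_prop = n_nbr / n
    ratio = pbr_prop / nbr_prop if nbr_prop > 0 else float("nan")
    return ExtentMetrics(
        pbr_proportion=pbr_prop, nbr_proportion=nbr_prop, ratio=ratio
    )


def tertile_split(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rank-based split into lower/middle/upper thirds.

    Sizes are ``floor(n/3)`` each with the remainder assigned to the middle
    group first, then the lower group (55 → 18/19/18, 56 → 19/19/18); ties
    keep the original subject order.  Returns index arrays into ``values``.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 3:
        raise ValueError("need at least 3 subjects for a tertile split")
    order = np.argsort(values, kind="stable")
    base, rem = divmod(n, 3)
    n_mid = base + (1 if rem >= 1 else 0)
    n_low = base + (1 if rem >= 2 else 0)
    lower = order[:n_low]
    middle = order[n_low : n_low + n_mid]
    upper = order[n_low + n_mid :]
    return lower, middle, upper


def framewise_displacement(
    motion: MotionTrace, head_radius: float = FD_HEAD_RADIUS
) -> tuple[np.ndarray, float]:
    """Per-volume framewise displacement and its sum over the run.

    ``FD_t = Σ|Δtranslation| + r·Σ|Δrotation|`` over the six parameters,
    with rotations converted to arc length on a ``head_radius`` mm sphere;
    the first volume has FD 0.
    """
    params = motion.params
    if params.shape[0] < 2:
        raise ValueError("need at least 2 volumes for framewise displacement")
    deltas = np.abs(np.diff(params, axis=0))
    fd = deltas[:, :3].sum(axis=1) + head_radius * deltas[:, 3:].sum(axis=1)
    per_volume = np.concatenate(([0.0], fd))
    return per_volume, float(per_volume.sum())
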