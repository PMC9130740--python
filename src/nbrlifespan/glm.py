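"""First-level general linear model for event-related BOLD data.

Regressors are built by placing a 50 ms boxcar of unit height at each event
on a fine (0.05 s) time grid, convolving with a haemodynamic kernel of unit
extremum, and sampling at volume acquisition times ``t = volume_index × TR``
(volume-start reference).  With this convention the fitted beta of an
isolated condition is the event amplitude in fractional signal change.

Fitting is ordinary least squares per voxel, with contrast t statistics
mapped through the t CDF onto the standard normal scale (Z statistics); an
AR(1) Cochrane–Orcutt correction is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as _ndimage
from scipy import stats as _stats

from .events import CONDITIONS, EventSchedule
from .hrf import HRTimecourse

#: Fine internal grid for convolution (equals the event duration).
FINE_DT = 0.05

#: Conventional voxelwise significance threshold used for map summaries.
Z_THRESHOLD = 3.1

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class MotionTrace:
    """Six rigid-body realignment parameters per volume.

    Columns 0–2 are translations in mm, columns 3–5 rotations in radians.
    """

    params: np.ndarray

    def __post_init__(self) -> None:
        params = np.asarray(self.params, dtype=float)
        if params.ndim != 2 or params.shape[1] != 6:
            raise ValueError("motion trace must be n_volumes × 6")
        if not np.all(np.isfinite(params)):
            raise ValueError("non-finite motion parameters")
        self.params = params

    @property
    def n_volumes(self) -> int:
        return self.params.shape[0]


@dataclass
class BOLDDataset:
    """A 4-D BOLD lattice with its repetition time and region label map."""

    values: np.ndarray  # (x, y, z, volume)
    tr: float
    label_map: np.ndarray
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        labels = np.asarray(self.label_map)
        if values.ndim != 4:
            raise ValueError("BOLD values must be 4-D (x, y, z, volume)")
        if labels.shape != values.shape[:3]:
            raise ValueError("label map must match spatial dimensions")
        if not np.all(np.isfinite(values)):
            raise ValueError("non-finite BOLD values")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        self.values = values
        self.label_map = labels

    @property
    def n_volumes(self) -> int:
        return self.values.shape[3]

    @property
    def grid(self) -> tuple[int, int, int]:
        return self.values.shape[:3]

    def region_timecourse(self, region: str) -> np.ndarray:
        """Spatial mean series over one labelled region."""
        from .atlas import region_mask

        mask = region_mask(self.label_map, region)
        if not mask.any():
            raise ValueError(f"region {region!r} empty in label map")
        return self.values[mask].mean(axis=0)


def sampled_regressor(
    onsets: np.ndarray,
    durations: np.ndarray,
    kernel: HRTimecourse,
    tr: float,
    n_volumes: int,
    fine_dt: float = FINE_DT,
) -> np.ndarray:
    """Unit-height event train convolved with ``kernel``, sampled at volume
    times.  An isolated event's column peaks at the kernel extremum value."""
    if tr <= 0:
        raise ValueError("tr must be positive")
    run_end = n_volumes * tr
    onsets = np.asarray(onsets, dtype=float)
    durations = np.asarray(durations, dtype=float)
    if onsets.size and np.max(onsets) >= run_end:
        raise ValueError("event beyond the end of the run")
    kern = kernel if kernel.dt == fine_dt else kernel.resampled(fine_dt)
    n_fine = int(np.ceil(run_end / fine_dt)) + 1
    train = np.zeros(n_fine)
    for onset, dur in zip(onsets, durations):
        start = int(round(onset / fine_dt))
        width = max(1, int(round(dur / fine_dt)))
        train[start : min(start + width, n_fine)] += 1.0
    conv = np.convolve(train, kern.samples)[:n_fine]
    vol_idx = np.round(np.arange(n_volumes) * tr / fine_dt).astype(int)
    return conv[vol_idx]


@dataclass
class DesignMatrix:
    """Volumes × regressors matrix with labels and named contrast vectors."""

    matrix: np.ndarray
    column_labels: list[str]
    contrasts: dict[str, np.ndarray]
    tr: float

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("design matrix must be 2-D")
        if len(self.column_labels) != self.matrix.shape[1]:
            raise ValueError("one label per design column required")
        for name, c in self.contrasts.items():
            c = np.asarray(c, dtype=float)
            if c.shape != (self.matrix.shape[1],):
                raise ValueError(f"contrast {name!r} has wrong length")
            self.contrasts[name] = c

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_regressors(self) -> int:
        return self.matrix.shape[1]

    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.matrix))


def drift_regressors(n_volumes: int, order: int) -> np.ndarray:
    """Legendre polynomial drift columns of degree 0..order on [-1, 1]."""
    x = np.linspace(-1.0, 1.0, n_volumes)
    return np.stack([np.polynomial.legendre.Legendre.basis(k)(x) for k in range(order + 1)], axis=1)


def build_design_matrix(
    schedule: EventSchedule,
    kernel: HRTimecourse,
    tr: float,
    n_volumes: int,
    motion: MotionTrace | None = None,
    drift_order: int | None = None,
) -> DesignMatrix:
    """Condition regressors (one per stimulus condition), optional motion
    nuisance columns and polynomial drift terms, with mean-over-conditions
    contrasts of both signs attached (``pos_mean`` and ``neg_mean``)."""
    cols: list[np.ndarray] = []
    labels: list[str] = []
    for cond in CONDITIONS:
        mask = np.array([c == cond for c in schedule.conditions], dtype=bool)
        cols.append(
            sampled_regressor(
                schedule.onsets[mask], schedule.durations[mask], kernel, tr, n_volumes
            )
        )
        labels.append(cond)
    if motion is not None:
        if motion.n_volumes != n_volumes:
            raise ValueError("motion trace length must equal n_volumes")
        demeaned = motion.params - motion.params.mean(axis=0)
        for j in range(6):
            cols.append(demeaned[:, j])
            labels.append(f"motion_{j}")
    if drift_order is not None:
        drifts = drift_regressors(n_volumes, drift_order)
        for k in range(drifts.shape[1]):
            cols.append(drifts[:, k])
            labels.append(f"drift_{k}")
    matrix = np.stack(cols, axis=1)
    n_cond = len(CONDITIONS)
    c = np.zeros(matrix.shape[1])
    c[:n_cond] = 1.0 / n_cond
    contrasts = {"pos_mean": c, "neg_mean": -c}
    return DesignMatrix(matrix=matrix, column_labels=labels, contrasts=contrasts, tr=tr)


def gaussian_smooth(data: BOLDDataset, fwhm: float) -> BOLDDataset:
    """Separable spatial Gaussian smoothing per volume (reflective boundary).

    ``fwhm`` is in mm and converted to voxel-space sigmas through the
    dataset's voxel size; ``fwhm=0`` is the identity.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be non-negative")
    if fwhm == 0:
        return data
    sigmas = tuple(
        fwhm * _FWHM_TO_SIGMA / vs for vs in data.voxel_size
    )
    smoothed = _ndimage.gaussian_filter(
        data.values, sigma=sigmas + (0.0,), mode="reflect"
    )
    return BOLDDataset(
        values=smoothed, tr=data.tr, label_map=data.label_map, voxel_size=data.voxel_size
    )


def t_to_z(t: np.ndarray, df: int) -> np.ndarray:
    """Monotone, odd map from t statistics to standard-normal Z scores."""
    t = np.asarray(t, dtype=float)
    z = np.full(t.shape, np.nan)
    pos = t >= 0
    with np.errstate(invalid="ignore"):
        z[pos] = _stats.norm.isf(_stats.t.sf(t[pos], df))
        z[~pos] = -_stats.norm.isf(_stats.t.sf(-t[~pos], df))
    return z


@dataclass
class FirstLevelResults:
    """Per-voxel beta, beta-variance and Z maps for each contrast.

    Voxels where the contrast is undefined (zero residual variance with a
    nonzero contrast, or outside the mask) carry NaN and are excluded from
    ``valid_mask``.
    """

    beta_maps: dict[str, np.ndarray]
    variance_maps: dict[str, np.ndarray]
    z_maps: dict[str, np.ndarray]
    regressor_betas: np.ndarray  # (x, y, z, n_regressors)
    valid_mask: np.ndarray
    degrees_of_freedom: int
    design: DesignMatrix

    def summary(self) -> str:
        import pandas as pd

        rows = []
        for name in self.beta_maps:
            z = self.z_maps[name][self.valid_mask]
            b = self.beta_maps[name][self.valid_mask]
            rows.append(
                {
                    "contrast": name,
                    "n_voxels": int(self.valid_mask.sum()),
                    "beta_mean": float(np.nanmean(b)),
                    "z_mean": float(np.nanmean(z)),
                    "z_max": float(np.nanmax(z)),
                    f"n_|z|>{Z_THRESHOLD}": int(np.sum(np.abs(z) > Z_THRESHOLD)),
                }
            )
        table = pd.DataFrame(rows).to_string(index=False)
        head = (
            "First-level GLM (OLS)\n"
            f"  volumes: {self.design.n_volumes}, regressors: "
            f"{self.design.n_regressors}, df: {self.degrees_of_freedom}\n"
        )
        return head + table


class FirstLevelGLM:
    """Ordinary-least-squares first-level model of a 4-D BOLD dataset.

    Parameters
    ----------
    data : BOLDDataset
    design : DesignMatrix
    mask : bool array, optional
        Voxels to fit; defaults to all voxels.

    ``fit()`` returns :class:`FirstLevelResults` with beta, variance and Z
    maps for every contrast attached to the design.
    """

    def __init__(
        self, data: BOLDDataset, design: DesignMatrix, mask: np.ndarray | None = None
    ):
        if design.n_volumes != data.n_volumes:
            raise ValueError("design and data disagree on volume count")
        if mask is None:
            mask = np.ones(data.grid, dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != data.grid:
            raise ValueError("mask must match the spatial grid")
        if not mask.any():
            raise ValueError("empty mask")
        self.data = data
        self.design = design
        self.mask = mask

    def fit(self, ar1_correction: bool = False) -> FirstLevelResults:
        X = self.design.matrix
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("rank-deficient design matrix")
        Y = self.data.values[self.mask].T  # n_volumes × n_voxels
        if ar1_correction:
            beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
            resid = Y - X @ beta
            num = np.sum(resid[1:] * resid[:-1])
            den = np.sum(resid[:-1] ** 2)
            rho = float(np.clip(num / den if den > 0 else 0.0, -0.99, 0.99))
            Y = Y[1:] - rho * Y[:-1]
            X = X[1:] - rho * X[:-1]
        n, p = X.shape
        df = n - p
        if df <= 0:
            raise ValueError("non-positive degrees of freedom")
        xtx_inv = np.linalg.inv(X.T @ X)
        beta = xtx_inv @ X.T @ Y
        resid = Y - X @ beta
        sigma2 = np.sum(resid**2, axis=0) / df

        grid = self.data.grid
        scale = np.mean(np.abs(Y), axis=0)
        degenerate = sigma2 <= np.maximum(scale, 1.0) ** 2 * 1e-24
        beta_maps: dict[str, np.ndarray] = {}
        var_maps: dict[str, np.ndarray] = {}
        z_maps: dict[str, np.ndarray] = {}
        for name, c in self.design.contrasts.items():
            cb = c @ beta
            cvar = float(c @ xtx_inv @ c) * sigma2
            with np.errstate(divide="ignore", invalid="ignore"):
                t = cb / np.sqrt(cvar)
            z = t_to_z(t, df)
            # zero residual variance with nonzero contrast → undefined
            z[degenerate & (cb != 0)] = np.nan
            beta_maps[name] = self._unmask(cb)
            var_maps[name] = self._unmask(cvar)
            z_maps[name] = self._unmask(z)
        valid = np.zeros(grid, dtype=bool)
        any_nan = np.zeros(self.mask.sum(), dtype=bool)
        for z in z_maps.values():
            any_nan |= ~np.isfinite(z[self.mask])
        valid[self.mask] = ~any_nan
        reg_betas = np.full(grid + (p,), np.nan)
        reg_betas[self.mask] = beta.T
        return FirstLevelResults(
            beta_maps=beta_maps,
            variance_maps=var_maps,
            z_maps=z_maps,
            regressor_betas=reg_betas,
            valid_mask=valid,
            degrees_of_freedom=df,
            design=self.design,
        )

    def _unmask(self, flat: np.ndarray) -> np.ndarray:
        out = np.full(self.data.grid, np.nan)
        out[self.mask] = flat
        return out


def fit_glm(
    data: BOLDDataset, design: DesignMatrix, mask: np.ndarray | None = None
) -> FirstLevelResults:
    """Functional wrapper around :class:`FirstLevelGLM`."""
    return FirstLevelGLM(data, design, mask).fit()


def fit_timecourse_glm(
    y: np.ndarray, design: DesignMatrix
) -> dict[str, tuple[float, float, float]]:
    """OLS fit of a single (e.g. ROI-mean) timecourse.

    Returns per contrast ``(beta, variance, z)``.
    """
    y = np.asarray(y, dtype=float)
    X = design.matrix
    if y.shape != (X.shape[0],):
        raise ValueError("timecourse length must equal design rows")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    n, p = X.shape
    df = n - p
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / df
    out = {}
    for name, c in design.contrasts.items():
        cb = float(c @ beta)
        cvar = float(c @ xtx_inv @ c) * sigma2
        if cvar > 0:
            z = float(t_to_z(np.array([cb / np.sqrt(cvar)]), df)[0])
        else:
            z = np.nan if cb != 0 else 0.0
        out[name] = (cb, cvar, z)
    return out
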