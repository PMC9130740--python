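"""Synthetic BOLD cohorts with lifespan haemodynamic-response trajectories.

The generator emulates the structure of an event-related sensorimotor study
across the adult lifespan (18–88 years, seven decile groups): a rapid
paradigm on a 2 s grid, TR 1.97 s, 261 volumes, and per-region evoked
responses whose ipsilateral sensorimotor (iSM1) amplitude shrinks toward
zero and whose latency grows with age, while contralateral sensorimotor,
visual, thalamic and posterior-cingulate responses stay stable in amplitude.

Forward model per voxel::

    y(t) = baseline + amplitude · (delta train ∗ unit-extremum region HR)(t)
           + polynomial drift(t) + AR(1) noise

Every stochastic element is driven by explicit integer seeds carried on the
subject specification; nothing reads ambient random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as _ndimage
from scipy import signal as _signal

from .atlas import DEFAULT_GRID, REGION_LABELS, RESPONSE_REGIONS, toy_atlas
from .events import DEFAULT_N_VOLUMES, DEFAULT_TR, EventSchedule
from .glm import BOLDDataset, MotionTrace, drift_regressors, sampled_regressor
from .hrf import HRTimecourse, stretched_double_gamma

#: Anchor ages for the linear lifespan trajectories: the mean ages of the
#: youngest and oldest decile groups.
AGE_ANCHOR_YOUNG = 25.8
AGE_ANCHOR_OLD = 82.6

#: Decile labels and their age ranges (years, half-open upper bound).
DECILE_RANGES = {
    "Twenties": (20.0, 30.0),
    "Thirties": (30.0, 40.0),
    "Forties": (40.0, 50.0),
    "Fifties": (50.0, 60.0),
    "Sixties": (60.0, 70.0),
    "Seventies": (70.0, 80.0),
    "Eighties": (80.0, 88.0),
}
DECILES = tuple(DECILE_RANGES)

#: Default lifespan trajectories: region → ((amp_young, amp_old),
#: (ttp_young, ttp_old)) anchored at the mean Twenties/Eighties ages.
#: iSM1 amplitude −0.034 → −0.013 and latency 10 → 18 s; cSM1 latency
#: 9.4 → 10.7 s and thalamus 8.2 → 10.1 s with stable amplitudes; V1 and
#: PCC stable throughout.  Amplitudes are fractional signal change.
DEFAULT_TRAJECTORIES: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "iSM1": ((-0.034, -0.013), (10.0, 18.0)),
    "cSM1": ((0.040, 0.040), (9.4, 10.7)),
    "V1": ((0.045, 0.045), (5.6, 5.6)),
    "thalamus": ((0.025, 0.025), (8.2, 10.1)),
    "PCC": ((-0.030, -0.030), (12.0, 12.0)),
    "background": ((0.0, 0.0), (6.0, 6.0)),
}

#: Summed framewise displacement anchors (mm) at the young/old anchor ages,
#: used to scale synthetic motion so total head motion grows with age.
FD_TOTAL_YOUNG = 63.5
FD_TOTAL_OLD = 135.5

#: Between-subject scatter of HR parameters (see docs/methods.md).
AMP_JITTER_SD = 0.003
TTP_JITTER_SD = 1.5
MIN_ABS_AMP = 0.003
TTP_CLIP = (5.0, 20.0)

#: Kernel window used for generation, seconds.
GENERATION_WINDOW = 32.0

_SIGNED_NEGATIVE = ("iSM1", "PCC")
_SIGNED_POSITIVE = ("cSM1", "V1", "thalamus")


def decile_of_age(age: float) -> str:
    for label, (lo, hi) in DECILE_RANGES.items():
        if lo <= age < hi or (label == "Eighties" and age <= 88.0):
            return label
    raise ValueError(f"age {age} outside the 18–88 study range deciles")


def hr_from_age(
    age: float,
    region: str,
    config: dict | None = None,
) -> tuple[float, float]:
    """Linearly interpolated (amplitude, time_to_peak) for ``region`` at
    ``age``, anchored at the mean Twenties and Eighties ages."""
    if not 18.0 <= age <= 88.0:
        raise ValueError("age must lie in [18, 88] years")
    table = DEFAULT_TRAJECTORIES if config is None else config
    if region not in table:
        raise ValueError(f"unknown region {region!r}")
    (amp_y, amp_o), (ttp_y, ttp_o) = table[region]
    frac = (age - AGE_ANCHOR_YOUNG) / (AGE_ANCHOR_OLD - AGE_ANCHOR_YOUNG)
    return (amp_y + frac * (amp_o - amp_y), ttp_y + frac * (ttp_o - ttp_y))


@dataclass(frozen=True)
class HRParams:
    """One region's evoked-response parameters for one subject."""

    amplitude: float  # fractional signal change, signed
    time_to_peak: float  # seconds


@dataclass(frozen=True)
class SubjectSpec:
    """Everything needed to synthesize one subject reproducibly."""

    subject_id: str
    age: float
    decile_label: str
    region_params: dict[str, HRParams]
    noise_sigma: float = 0.01
    ar1_rho: float = 0.3
    drift_coefs: tuple[float, ...] = (0.01, -0.005)  # Legendre degrees 1, 2, …
    motion_seed: int = 0
    noise_seed: int = 0

    def __post_init__(self) -> None:
        if not 18.0 <= self.age <= 88.0:
            raise ValueError("age must lie in [18, 88]")
        if not abs(self.ar1_rho) < 1:
            raise ValueError("|ar1_rho| must be < 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        for name, p in self.region_params.items():
            if not (np.isfinite(p.amplitude) and np.isfinite(p.time_to_peak)):
                raise ValueError(f"non-finite HR parameters for {name}")
            if name in _SIGNED_NEGATIVE and p.amplitude > 0:
                raise ValueError(f"{name} amplitude must be ≤ 0")
            if name in _SIGNED_POSITIVE and p.amplitude < 0:
                raise ValueError(f"{name} amplitude must be ≥ 0")
        if not all(np.isfinite(self.drift_coefs)):
            raise ValueError("non-finite drift coefficients")


def subject_from_age(
    subject_id: str,
    age: float,
    seed: int,
    jitter: bool = True,
    config: dict | None = None,
    noise_sigma: float = 0.01,
    ar1_rho: float = 0.3,
    drift_coefs: tuple[float, ...] = (0.01, -0.005),
) -> SubjectSpec:
    """Draw one subject's specification from the lifespan trajectories.

    With ``jitter`` the HR parameters get between-subject scatter (clipped so
    every region keeps its response polarity); without it they sit exactly on
    the trajectory.
    """
    rng = np.random.default_rng(seed)
    params: dict[str, HRParams] = {}
    for region in RESPONSE_REGIONS + ("background",):
        amp, ttp = hr_from_age(age, region, config)
        if jitter and region != "background":
            amp = amp + rng.normal(0.0, AMP_JITTER_SD)
            ttp = float(np.clip(ttp + rng.normal(0.0, TTP_JITTER_SD), *TTP_CLIP))
            if region in _SIGNED_NEGATIVE:
                amp = min(amp, -MIN_ABS_AMP)
            elif region in _SIGNED_POSITIVE:
                amp = max(amp, MIN_ABS_AMP)
        params[region] = HRParams(amplitude=float(amp), time_to_peak=float(ttp))
    return SubjectSpec(
        subject_id=subject_id,
        age=float(age),
        decile_label=decile_of_age(age),
        region_params=params,
        noise_sigma=noise_sigma,
        ar1_rho=ar1_rho,
        drift_coefs=tuple(drift_coefs),
        motion_seed=int(rng.integers(2**31 - 1)),
        noise_seed=int(rng.integers(2**31 - 1)),
    )


def region_kernel(spec: SubjectSpec, region: str, dt: float = 0.05) -> HRTimecourse:
    """Unit-extremum generative HR kernel for one region of one subject."""
    return stretched_double_gamma(
        dt, GENERATION_WINDOW, spec.region_params[region].time_to_peak
    )


def _drift_series(spec: SubjectSpec, n_volumes: int) -> np.ndarray:
    if not spec.drift_coefs:
        return np.zeros(n_volumes)
    basis = drift_regressors(n_volumes, len(spec.drift_coefs))[:, 1:]
    return basis @ np.asarray(spec.drift_coefs)


def _ar1_noise(
    rng: np.random.Generator, shape: tuple[int, ...], sigma: float, rho: float
) -> np.ndarray:
    """Stationary AR(1) series of marginal SD ``sigma`` along the last axis."""
    innov = rng.standard_normal(shape) * (sigma * np.sqrt(1.0 - rho**2))
    innov[..., 0] /= np.sqrt(1.0 - rho**2)
    return _signal.lfilter([1.0], [1.0, -rho], innov, axis=-1)


def noiseless_region_signal(
    spec: SubjectSpec,
    schedule: EventSchedule,
    region: str,
    tr: float = DEFAULT_TR,
    n_volumes: int = DEFAULT_N_VOLUMES,
    baseline: float = 1.0,
) -> np.ndarray:
    """Baseline + evoked response + drift for one region (no noise).

    This is exactly the series every voxel of the region carries before
    noise, hence also the region-mean of a noiseless dataset.
    """
    p = spec.region_params[region]
    reg = sampled_regressor(
        schedule.onsets, schedule.durations, region_kernel(spec, region), tr, n_volumes
    )
    return baseline + p.amplitude * reg + _drift_series(spec, n_volumes)


def synthesize_subject(
    spec: SubjectSpec,
    schedule: EventSchedule,
    grid_shape: tuple[int, int, int] = DEFAULT_GRID,
    tr: float = DEFAULT_TR,
    n_volumes: int = DEFAULT_N_VOLUMES,
    baseline: float = 1.0,
) -> tuple[BOLDDataset, MotionTrace]:
    """Forward-simulate one subject's 4-D BOLD dataset and motion trace."""
    if n_volumes * tr < schedule.run_length - 1e-9:
        raise ValueError("acquisition shorter than the event schedule")
    labels = toy_atlas(grid_shape)
    values = np.empty(grid_shape + (n_volumes,))
    background = baseline + _drift_series(spec, n_volumes)
    values[:] = background
    for region in RESPONSE_REGIONS:
        p = spec.region_params[region]
        if p.amplitude == 0:
            continue
        reg = sampled_regressor(
            schedule.onsets, schedule.durations, region_kernel(spec, region), tr, n_volumes
        )
        values[labels == REGION_LABELS[region]] += p.amplitude * reg
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.noise_seed)
        values += _ar1_noise(
            rng, grid_shape + (n_volumes,), spec.noise_sigma * baseline, spec.ar1_rho
        )
    data = BOLDDataset(values=values, tr=tr, label_map=labels)
    motion = generate_motion(spec, n_volumes)
    return data, motion


def synthesize_region_timecourse(
    spec: SubjectSpec,
    schedule: EventSchedule,
    region: str,
    tr: float = DEFAULT_TR,
    n_volumes: int = DEFAULT_N_VOLUMES,
    baseline: float = 1.0,
    n_voxels: int = 27,
) -> np.ndarray:
    """Region-mean series simulated directly (fast path for large sweeps).

    Identical forward model to :func:`synthesize_subject` followed by a
    region average: the signal part matches exactly and the noise SD shrinks
    by ``sqrt(n_voxels)`` (region voxels carry independent noise).
    """
    y = noiseless_region_signal(spec, schedule, region, tr, n_volumes, baseline)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.noise_seed)
        y = y + _ar1_noise(
            rng,
            (n_volumes,),
            spec.noise_sigma * baseline / np.sqrt(n_voxels),
            spec.ar1_rho,
        )
    return y


def fd_target_for_age(age: float) -> float:
    """Summed-FD anchor (mm) interpolated linearly in age."""
    frac = (age - AGE_ANCHOR_YOUNG) / (AGE_ANCHOR_OLD - AGE_ANCHOR_YOUNG)
    return FD_TOTAL_YOUNG + frac * (FD_TOTAL_OLD - FD_TOTAL_YOUNG)


def generate_motion(spec: SubjectSpec, n_volumes: int) -> MotionTrace:
    """Smooth random-walk realignment parameters whose summed framewise
    displacement is anchored to an age-increasing target."""
    from .roi import framewise_displacement

    rng = np.random.default_rng(spec.motion_seed)
    steps = np.empty((n_volumes, 6))
    steps[:, :3] = rng.normal(0.0, 0.02, size=(n_volumes, 3))  # mm
    steps[:, 3:] = rng.normal(0.0, 4e-4, size=(n_volumes, 3))  # rad
    walk = np.cumsum(steps, axis=0)
    walk = _ndimage.gaussian_filter1d(walk, sigma=3.0, axis=0, mode="nearest")
    trace = MotionTrace(params=walk)
    _, total = framewise_displacement(trace)
    target = fd_target_for_age(spec.age) * float(np.exp(rng.normal(0.0, 0.15)))
    if total > 0:
        trace = MotionTrace(params=walk * (target / total))
    return trace


def simulate_cohort_specs(
    n_per_decile: int,
    seed: int,
    jitter: bool = True,
    config: dict | None = None,
    **spec_kwargs,
) -> list[SubjectSpec]:
    """Draw ``n_per_decile`` subjects per decile with uniform ages in each
    decile's range.  Deterministic given ``seed``."""
    rng = np.random.default_rng(seed)
    specs: list[SubjectSpec] = []
    for label, (lo, hi) in DECILE_RANGES.items():
        for k in range(n_per_decile):
            age = float(rng.uniform(max(lo, 18.0), min(hi, 88.0)))
            specs.append(
                subject_from_age(
                    f"sub-{label[:3].lower()}{k:03d}",
                    age,
                    seed=int(rng.integers(2**31 - 1)),
                    jitter=jitter,
                    config=config,
                    **spec_kwargs,
                )
            )
    return specs
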