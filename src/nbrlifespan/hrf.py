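"""Haemodynamic response timecourses and kernels.

A distinction runs through the package: the canonical double-gamma HRF is the
conventional *impulse response function* used as a convolution kernel, while
the deconvolved HR is the *evoked response* to this particular stimulus
(neural input of unknown shape convolved with an unknown HRF).  Both are
represented by :class:`HRTimecourse` — a regularly sampled curve over a
post-stimulus window.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats as _stats

#: Conventional double-gamma parameters: response peak delay 6 s, undershoot
#: delay 16 s, unit dispersions, undershoot ratio 1/6.
DG_PEAK_DELAY = 6.0
DG_UNDERSHOOT_DELAY = 16.0
DG_PEAK_DISP = 1.0
DG_UNDERSHOOT_DISP = 1.0
DG_RATIO = 6.0

#: Default kernel window, seconds.
DEFAULT_WINDOW = 32.0


@dataclass(frozen=True)
class HRTimecourse:
    """A sampled haemodynamic response or kernel.

    ``samples`` holds fractional signal change per sample on the grid
    ``t = 0, dt, 2·dt, …, floor(window/dt)·dt``.
    """

    samples: np.ndarray
    dt: float
    window: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        expected = int(np.floor(self.window / self.dt + 1e-9)) + 1
        if samples.ndim != 1 or samples.size != expected:
            raise ValueError(
                f"expected {expected} samples for window {self.window} s at "
                f"dt {self.dt} s, got {samples.size}"
            )
        if not np.all(np.isfinite(samples)):
            raise ValueError("non-finite HR samples")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) * self.dt

    def resampled(self, dt: float) -> "HRTimecourse":
        """Linear-interpolation resampling onto a new grid (0 outside)."""
        n = int(np.floor(self.window / dt + 1e-9)) + 1
        t = np.arange(n) * dt
        return HRTimecourse(
            samples=np.interp(t, self.times, self.samples, left=0.0, right=0.0),
            dt=dt,
            window=self.window,
        )


def _double_gamma(t: np.ndarray) -> np.ndarray:
    """Unnormalized two-gamma difference evaluated at times ``t`` (s)."""
    t = np.asarray(t, dtype=float)
    peak = _stats.gamma.pdf(t, a=DG_PEAK_DELAY / DG_PEAK_DISP, scale=DG_PEAK_DISP)
    under = _stats.gamma.pdf(
        t, a=DG_UNDERSHOOT_DELAY / DG_UNDERSHOOT_DISP, scale=DG_UNDERSHOOT_DISP
    )
    return peak - under / DG_RATIO


@lru_cache(maxsize=1)
def _double_gamma_peak_time() -> float:
    """Continuous-time argmax of the double gamma, from a 1 ms grid."""
    t = np.arange(0.0, 12.0, 0.001)
    return float(t[np.argmax(_double_gamma(t))])


def canonical_double_gamma(dt: float, window: float = DEFAULT_WINDOW) -> HRTimecourse:
    """The canonical double-gamma HRF, unit positive extremum.

    Peak delay 6 s, undershoot delay 16 s, undershoot ratio 1/6 — the
    conventional defaults; its argmax sits near 5 s.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if window < 24.0:
        raise ValueError("window must cover at least 24 s")
    n = int(np.floor(window / dt + 1e-9)) + 1
    y = _double_gamma(np.arange(n) * dt)
    return HRTimecourse(samples=y / np.max(y), dt=dt, window=window)


def stretched_double_gamma(
    dt: float, window: float, time_to_peak: float
) -> HRTimecourse:
    """Double gamma with its time axis stretched so the peak lands at
    ``time_to_peak`` seconds; unit positive extremum.

    This is the generative family for synthetic region HRs: it keeps the
    canonical morphology (rise, peak, undershoot) while making latency a free
    parameter, so Table-style lifespan latencies (10–18 s) are expressible.
    """
    if time_to_peak <= 0:
        raise ValueError("time_to_peak must be positive")
    n = int(np.floor(window / dt + 1e-9)) + 1
    t = np.arange(n) * dt
    factor = _double_gamma_peak_time() / time_to_peak
    y = _double_gamma(t * factor)
    return HRTimecourse(samples=y / np.max(y), dt=dt, window=window)


def normalize_hr(hr: HRTimecourse) -> HRTimecourse:
    """Divide by the maximum absolute amplitude, preserving sign.

    The extremum magnitude of the output is exactly 1.  A negative-going HR
    therefore keeps its polarity (extremum −1); a GLM fitted with such a
    kernel yields a positive beta for a decreasing signal, so downstream
    consumers must read maps from the contrast aligned with the kernel's
    polarity.
    """
    peak = np.max(np.abs(hr.samples))
    if peak == 0:
        raise ValueError("cannot normalize an all-zero HR")
    return HRTimecourse(samples=hr.samples / peak, dt=hr.dt, window=hr.window)


@dataclass(frozen=True)
class HRMetrics:
    """Peak magnitude (signed fractional signal change) and its latency."""

    peak_magnitude: float
    time_to_peak: float


def hr_metrics(hr: HRTimecourse) -> HRMetrics:
    """Signed extremum and its latency, ties broken by the earliest bin."""
    if np.all(hr.samples == 0):
        raise ValueError("all-zero HR has no peak")
    idx = int(np.argmax(np.abs(hr.samples)))  # argmax returns earliest tie
    return HRMetrics(
        peak_magnitude=float(hr.samples[idx]),
        time_to_peak=float(idx * hr.dt),
    )


def decile_mean_hr(hrs: list[HRTimecourse]) -> HRTimecourse:
    """Pointwise arithmetic mean of HRs on a common grid."""
    if not hrs:
        raise ValueError("empty HR list")
    first = hrs[0]
    for hr in hrs[1:]:
        if hr.dt != first.dt or hr.window != first.window:
            raise ValueError("HRs must share dt and window")
    mean = np.mean(np.stack([hr.samples for hr in hrs]), axis=0)
    return HRTimecourse(samples=mean, dt=first.dt, window=first.window)
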