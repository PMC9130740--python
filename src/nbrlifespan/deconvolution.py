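"""FIR deconvolution of evoked haemodynamic responses from ROI signals.

The evoked response HR is modelled as ``signal = neural input ∗ HR`` with the
neural input taken as a constant-amplitude delta train at the event timings
(all conditions pooled).  Inverting this relation by least squares — one
unknown per post-stimulus lag bin at TR resolution — yields the HR without
assuming any functional form.  Polynomial drift regressors are included as
nuisance terms by default; an optional ridge penalty is available for
ill-conditioned schedules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .events import EventSchedule
from .glm import drift_regressors
from .hrf import (
    HRMetrics,
    HRTimecourse,
    decile_mean_hr,
    hr_metrics,
    normalize_hr,
)

__all__ = [
    "DEFAULT_WINDOW",
    "FIRDeconvolution",
    "FIRDeconvolutionResults",
    "lag_design",
    "fir_convolve",
    "deconvolve_hr",
    "hr_metrics",
    "decile_mean_hr",
    "normalize_hr",
    "HRMetrics",
    "HRTimecourse",
]

#: Default FIR window, seconds; covers latencies up to ~18 s plus recovery.
DEFAULT_WINDOW = 24.0


def n_lag_bins(window: float, tr: float) -> int:
    return int(np.floor(window / tr + 1e-9)) + 1


def lag_design(
    schedule: EventSchedule, tr: float, n_volumes: int, window: float
) -> np.ndarray:
    """Lagged delta-train design: entry (i, k) counts events whose lag to
    volume ``i`` falls in bin ``k`` (bin k covers ``[k·TR, (k+1)·TR)``)."""
    n_lags = n_lag_bins(window, tr)
    X = np.zeros((n_volumes, n_lags))
    vol_times = np.arange(n_volumes) * tr
    for onset in schedule.onsets:
        lags = vol_times - onset
        k = np.floor(lags / tr).astype(int)
        ok = (lags >= 0) & (k < n_lags)
        np.add.at(X, (np.flatnonzero(ok), k[ok]), 1.0)
    return X


def fir_convolve(
    schedule: EventSchedule, hr: HRTimecourse, n_volumes: int
) -> np.ndarray:
    """Forward FIR model: the volume series implied by an HR sampled on the
    TR lag grid (the exact inverse operation of the FIR estimator)."""
    X = lag_design(schedule, hr.dt, n_volumes, hr.window)
    return X @ hr.samples


@dataclass
class FIRDeconvolutionResults:
    """Estimated HR with per-bin standard errors and fit diagnostics."""

    hr: HRTimecourse
    bse: np.ndarray
    drift_coefs: np.ndarray
    residual_sd: float
    degrees_of_freedom: int

    def metrics(self) -> HRMetrics:
        return hr_metrics(self.hr)

    def plot(self, ax=None, **kwargs):
        """Errorbar plot of the estimated HR (± 1 SE) over post-stimulus time."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.axhline(0.0, color="0.7", lw=0.8)
        ax.errorbar(self.hr.times, self.hr.samples, yerr=self.bse, **kwargs)
        ax.set_xlabel("post-stimulus time (s)")
        ax.set_ylabel("signal change (fraction of baseline)")
        return ax

    def summary(self) -> str:
        import pandas as pd

        table = pd.DataFrame(
            {
                "lag_s": self.hr.times,
                "hr": self.hr.samples,
                "se": self.bse,
            }
        ).to_string(index=False, float_format=lambda v: f"{v: .5f}")
        m = None
        try:
            m = self.metrics()
        except ValueError:
            pass
        head = (
            "FIR deconvolution\n"
            f"  window: {self.hr.window} s at dt {self.hr.dt} s, "
            f"df: {self.degrees_of_freedom}, residual SD: {self.residual_sd:.5f}\n"
        )
        if m is not None:
            head += (
                f"  peak magnitude: {m.peak_magnitude:+.5f} at "
                f"{m.time_to_peak:.2f} s\n"
            )
        return head + table


class FIRDeconvolution:
    """Least-squares FIR model of an ROI-mean timecourse.

    Parameters
    ----------
    timecourse : 1-D array
        ROI-mean BOLD series over volumes.
    schedule : EventSchedule
        Event timings; all conditions are pooled into a single
        constant-amplitude delta train.
    tr : float
        Repetition time, seconds; also the lag-bin width.
    window : float
        Post-stimulus window covered by the FIR basis, seconds.
    drift_order : int or None
        Degree of Legendre drift nuisance regressors (None disables; the
        constant term is included whenever drift is on).
    ridge : float
        Optional Tikhonov penalty on the FIR coefficients (0 = plain OLS).
    """

    def __init__(
        self,
        timecourse: np.ndarray,
        schedule: EventSchedule,
        tr: float,
        window: float = DEFAULT_WINDOW,
        drift_order: int | None = 2,
        ridge: float = 0.0,
    ):
        y = np.asarray(timecourse, dtype=float)
        if y.ndim != 1:
            raise ValueError("timecourse must be 1-D")
        if window / tr < 2:
            raise ValueError("window must cover at least 2 lag bins")
        if ridge < 0:
            raise ValueError("ridge must be non-negative")
        self.y = y
        self.schedule = schedule
        self.tr = float(tr)
        self.window = float(window)
        self.drift_order = drift_order
        self.ridge = float(ridge)

    def fit(self) -> FIRDeconvolutionResults:
        n_volumes = self.y.size
        n_lags = n_lag_bins(self.window, self.tr)
        X_fir = lag_design(self.schedule, self.tr, n_volumes, self.window)
        if self.drift_order is not None:
            X_dr = drift_regressors(n_volumes, self.drift_order)
        else:
            X_dr = np.empty((n_volumes, 0))
        X = np.hstack([X_fir, X_dr])
        if self.ridge == 0 and np.linalg.matrix_rank(X) < X.shape[1]:
            # greedy scan to name the offending lag bins in the error
            bad: list[int] = []
            cur = X_dr
            rank = np.linalg.matrix_rank(cur) if cur.size else 0
            for k in range(n_lags):
                aug = np.hstack([cur, X_fir[:, [k]]])
                r2 = np.linalg.matrix_rank(aug)
                if r2 == rank:
                    bad.append(k)
                else:
                    cur, rank = aug, r2
            raise ValueError(
                f"rank-deficient lag design; offending lag bins: {bad}"
            )
        n, p = X.shape
        df = n - p
        if df <= 0:
            raise ValueError("more parameters than volumes")
        gram = X.T @ X
        if self.ridge > 0:
            penalty = np.zeros(p)
            penalty[:n_lags] = self.ridge
            gram = gram + np.diag(penalty)
        gram_inv = np.linalg.inv(gram)
        beta = gram_inv @ X.T @ self.y
        resid = self.y - X @ beta
        sigma2 = float(resid @ resid) / max(df, 1)
        bse = np.sqrt(sigma2 * np.diag(gram_inv)[:n_lags])
        hr = HRTimecourse(
            samples=beta[:n_lags], dt=self.tr, window=(n_lags - 1) * self.tr
        )
        return FIRDeconvolutionResults(
            hr=hr,
            bse=bse,
            drift_coefs=beta[n_lags:],
            residual_sd=float(np.sqrt(sigma2)),
            degrees_of_freedom=df,
        )


def deconvolve_hr(
    timecourse: np.ndarray,
    schedule: EventSchedule,
    tr: float,
    window: float = DEFAULT_WINDOW,
    drift_order: int | None = 2,
    ridge: float = 0.0,
) -> HRTimecourse:
    """Functional wrapper: fit the FIR model and return the HR alone."""
    return (
        FIRDeconvolution(timecourse, schedule, tr, window, drift_order, ridge)
        .fit()
        .hr
    )
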