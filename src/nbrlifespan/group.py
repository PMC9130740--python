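"""Second-level maps and cohort statistics.

Voxelwise group models (mean + mean-subtracted covariate, pairwise group
differences) plus the scalar machinery used on ROI statistics: one-way
ANOVA, Welch post-hoc t-tests, Pearson correlations, age residualization and
the nested-regression incremental-variance F-test.  p-values are reported
uncorrected; a Bonferroni column is provided where tables are emitted rather
than silently correcting.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .glm import t_to_z


@dataclass
class SecondLevelMaps:
    """Voxelwise group mean and covariate-slope maps with Z statistics."""

    mean_beta: np.ndarray
    mean_z: np.ndarray
    covariate_beta: np.ndarray
    covariate_z: np.ndarray
    degrees_of_freedom: int

    def summary(self) -> str:
        finite = np.isfinite(self.covariate_z)
        return (
            "Second-level GLM (mean + mean-subtracted covariate)\n"
            f"  df: {self.degrees_of_freedom}\n"
            f"  mean-effect |Z| max: {np.nanmax(np.abs(self.mean_z)):.3f}\n"
            f"  covariate |Z| max: {np.nanmax(np.abs(self.covariate_z[finite])):.3f}"
        )


def second_level_mean_covariate(
    subject_maps: list[np.ndarray] | np.ndarray, covariate: np.ndarray
) -> SecondLevelMaps:
    """Per-voxel OLS on [ones, covariate − mean(covariate)].

    The intercept beta equals the sample-mean map exactly (the demeaned
    covariate is orthogonal to the intercept); the covariate Z map carries
    positive and negative age effects with sign.
    """
    maps = np.stack([np.asarray(m, dtype=float) for m in subject_maps])
    cov = np.asarray(covariate, dtype=float)
    n = maps.shape[0]
    if cov.shape != (n,):
        raise ValueError("one covariate value per subject required")
    if n < 3:
        raise ValueError("need at least 3 subjects")
    c = cov - cov.mean()
    if np.allclose(c, 0):
        raise ValueError("constant covariate")
    X = np.column_stack([np.ones(n), c])
    grid = maps.shape[1:]
    Y = maps.reshape(n, -1)
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y
    resid = Y - X @ beta
    df = n - 2
    sigma2 = np.sum(resid**2, axis=0) / df
    z = np.empty((2,) + sigma2.shape)
    for j in range(2):
        with np.errstate(divide="ignore", invalid="ignore"):
            t = beta[j] / np.sqrt(sigma2 * xtx_inv[j, j])
        z[j] = t_to_z(t, df)
    return SecondLevelMaps(
        mean_beta=beta[0].reshape(grid),
        mean_z=z[0].reshape(grid),
        covariate_beta=beta[1].reshape(grid),
        covariate_z=z[1].reshape(grid),
        degrees_of_freedom=df,
    )


def pairwise_decile_difference(
    maps_a: list[np.ndarray] | np.ndarray, maps_b: list[np.ndarray] | np.ndarray
) -> np.ndarray:
    """Per-voxel pooled-variance two-sample t (a − b), mapped to Z.

    Voxels with zero pooled variance are flagged invalid (NaN).
    """
    A = np.stack([np.asarray(m, dtype=float) for m in maps_a])
    B = np.stack([np.asarray(m, dtype=float) for m in maps_b])
    na, nb = A.shape[0], B.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("both groups need at least 2 subjects")
    df = na + nb - 2
    mean_diff = A.mean(axis=0) - B.mean(axis=0)
    ss = (na - 1) * A.var(axis=0, ddof=1) + (nb - 1) * B.var(axis=0, ddof=1)
    pooled = ss / df
    se = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean_diff / se
    t[se == 0] = np.nan
    return t_to_z(t, df)


def one_way_anova(groups: list[np.ndarray]) -> tuple[float, int, int, float]:
    """Classical between/within decomposition → (F, df1, df2, p)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need ≥ 2 groups with ≥ 2 values each")
    allv = np.concatenate(groups)
    if np.all(allv == allv[0]):
        raise ValueError("all values identical: F undefined (0/0)")
    f, p = _stats.f_oneway(*groups)
    df1 = len(groups) - 1
    df2 = allv.size - len(groups)
    return float(f), df1, df2, float(p)


def posthoc_ttests(
    groups: list[np.ndarray], labels: list[str] | None = None
) -> pd.DataFrame:
    """Welch two-sample t-test per group pair.

    Uncorrected p-values plus a Bonferroni column (never silently applied).
    Degenerate pairs (both groups constant and equal) are flagged NaN.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    rows = []
    n_pairs = len(groups) * (len(groups) - 1) // 2
    for (i, a), (j, b) in combinations(enumerate(groups), 2):
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            t, p = (np.nan, np.nan)
        else:
            t, p = _stats.ttest_ind(a, b, equal_var=False)
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "t": float(t),
                "p": float(p),
                "p_bonferroni": float(min(1.0, p * n_pairs)) if np.isfinite(p) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def pearson_corr(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Product-moment correlation with its t-transform p-value (n−2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors with n ≥ 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance input")
    r, p = _stats.pearsonr(x, y)
    return float(r), float(p)


def residualize_on_age(values: np.ndarray, ages: np.ndarray) -> np.ndarray:
    """Residuals of a simple linear regression of ``values`` on ``ages``."""
    values = np.asarray(values, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if values.size != ages.size or values.size < 3:
        raise ValueError("need equal-length vectors with n ≥ 3")
    if np.var(ages) == 0:
        raise ValueError("constant age vector")
    X = np.column_stack([np.ones(ages.size), ages])
    beta, *_ = np.linalg.lstsq(X, values, rcond=None)
    return values - X @ beta


def nested_regression_f(
    y: np.ndarray,
    base_predictors: np.ndarray,
    added_predictor: np.ndarray,
) -> tuple[float, float, float]:
    """Partial F-test for one added predictor over a base OLS model.

    Returns (ΔR², F, p).  The base design gets an intercept prepended; a
    collinear added predictor raises.
    """
    y = np.asarray(y, dtype=float)
    base = np.atleast_2d(np.asarray(base_predictors, dtype=float))
    if base.shape[0] != y.size:
        base = base.T
    added = np.asarray(added_predictor, dtype=float)
    n = y.size
    X0 = np.column_stack([np.ones(n), base])
    if np.linalg.matrix_rank(X0) < X0.shape[1]:
        raise ValueError("base model is rank deficient")
    X1 = np.column_stack([X0, added])
    if np.linalg.matrix_rank(X1) < X1.shape[1]:
        raise ValueError("added predictor is collinear with the base model")
    p1 = X1.shape[1]
    if n <= p1 + 1:
        raise ValueError("too few observations for the nested comparison")

    def rss(X: np.ndarray) -> float:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    rss0, rss1 = rss(X0), rss(X1)
    tss = float(np.sum((y - y.mean()) ** 2))
    delta_r2 = (rss0 - rss1) / tss if tss > 0 else 0.0
    df2 = n - p1
    f = max(0.0, (rss0 - rss1)) / (rss1 / df2) if rss1 > 0 else np.inf
    p = float(_stats.f.sf(f, 1, df2)) if np.isfinite(f) else 0.0
    return float(delta_r2), float(f), p


def regression_slope_ci(
    x: np.ndarray, y: np.ndarray, alpha: float = 0.05
) -> tuple[float, float, float]:
    """OLS slope of y on x with its two-sided (1−alpha) confidence bounds."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3 or np.var(x) == 0:
        raise ValueError("need n ≥ 3 with non-constant x")
    res = _stats.linregress(x, y)
    half = float(_stats.t.ppf(1 - alpha / 2, n - 2)) * res.stderr
    return float(res.slope), float(res.slope - half), float(res.slope + half)
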