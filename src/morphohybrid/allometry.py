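"""Size analysis and shape-size regression.

Group tests on log10 centroid size (one-way ANOVA plus pairwise t-tests with
Bonferroni correction), multivariate regression of shape variables on log
size with a permutation test on the explained variance, and a residual
randomization (RRPP) test of allometric-slope homogeneity among groups.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AllometryResult",
    "size_anova",
    "shape_size_regression",
    "slope_homogeneity",
]


@dataclasses.dataclass
class AllometryResult:
    r_squared: float
    p_value: float
    slope: np.ndarray                       # pooled regression coefficient vector
    slope_vectors: dict[str, np.ndarray] | None = None  # per-group slopes
    homogeneity_p: float | None = None      # size x group interaction


def size_anova(
    log_sizes: Sequence[float], labels: Sequence[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One-way ANOVA on log10 centroid size plus all pairwise t-tests
    (pooled variance) with Bonferroni correction.

    Returns ``(anova_table, pairwise_table)``.
    """
    y = np.asarray(log_sizes, dtype=float)
    labels = np.asarray(labels)
    groups = sorted(set(labels))
    if len(groups) < 2:
        raise ValueError("size ANOVA needs at least 2 groups")
    samples = [y[labels == g] for g in groups]
    for g, s in zip(groups, samples):
        if s.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 specimens")
    if all(np.ptp(s) == 0 for s in samples) and np.ptp(y) == 0:
        f_stat, p = 0.0, 1.0
        flag = "zero within-group variance"
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            f_stat, p = stats.f_oneway(*samples)
        flag = ""
        if not np.isfinite(f_stat):
            f_stat, p, flag = np.inf, 0.0, "zero within-group variance"
    anova = pd.DataFrame(
        {
            "F": [float(f_stat)],
            "p": [float(p)],
            "df_between": [len(groups) - 1],
            "df_within": [y.size - len(groups)],
            "flag": [flag],
        }
    )
    pairs = list(itertools.combinations(range(len(groups)), 2))
    rows = []
    for i, j in pairs:
        t, pt = stats.ttest_ind(samples[i], samples[j], equal_var=True)
        rows.append(
            (groups[i], groups[j], float(t), float(pt), min(1.0, float(pt) * len(pairs)))
        )
    pairwise = pd.DataFrame(rows, columns=["group_a", "group_b", "t", "p", "p_adj"])
    return anova, pairwise


def _multivariate_fit(x_design: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Least squares of every column of ``y`` on ``x_design``.

    Returns ``(coefficients, residual sum of squares trace)``.
    """
    coef, *_ = np.linalg.lstsq(x_design, y, rcond=None)
    resid = y - x_design @ coef
    return coef, float((resid**2).sum())


def shape_size_regression(
    shape_variables: np.ndarray,
    log_sizes: Sequence[float],
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
) -> AllometryResult:
    """Multivariate regression of shape variables on log10 centroid size.

    R² is trace(SS_model)/trace(SS_total); significance permutes the size
    values against the shapes.
    """
    y = np.asarray(shape_variables, dtype=float)
    x = np.asarray(log_sizes, dtype=float)
    n = y.shape[0]
    if n < 4:
        raise ValueError("shape-size regression needs n ≥ 4")
    if np.ptp(x) == 0:
        raise ValueError("constant size vector: slope undefined")
    yc = y - y.mean(axis=0)
    xc = x - x.mean()
    sxx = float(xc @ xc)
    ss_total = float((yc**2).sum())
    if ss_total == 0:
        return AllometryResult(r_squared=0.0, p_value=1.0, slope=np.zeros(y.shape[1]))

    def r2_of(xc_: np.ndarray) -> float:
        beta = (xc_ @ yc) / (xc_ @ xc_)
        return float((xc_ @ xc_) * (beta**2).sum() / ss_total)

    slope = (xc @ yc) / sxx
    r2 = r2_of(xc)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        if r2_of(rng.permutation(xc)) >= r2 - 1e-15:
            exceed += 1
    return AllometryResult(
        r_squared=r2,
        p_value=(exceed + 1) / (n_perm + 1),
        slope=slope,
    )


def _design_matrices(x: np.ndarray, labels: np.ndarray):
    groups = sorted(set(labels))
    n = x.size
    dummies = np.column_stack([(labels == g).astype(float) for g in groups[1:]])
    xc = (x - x.mean())[:, None]
    reduced = np.column_stack([np.ones(n), xc, dummies])
    full = np.column_stack([reduced, dummies * xc])
    return reduced, full, groups


def slope_homogeneity(
    shape_variables: np.ndarray,
    log_sizes: Sequence[float],
    labels: Sequence[str],
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float, dict[str, np.ndarray]]:
    """Test of common allometric slopes among groups by residual
    randomization (RRPP).

    Compares the full model (size + group + size x group) to the reduced
    model (size + group) on summed squared deviations; the null refits both
    models to datasets rebuilt from the reduced model's fitted values plus
    permuted reduced-model residuals. A small p means the slopes are NOT
    parallel. Returns ``(p, observed pseudo-F, per-group slope vectors)``.
    """
    y = np.asarray(shape_variables, dtype=float)
    x = np.asarray(log_sizes, dtype=float)
    labels = np.asarray(labels)
    groups = sorted(set(labels))
    if len(groups) < 2:
        raise ValueError("slope homogeneity needs ≥ 2 groups")
    for g in groups:
        mask = labels == g
        if mask.sum() < 3:
            raise ValueError(f"group {g!r} has fewer than 3 specimens")
        if np.ptp(x[mask]) == 0:
            raise ValueError(f"group {g!r} has constant size")
    reduced, full, groups = _design_matrices(x, labels)
    n = y.shape[0]
    df1 = full.shape[1] - reduced.shape[1]
    df2 = n - full.shape[1]
    coef_r, rss_r = _multivariate_fit(reduced, y)
    _, rss_f = _multivariate_fit(full, y)

    def pseudo_f(rss_red: float, rss_full: float) -> float:
        if rss_full <= 0:
            return 0.0 if rss_red <= rss_full + 1e-30 else np.inf
        return ((rss_red - rss_full) / df1) / (rss_full / df2)

    f_obs = pseudo_f(rss_r, rss_f)
    fitted_r = reduced @ coef_r
    resid_r = y - fitted_r
    # Precompute annihilator matrices so each permutation is two matmuls.
    pinv_r = np.linalg.pinv(reduced)
    pinv_f = np.linalg.pinv(full)
    ann_r = np.eye(n) - reduced @ pinv_r
    ann_f = np.eye(n) - full @ pinv_f
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        y_star = fitted_r + resid_r[rng.permutation(n)]
        rss_r_s = float(((ann_r @ y_star) ** 2).sum())
        rss_f_s = float(((ann_f @ y_star) ** 2).sum())
        if pseudo_f(rss_r_s, rss_f_s) >= f_obs - 1e-15:
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)

    # per-group slope vectors from group-wise simple regressions
    slopes: dict[str, np.ndarray] = {}
    for g in groups:
        mask = labels == g
        xg = x[mask] - x[mask].mean()
        yg = y[mask] - y[mask].mean(axis=0)
        slopes[g] = (xg @ yg) / float(xg @ xg)
    return float(p), float(f_obs), slopes
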