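"""Shape-space ordination, group testing and disparity.

PCA of tangent-space shape variables, PC retention by explained variance,
pairwise and two-way MANOVA (Wilks' Λ via statsmodels), Procrustes variance
per group and permutation tests for pairwise disparity differences.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.multivariate.manova import MANOVA

__all__ = [
    "PCAResult",
    "DisparityResult",
    "pca",
    "retain_pcs",
    "pairwise_manova",
    "two_way_manova",
    "procrustes_variance",
    "disparity_pairwise",
]


class DegenerateDataError(ValueError):
    """Data carry no usable variation for the requested test."""


@dataclasses.dataclass
class PCAResult:
    eigenvalues: np.ndarray         # non-negative, descending
    axes: np.ndarray                # (n_axes, p) orthonormal loadings (rows)
    scores: np.ndarray              # (n, n_axes)
    variance_fractions: np.ndarray  # eigenvalues / sum
    mean: np.ndarray                # (p,) column means removed before the SVD
    degenerate: bool = False

    @property
    def n_axes(self) -> int:
        return self.axes.shape[0]


@dataclasses.dataclass
class DisparityResult:
    variances: dict[str, float]
    pairwise_p: dict[tuple[str, str], float]
    pairwise_p_raw: dict[tuple[str, str], float] = dataclasses.field(default_factory=dict)
    flags: dict[str, str] = dataclasses.field(default_factory=dict)


def pca(shape_variables: np.ndarray) -> PCAResult:
    """Eigendecomposition of the specimen covariance of shape variables.

    For 3D Procrustes data at most ``min(n-1, 3k-7)`` axes carry variance.
    Axis signs follow the convention that the largest-magnitude loading of
    each axis is positive.
    """
    x = np.asarray(shape_variables, dtype=float)
    n, p = x.shape
    if n < 3:
        raise ValueError("PCA needs at least 3 specimens")
    mean = x.mean(axis=0)
    xc = x - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    eig = s**2 / (n - 1)
    total = eig.sum()
    if total == 0:
        return PCAResult(
            eigenvalues=np.zeros(1),
            axes=np.zeros((1, p)),
            scores=np.zeros((n, 1)),
            variance_fractions=np.zeros(1),
            mean=mean,
            degenerate=True,
        )
    keep = eig > max(1e-12 * total, 0.0)
    keep[0] = True
    eig, vt, u, s = eig[keep], vt[keep], u[:, keep], s[keep]
    # deterministic axis signs
    flip = np.sign(vt[np.arange(vt.shape[0]), np.argmax(np.abs(vt), axis=1)])
    vt = vt * flip[:, None]
    scores = xc @ vt.T
    return PCAResult(
        eigenvalues=eig,
        axes=vt,
        scores=scores,
        variance_fractions=eig / total,
        mean=mean,
    )


def retain_pcs(result: PCAResult, threshold: float = 0.90) -> list[int]:
    """Indices of the smallest leading axis set explaining ≥ ``threshold``."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    cum = np.cumsum(result.variance_fractions)
    m = int(np.searchsorted(cum, threshold - 1e-12) + 1)
    m = min(m, result.n_axes)
    return list(range(m))


def _wilks_from_manova(endog: np.ndarray, labels: np.ndarray, term: str = "C(group)"):
    p = endog.shape[1]
    if p == 1:
        # Wilks' test on a single response is the classical one-way F test
        from scipy.stats import f_oneway

        groups = [endog[labels == g, 0] for g in sorted(set(labels))]
        f_val, p_val = f_oneway(*groups)
        n, k = endog.shape[0], len(groups)
        wilks = 1.0 / (1.0 + f_val * (k - 1) / (n - k))
        return float(wilks), float(f_val), float(p_val)
    cols = [f"y{i}" for i in range(p)]
    df = pd.DataFrame(endog, columns=cols)
    df["group"] = labels
    formula = "+".join(cols) + " ~ C(group)"
    res = MANOVA.from_formula(formula, data=df).mv_test()
    stat = res.results[term]["stat"]
    return (
        float(stat.loc["Wilks' lambda", "Value"]),
        float(stat.loc["Wilks' lambda", "F Value"]),
        float(stat.loc["Wilks' lambda", "Pr > F"]),
    )


def pairwise_manova(
    scores: np.ndarray,
    labels: Sequence[str],
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Pairwise multivariate location tests (Wilks' Λ with F approximation)
    on retained PC scores, Bonferroni-corrected over the pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    groups = sorted(set(labels))
    if len(groups) < 2:
        raise ValueError("pairwise MANOVA needs at least 2 groups")
    p = scores.shape[1]
    for g in groups:
        n_g = int((labels == g).sum())
        if n_g <= p:
            raise DegenerateDataError(
                f"group {g!r} has n={n_g} ≤ {p} retained axes; lower the "
                "PC retention threshold"
            )
        sub = scores[labels == g]
        if np.linalg.matrix_rank(sub - sub.mean(axis=0)) < min(p, n_g - 1):
            raise DegenerateDataError(
                f"singular within-group covariance in group {g!r}"
            )
    pairs = list(itertools.combinations(groups, 2))
    n_pairs = len(pairs)
    rows = []
    for a, b in pairs:
        mask = (labels == a) | (labels == b)
        wilks, fval, pval = _wilks_from_manova(scores[mask], labels[mask])
        p_adj = min(1.0, pval * n_pairs) if correction == "bonferroni" else pval
        rows.append((a, b, wilks, fval, pval, p_adj))
    return pd.DataFrame(
        rows, columns=["group_a", "group_b", "wilks_lambda", "F", "p", "p_adj"]
    )


def two_way_manova(
    scores: np.ndarray,
    species: Sequence[str],
    sex: Sequence[str | None],
    exclude_sexes: tuple[str, ...] = ("gelding",),
) -> dict[str, float]:
    """Crossed species x sex multivariate linear model on PC scores.

    Geldings (and specimens of unknown sex) are excluded from the sex factor.
    Returns Wilks' Λ p-values for both main effects and the interaction; a
    significant interaction is the pipeline's trigger for sex-stratified
    reanalysis of the bone.
    """
    scores = np.asarray(scores, dtype=float)
    species = np.asarray(species)
    sex = np.asarray([s if s is not None else "" for s in sex])
    mask = ~np.isin(sex, list(exclude_sexes) + [""])
    scores, species, sex = scores[mask], species[mask], sex[mask]
    if len(set(species)) < 2 or len(set(sex)) < 2:
        raise DegenerateDataError(
            "two-way MANOVA needs ≥ 2 observed levels of both factors "
            f"(found species={sorted(set(species))}, sex={sorted(set(sex))})"
        )
    empty = [
        (a, b)
        for a in sorted(set(species))
        for b in sorted(set(sex))
        if not np.any((species == a) & (sex == b))
    ]
    if empty:
        raise DegenerateDataError(f"empty cells in species x sex cross: {empty}")
    p = scores.shape[1]
    cols = [f"y{i}" for i in range(p)]
    df = pd.DataFrame(scores, columns=cols)
    df["species"] = species
    df["sex"] = sex
    if p == 1:
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        fit = smf.ols("y0 ~ C(species) * C(sex)", data=df).fit()
        table = sm.stats.anova_lm(fit, typ=2)

        def _p(term):
            return float(table.loc[term, "PR(>F)"])

    else:
        res = MANOVA.from_formula(
            "+".join(cols) + " ~ C(species) * C(sex)", data=df
        ).mv_test()

        def _p(term):
            return float(res.results[term]["stat"].loc["Wilks' lambda", "Pr > F"])

    return {
        "species_p": _p("C(species)"),
        "sex_p": _p("C(sex)"),
        "interaction_p": _p("C(species):C(sex)"),
        "n_used": int(mask.sum()),
    }


def procrustes_variance(
    shape_variables: np.ndarray, labels: Sequence[str]
) -> dict[str, float]:
    """Morphological disparity per group: mean squared tangent distance of
    group members to their group mean shape (divisor n)."""
    x = np.asarray(shape_variables, dtype=float)
    labels = np.asarray(labels)
    out: dict[str, float] = {}
    for g in sorted(set(labels)):
        sub = x[labels == g]
        if sub.shape[0] < 2:
            raise DegenerateDataError(
                f"group {g!r} is a singleton: Procrustes variance undefined"
            )
        dev = sub - sub.mean(axis=0)
        out[g] = float((dev**2).sum() / sub.shape[0])
    return out


def disparity_pairwise(
    shape_variables: np.ndarray,
    labels: Sequence[str],
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
    correction: str = "bonferroni",
) -> DisparityResult:
    """Permutation comparison of group Procrustes variances.

    Statistic |var_i - var_j|. The null randomizes the residuals from the
    group mean shapes across specimens (residual randomization): squared
    residual norms are exchangeable between groups when dispersions are
    equal, regardless of how far apart the group means sit — permuting raw
    group labels instead would mix the mean separation into the permuted
    variances and destroy the test's level.
    p = (count permuted ≥ observed + 1) / (n_perm + 1), Bonferroni over pairs.
    """
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    x = np.asarray(shape_variables, dtype=float)
    labels = np.asarray(labels)
    groups = sorted(set(labels))
    g_index = {g: i for i, g in enumerate(groups)}
    idx = np.array([g_index[l] for l in labels])
    n_groups = len(groups)
    counts = np.bincount(idx, minlength=n_groups).astype(float)
    # squared residual norms from each specimen's own group mean
    resid2 = np.empty(len(x))
    for i in range(n_groups):
        mask = idx == i
        dev = x[mask] - x[mask].mean(axis=0)
        resid2[mask] = (dev**2).sum(axis=1)
    obs_var = np.bincount(idx, weights=resid2, minlength=n_groups) / counts
    pairs = list(itertools.combinations(range(n_groups), 2))
    obs_stat = np.array([abs(obs_var[i] - obs_var[j]) for i, j in pairs])

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    exceed = np.zeros(len(pairs))
    for _ in range(n_perm):
        perm2 = rng.permutation(resid2)
        var = np.bincount(idx, weights=perm2, minlength=n_groups) / counts
        stat = np.array([abs(var[i] - var[j]) for i, j in pairs])
        exceed += stat >= obs_stat - 1e-15
    p_raw = (exceed + 1) / (n_perm + 1)
    factor = len(pairs) if correction == "bonferroni" else 1
    p_adj = np.minimum(1.0, p_raw * factor)
    return DisparityResult(
        variances={g: float(obs_var[g_index[g]]) for g in groups},
        pairwise_p={
            (groups[i], groups[j]): float(p_adj[m]) for m, (i, j) in enumerate(pairs)
        },
        pairwise_p_raw={
            (groups[i], groups[j]): float(p_raw[m]) for m, (i, j) in enumerate(pairs)
        },
    )
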