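"""Transgression and dominance of hybrid mean shape.

Both indices are built from Euclidean distances between group mean shapes in
the full tangent-space shape variables.

* Degree of transgression: the excess of the summed hybrid-parent distances
  over the inter-parent distance, as a percentage of the inter-parent
  distance: ``(dDHy + dHoHy - dDHo) * 100 / dDHo``. It is 0 exactly when the
  hybrid mean lies on the segment joining the parent means, and grows as the
  hybrid mean moves off that segment.
* Degree of dominance: the deviation of the donkey-hybrid distance from the
  average hybrid-parent distance, as a percentage of that average:
  ``(m - dDHy) * 100 / m`` with ``m = (dDHy + dHoHy) / 2``. Positive values
  mean the hybrids sit closer to the donkeys, negative closer to the horses;
  the extremes ±100 are reached when the hybrid mean coincides with a parent
  mean. (Published statements of the dominance formula sometimes write the
  horse-hybrid distance as dCHy, C for *Equus caballus*; it is the same
  quantity as dHoHy.)
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "HybridIndexResult",
    "group_mean_shapes",
    "transgression_percent",
    "dominance_percent",
    "hybrid_indices",
    "hybrid_indices_with_uncertainty",
]

DONKEY, HORSE, HYBRID = "donkey", "horse", "hybrid"


@dataclasses.dataclass
class HybridIndexResult:
    d_donkey_horse: float
    d_donkey_hybrid: float
    d_horse_hybrid: float
    transgression_pct: float
    dominance_pct: float
    transgression_ci: tuple[float, float] | None = None
    dominance_ci: tuple[float, float] | None = None
    n_boot: int = 0


def group_mean_shapes(
    shape_variables: np.ndarray, labels: Sequence[str]
) -> dict[str, np.ndarray]:
    """Arithmetic mean of the shape variables of each group."""
    x = np.asarray(shape_variables, dtype=float)
    labels = np.asarray(labels)
    out = {}
    for g in sorted(set(labels)):
        out[g] = x[labels == g].mean(axis=0)
    return out


def _distances(means: Mapping[str, np.ndarray]) -> tuple[float, float, float]:
    for g in (DONKEY, HORSE, HYBRID):
        if g not in means:
            raise ValueError(f"missing group {g!r} in mean shapes")
    d_dho = float(np.linalg.norm(means[DONKEY] - means[HORSE]))
    d_dhy = float(np.linalg.norm(means[DONKEY] - means[HYBRID]))
    d_hohy = float(np.linalg.norm(means[HORSE] - means[HYBRID]))
    return d_dho, d_dhy, d_hohy


def transgression_percent(d_donkey_horse: float, d_donkey_hybrid: float, d_horse_hybrid: float) -> float:
    if d_donkey_horse <= 0:
        raise ValueError("coincident parent means: transgression undefined")
    return (d_donkey_hybrid + d_horse_hybrid - d_donkey_horse) * 100.0 / d_donkey_horse


def dominance_percent(d_donkey_hybrid: float, d_horse_hybrid: float) -> float:
    m = (d_donkey_hybrid + d_horse_hybrid) / 2.0
    if m <= 0:
        raise ValueError("hybrid mean coincides with both parents: dominance undefined")
    return (m - d_donkey_hybrid) * 100.0 / m


def hybrid_indices(
    shape_variables: np.ndarray, labels: Sequence[str]
) -> HybridIndexResult:
    """Point estimates of the three mean-shape distances and both indices."""
    means = group_mean_shapes(shape_variables, labels)
    d_dho, d_dhy, d_hohy = _distances(means)
    return HybridIndexResult(
        d_donkey_horse=d_dho,
        d_donkey_hybrid=d_dhy,
        d_horse_hybrid=d_hohy,
        transgression_pct=transgression_percent(d_dho, d_dhy, d_hohy),
        dominance_pct=dominance_percent(d_dhy, d_hohy),
    )


def hybrid_indices_with_uncertainty(
    shape_variables: np.ndarray,
    labels: Sequence[str],
    n_boot: int = 999,
    seed: int | np.random.Generator = 0,
    ci: float = 0.95,
) -> HybridIndexResult:
    """Point estimates plus nonparametric bootstrap percentile intervals.

    Specimens are resampled with replacement within each group; the indices
    are recomputed on each replicate.
    """
    if n_boot < 100:
        raise ValueError("use at least 100 bootstrap replicates")
    x = np.asarray(shape_variables, dtype=float)
    labels = np.asarray(labels)
    for g in (DONKEY, HORSE, HYBRID):
        if (labels == g).sum() < 5:
            raise ValueError(f"group {g!r} needs n ≥ 5 for the bootstrap")
    result = hybrid_indices(x, labels)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = {g: np.flatnonzero(labels == g) for g in (DONKEY, HORSE, HYBRID)}
    trans = np.empty(n_boot)
    dom = np.empty(n_boot)
    for b in range(n_boot):
        means = {
            g: x[rng.choice(rows, size=rows.size, replace=True)].mean(axis=0)
            for g, rows in idx.items()
        }
        d_dho, d_dhy, d_hohy = _distances(means)
        trans[b] = transgression_percent(d_dho, d_dhy, d_hohy)
        dom[b] = dominance_percent(d_dhy, d_hohy)
    lo, hi = (1 - ci) / 2 * 100, (1 + ci) / 2 * 100
    result.transgression_ci = tuple(np.percentile(trans, [lo, hi]))
    result.dominance_ci = tuple(np.percentile(dom, [lo, hi]))
    result.n_boot = n_boot
    return result
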