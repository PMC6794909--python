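"""Morphological integration between bones via two-block partial least squares.

The cross-covariance matrix of two centered blocks of shape variables is
decomposed by SVD; paired singular axes maximize the covariance between
blocks. rPLS is the Pearson correlation of the first-axis score pair, its
significance comes from permuting the specimens of one block, and a
standardized effect size (z-score of the Fisher-transformed rPLS against its
permutation null) makes integration strength comparable between datasets of
different size and dimension. Networks of rPLS over anatomically defined bone
pair sets (serial homologs, within-limb adjacent bones, functional
equivalents) summarize the integration pattern of each group.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .procrustes import AlignedSample

__all__ = [
    "BonePairSet",
    "PLSResult",
    "default_pair_sets",
    "two_block_pls",
    "pls_permutation_test",
    "pls_effect_size",
    "compare_effect_sizes",
    "covariation_network",
    "pls_shape_changes",
]


@dataclasses.dataclass
class BonePairSet:
    """A named family of anatomically motivated bone pairs."""

    name: str
    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        seen = set()
        for a, b in self.pairs:
            key = frozenset((a, b))
            if key in seen:
                raise ValueError(f"duplicate pair {a}-{b} in set {self.name!r}")
            seen.add(key)


def default_pair_sets() -> list[BonePairSet]:
    """The shipped pair families over the sixteen equid limb bones.

    Serial homologs pair developmentally corresponding fore- and hind-limb
    elements; within-limb adjacency follows the proximo-distal chains (with
    talus and calcaneus both linked to tibia and metatarsal); functional
    equivalents pair bones playing matching mechanical roles across limbs
    after the therian reorganization of the skeleton.
    """
    serial = BonePairSet(
        "serial_homologs",
        [
            ("scapula", "coxal"),
            ("humerus", "femur"),
            ("radioulna", "tibia"),
            ("metacarpal", "metatarsal"),
            ("prox_phal_ant", "prox_phal_post"),
            ("mid_phal_ant", "mid_phal_post"),
            ("dist_phal_ant", "dist_phal_post"),
        ],
    )
    adjacent = BonePairSet(
        "within_limb_adjacent",
        [
            ("scapula", "humerus"),
            ("humerus", "radioulna"),
            ("radioulna", "metacarpal"),
            ("metacarpal", "prox_phal_ant"),
            ("prox_phal_ant", "mid_phal_ant"),
            ("mid_phal_ant", "dist_phal_ant"),
            ("coxal", "femur"),
            ("femur", "tibia"),
            ("tibia", "talus"),
            ("tibia", "calcaneus"),
            ("talus", "metatarsal"),
            ("calcaneus", "metatarsal"),
            ("metatarsal", "prox_phal_post"),
            ("prox_phal_post", "mid_phal_post"),
            ("mid_phal_post", "dist_phal_post"),
        ],
    )
    functional = BonePairSet(
        "functional_equivalents",
        [
            ("scapula", "femur"),
            ("humerus", "tibia"),
            ("radioulna", "metatarsal"),
        ],
    )
    return [serial, adjacent, functional]


@dataclasses.dataclass
class PLSResult:
    singular_values: np.ndarray
    covariance_fractions: np.ndarray
    block1_axes: np.ndarray   # (n_axes, p) rows
    block2_axes: np.ndarray   # (n_axes, q) rows
    block1_scores: np.ndarray
    block2_scores: np.ndarray
    r_pls: float
    p_value: float | None = None
    permuted_r: np.ndarray | None = None
    z_score: float | None = None
    z_se: float | None = None
    n_perm: int | None = None
    seed: int | None = None

    @property
    def n(self) -> int:
        return self.block1_scores.shape[0]


def _first_axis_r(xc: np.ndarray, yc: np.ndarray) -> float:
    u, s, vt = np.linalg.svd(xc.T @ yc, full_matrices=False)
    s1 = xc @ u[:, 0]
    s2 = yc @ vt[0]
    denom = np.linalg.norm(s1) * np.linalg.norm(s2)
    if denom == 0:
        return 0.0
    return float(s1 @ s2 / denom)


def two_block_pls(block1: np.ndarray, block2: np.ndarray) -> PLSResult:
    """Singular decomposition of the between-block cross-covariance.

    Blocks must hold the same specimens in the same order. ``r_pls`` is the
    Pearson correlation of the first pair of axis scores;
    ``covariance_fractions`` are the squared singular values normalized to
    sum 1.
    """
    x = np.asarray(block1, dtype=float)
    y = np.asarray(block2, dtype=float)
    if x.shape[0] != y.shape[0]:
        raise ValueError(
            f"specimen mismatch: block1 has {x.shape[0]} rows, block2 {y.shape[0]}"
        )
    n = x.shape[0]
    if n < 4:
        raise ValueError("two-block PLS needs n ≥ 4")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    u, s, vt = np.linalg.svd(xc.T @ yc / (n - 1), full_matrices=False)
    r = min(len(s), n - 1)
    u, s, vt = u[:, :r], s[:r], vt[:r]
    # deterministic sign: largest-|loading| element of each block1 axis positive
    flip = np.sign(u[np.argmax(np.abs(u), axis=0), np.arange(r)])
    u = u * flip
    vt = vt * flip[:, None]
    s1 = xc @ u
    s2 = yc @ vt.T
    with np.errstate(invalid="ignore"):
        r_pls = float(np.corrcoef(s1[:, 0], s2[:, 0])[0, 1])
    if not np.isfinite(r_pls):
        r_pls = 0.0
    total = (s**2).sum()
    fractions = s**2 / total if total > 0 else np.zeros_like(s)
    return PLSResult(
        singular_values=s,
        covariance_fractions=fractions,
        block1_axes=u.T,
        block2_axes=vt,
        block1_scores=s1,
        block2_scores=s2,
        r_pls=r_pls,
    )


def pls_permutation_test(
    block1: np.ndarray,
    block2: np.ndarray,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
) -> PLSResult:
    """Permutation significance of rPLS.

    The specimen rows of block2 are permuted ``n_perm`` times; the first-axis
    correlation is recomputed each time and
    ``p = (count permuted ≥ observed + 1) / (n_perm + 1)``.
    """
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    result = two_block_pls(block1, block2)
    x = np.asarray(block1, dtype=float)
    y = np.asarray(block2, dtype=float)
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = x.shape[0]
    permuted = np.empty(n_perm)
    for b in range(n_perm):
        permuted[b] = _first_axis_r(xc, yc[rng.permutation(n)])
    result.permuted_r = permuted
    result.p_value = float((np.sum(permuted >= result.r_pls - 1e-15) + 1) / (n_perm + 1))
    result.n_perm = n_perm
    z, se = pls_effect_size(result.r_pls, permuted)
    result.z_score, result.z_se = z, se
    return result


def _fisher(r: np.ndarray | float) -> np.ndarray | float:
    return np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))


def pls_effect_size(r_obs: float, permuted_r: np.ndarray) -> tuple[float, float]:
    """Standardized effect size of rPLS against its permutation null.

    ``z = (t(r_obs) - mean(t(r_perm))) / sd(t(r_perm))`` with ``t`` Fisher's
    transformation. Because z studentizes the observed value against its own
    null distribution, its sampling variance under the null is ~1; the
    reported standard error adds the finite-permutation estimation error of
    the null mean and spread:
    ``se = sqrt(1 + 1/N + z^2 / (2 N))`` for ``N`` permutations.
    """
    permuted_r = np.asarray(permuted_r, dtype=float)
    if permuted_r.size < 99:
        raise ValueError("need a permutation distribution of size ≥ 99")
    f_perm = _fisher(permuted_r)
    sd = float(np.std(f_perm, ddof=1))
    if sd <= 1e-12 * max(1.0, abs(float(f_perm.mean()))):
        raise ValueError("zero permutation spread: effect size undefined")
    z = float((_fisher(r_obs) - f_perm.mean()) / sd)
    n = permuted_r.size
    se = float(np.sqrt(1.0 + 1.0 / n + z**2 / (2.0 * n)))
    return z, se


def compare_effect_sizes(result_a: PLSResult, result_b: PLSResult) -> tuple[float, float]:
    """Two-sample comparison of integration effect sizes.

    Statistic ``|z_a - z_b| / sqrt(se_a^2 + se_b^2)`` referred to the standard
    normal (two-sided). Returns ``(statistic, p)``; Bonferroni over a set of
    comparisons is applied by the caller assembling the report.
    """
    for r in (result_a, result_b):
        if r.z_score is None or r.z_se is None:
            raise ValueError("PLSResult lacks effect size; run pls_permutation_test")
    stat = abs(result_a.z_score - result_b.z_score) / np.sqrt(
        result_a.z_se**2 + result_b.z_se**2
    )
    p = 2.0 * float(stats.norm.sf(stat))
    return float(stat), min(1.0, p)


def covariation_network(
    shape_variables: Mapping[str, np.ndarray],
    specimen_ids: Mapping[str, Sequence[str]],
    labels: Mapping[str, str],
    pair_sets: Sequence[BonePairSet],
    n_perm: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
    groups: Sequence[str] | None = None,
) -> pd.DataFrame:
    """rPLS network over bone pairs, per group, with familywise correction.

    ``shape_variables`` maps bone -> (n_bone, p_bone) tangent variables from
    that bone's own GPA; ``specimen_ids`` maps bone -> row specimen ids;
    ``labels`` maps specimen id -> group label. For each group and pair the
    PLS runs on the specimens common to both bones. Bonferroni families
    follow the rule "all tests including a same bone" within a group: an
    edge is significant only if its p-value survives the correction in the
    families of both of its bones. Pairs with fewer than 4 shared specimens
    are skipped with a warning.
    """
    if groups is None:
        groups = sorted(set(labels.values()))
    seed_seq = np.random.SeedSequence(seed)
    rows = []
    all_pairs = [
        (ps.name, a, b) for ps in pair_sets for (a, b) in ps.pairs
    ]
    streams = {
        (g, a, b): np.random.default_rng(s)
        for (g, (ps, a, b)), s in zip(
            itertools.product(groups, all_pairs),
            seed_seq.spawn(len(groups) * len(all_pairs)),
        )
    }
    for g in groups:
        for ps_name, a, b in all_pairs:
            if a not in shape_variables or b not in shape_variables:
                continue  # bone not part of this study
            ids_a = [s for s in specimen_ids[a] if labels.get(s) == g]
            ids_b = set(s for s in specimen_ids[b] if labels.get(s) == g)
            common = [s for s in ids_a if s in ids_b]
            if len(common) < 4:
                warnings.warn(
                    f"pair {a}-{b} in group {g!r}: only {len(common)} shared "
                    "specimens, skipped"
                )
                continue
            row_a = {s: i for i, s in enumerate(specimen_ids[a])}
            row_b = {s: i for i, s in enumerate(specimen_ids[b])}
            xa = np.asarray(shape_variables[a])[[row_a[s] for s in common]]
            xb = np.asarray(shape_variables[b])[[row_b[s] for s in common]]
            res = pls_permutation_test(xa, xb, n_perm=n_perm, seed=streams[(g, a, b)])
            rows.append(
                {
                    "group": g,
                    "bone_a": a,
                    "bone_b": b,
                    "pair_set": ps_name,
                    "n": len(common),
                    "r_pls": res.r_pls,
                    "p": res.p_value,
                    "z": res.z_score,
                    "z_se": res.z_se,
                }
            )
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    # familywise Bonferroni: for each bone the family is every tested pair
    # (within the group) containing it; an edge must survive in both families
    p_adj = np.zeros(len(table))
    for g in groups:
        in_group = (table["group"] == g).to_numpy()
        bones = set(table.loc[in_group, "bone_a"]) | set(table.loc[in_group, "bone_b"])
        for bone in bones:
            fam = in_group & (
                (table["bone_a"] == bone) | (table["bone_b"] == bone)
            ).to_numpy()
            m = int(fam.sum())
            p_adj[fam] = np.maximum(
                p_adj[fam], np.minimum(1.0, table.loc[fam, "p"].to_numpy() * m)
            )
    table["p_adj"] = p_adj
    table["significant"] = table["p_adj"] < alpha
    return table


def network_graph(table: pd.DataFrame, group: str):
    """Edge-list -> networkx graph for one group (rendering convenience)."""
    import networkx as nx

    g = nx.Graph()
    sub = table[table["group"] == group]
    for _, row in sub.iterrows():
        g.add_edge(
            row["bone_a"],
            row["bone_b"],
            r_pls=row["r_pls"],
            p_adj=row["p_adj"],
            z=row["z"],
            pair_set=row["pair_set"],
            significant=bool(row["significant"]),
        )
    return g


@dataclasses.dataclass
class ShapeChangeResult:
    block1_shapes: tuple[np.ndarray, np.ndarray]  # (low, high) k x 3 shapes
    block2_shapes: tuple[np.ndarray, np.ndarray]
    block1_displacements: np.ndarray  # per-landmark displacement norms
    block2_displacements: np.ndarray


def pls_shape_changes(
    result: PLSResult,
    aligned1: AlignedSample,
    aligned2: AlignedSample,
    quantile: float = 0.95,
) -> ShapeChangeResult:
    """Consensus shapes deformed along the first PLS axes to score quantiles.

    For each block the consensus is displaced by the first-axis loading
    vector times the requested (and the mirrored) score quantile; the
    per-landmark Euclidean displacement norms between the two extremes are
    the basis of covariation-intensity visualizations.
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    out_shapes = []
    out_disp = []
    for aligned, axes, scores in (
        (aligned1, result.block1_axes, result.block1_scores),
        (aligned2, result.block2_axes, result.block2_scores),
    ):
        lo = float(np.quantile(scores[:, 0], min(quantile, 1 - quantile)))
        hi = float(np.quantile(scores[:, 0], max(quantile, 1 - quantile)))
        axis = axes[0]
        k = aligned.consensus.shape[0]
        delta = axis.reshape(k, 3)
        shape_lo = aligned.consensus + lo * delta
        shape_hi = aligned.consensus + hi * delta
        out_shapes.append((shape_lo, shape_hi))
        out_disp.append(np.linalg.norm((hi - lo) * delta, axis=1))
    return ShapeChangeResult(
        block1_shapes=out_shapes[0],
        block2_shapes=out_shapes[1],
        block1_displacements=out_disp[0],
        block2_displacements=out_disp[1],
    )
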