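"""Superimposition core: centroid size, ordinary and generalized Procrustes
analysis, tangent-space shape variables and Procrustes distances.

The fit is the full Procrustes fit: every configuration is centered and
scaled to unit centroid size, then rotated (proper rotations only) to the
iteratively updated consensus. Size is analysed separately via centroid size,
so shape variables are scale-free. The converged consensus is oriented along
its principal axes with a deterministic sign convention, which makes the
output invariant (to tolerance) under arbitrary rotation, translation and
scaling of any input.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np

from .geometry import batched_rotations, center, centroid_size, kabsch_rotation
from .io import LandmarkConfiguration

__all__ = [
    "AlignedSample",
    "centroid_size",
    "ordinary_procrustes",
    "procrustes_distance",
    "gpa",
    "tangent_project",
]


class DegenerateShapeError(ValueError):
    """All landmarks coincident: shape undefined."""


@dataclasses.dataclass
class AlignedSample:
    """Result of GPA on one bone: consensus, superimposed coordinates,
    centroid sizes and flattened tangent-space shape variables."""

    bone_id: str
    specimen_ids: list[str]
    landmark_ids: tuple[str, ...]
    consensus: np.ndarray        # (k, 3), centered at the origin
    aligned_coords: np.ndarray   # (n, k, 3), each with unit centroid size
    centroid_sizes: np.ndarray   # (n,)
    shape_variables: np.ndarray  # (n, 3k) tangent projection
    iterations_used: int
    converged: bool = True

    @property
    def n(self) -> int:
        return self.aligned_coords.shape[0]

    @property
    def k(self) -> int:
        return self.consensus.shape[0]


def _as_coords(config) -> np.ndarray:
    if isinstance(config, LandmarkConfiguration):
        return config.oriented_coords()
    return np.asarray(config, dtype=float)


def _center_scale(coords: np.ndarray) -> np.ndarray:
    c = center(coords)
    size = np.sqrt((c**2).sum())
    if size == 0:
        raise DegenerateShapeError("all landmarks coincident")
    return c / size


def ordinary_procrustes(a, b) -> tuple[np.ndarray, np.ndarray, float]:
    """Ordinary (pairwise) Procrustes superimposition of ``b`` onto ``a``.

    Both configurations are centered and scaled to unit centroid size; the
    returned proper rotation (determinant +1) minimizes the root summed
    squared deviation. Returns ``(rotation, aligned_b, distance)``; the
    distance is symmetric in its arguments.
    """
    ca, cb = _as_coords(a), _as_coords(b)
    if ca.shape != cb.shape:
        raise ValueError(f"landmark count mismatch: {ca.shape} vs {cb.shape}")
    ca, cb = _center_scale(ca), _center_scale(cb)
    rot = kabsch_rotation(cb, ca)
    aligned = cb @ rot
    dist = float(np.sqrt(((ca - aligned) ** 2).sum()))
    return rot, aligned, dist


def procrustes_distance(a, b) -> float:
    return ordinary_procrustes(a, b)[2]


def gpa(
    configs: Sequence,
    max_iter: int = 100,
    tol: float = 1e-10,
    bone_id: str | None = None,
    shape_variable_kind: str = "tangent",
) -> AlignedSample:
    """Generalized Procrustes analysis of ≥ 2 configurations with common k.

    Iteratively rotates all unit-size configurations to the running consensus
    until the root-mean-square change of the consensus drops below ``tol``.
    Non-convergence in ``max_iter`` raises a warning and reports
    ``iterations_used``. ``shape_variable_kind`` selects tangent-projected
    shape variables (default) or raw Procrustes residuals.
    """
    configs = list(configs)
    if len(configs) < 2:
        raise ValueError("GPA needs at least 2 configurations")
    first = configs[0]
    if bone_id is None:
        bone_id = getattr(first, "bone_id", "bone")
    specimen_ids = [
        getattr(c, "specimen_id", f"spec{i + 1}") for i, c in enumerate(configs)
    ]
    landmark_ids = getattr(first, "landmark_ids", None) or tuple(
        f"L{i + 1}" for i in range(_as_coords(first).shape[0])
    )
    raw = [_as_coords(c) for c in configs]
    ks = {r.shape[0] for r in raw}
    if len(ks) != 1:
        raise ValueError(f"configurations differ in landmark count: {sorted(ks)}")
    sizes = np.array([centroid_size(r) for r in raw])
    x = np.stack([_center_scale(r) for r in raw])  # (n, k, 3)

    reference = x[0].copy()
    reference /= np.sqrt((reference**2).sum())
    iterations = 0
    converged = False
    for iterations in range(1, max_iter + 1):
        rots = batched_rotations(x, reference)
        x = np.einsum("nkj,njl->nkl", x, rots)
        consensus = x.mean(axis=0)
        consensus -= consensus.mean(axis=0)
        new_ref = consensus / np.sqrt((consensus**2).sum())
        delta = np.sqrt(((new_ref - reference) ** 2).mean())
        reference = new_ref
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"GPA did not converge in {max_iter} iterations (last RMS change "
            f"{delta:.3e})",
            RuntimeWarning,
        )

    # Orient the consensus along its principal axes (deterministic up to the
    # sign convention below) so repeated runs and rigidly transformed inputs
    # produce the same output frame.
    consensus = x.mean(axis=0)
    consensus -= consensus.mean(axis=0)
    rot = _principal_axes_rotation(consensus)
    consensus = consensus @ rot
    x = np.einsum("nkj,jl->nkl", x, rot)
    consensus = x.mean(axis=0)
    consensus -= consensus.mean(axis=0)

    sample = AlignedSample(
        bone_id=bone_id,
        specimen_ids=specimen_ids,
        landmark_ids=tuple(landmark_ids),
        consensus=consensus,
        aligned_coords=x,
        centroid_sizes=sizes,
        shape_variables=np.empty((len(configs), 0)),
        iterations_used=iterations,
        converged=converged,
    )
    sample.shape_variables = tangent_project(sample, kind=shape_variable_kind)
    return sample


def _principal_axes_rotation(consensus: np.ndarray) -> np.ndarray:
    """Rotation taking the consensus onto its principal axes, with signs fixed
    so the landmark with the largest |projection| scores positive on each axis."""
    cov = consensus.T @ consensus
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    rot = eigvec[:, order]
    proj = consensus @ rot
    for j in range(2):
        i = np.argmax(np.abs(proj[:, j]))
        if proj[i, j] < 0:
            rot[:, j] *= -1.0
    # Third axis by right-hand rule: keeps the transform a proper rotation.
    rot[:, 2] = np.cross(rot[:, 0], rot[:, 1])
    return rot


def tangent_project(aligned: AlignedSample, kind: str = "tangent") -> np.ndarray:
    """Flattened deviations from the consensus.

    ``kind='tangent'`` (default) orthogonally projects each specimen onto the
    tangent space at the consensus pole before taking deviations, the
    convention of the classic morphometrics toolkits; ``kind='residual'``
    returns plain Procrustes residuals. For small deviations the Euclidean
    distance between two specimens' shape variables approximates their
    Procrustes distance.
    """
    flat = aligned.aligned_coords.reshape(aligned.n, -1)
    c = aligned.consensus.ravel()
    c_hat = c / np.linalg.norm(c)
    if kind == "residual":
        dev = flat - c
    elif kind == "tangent":
        proj = flat - np.outer(flat @ c_hat, c_hat)
        dev = proj - proj.mean(axis=0)
    else:
        raise ValueError(f"unknown shape variable kind {kind!r}")
    return dev - dev.mean(axis=0)
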