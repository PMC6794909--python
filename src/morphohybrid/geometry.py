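"""Low-level shape-space geometry shared by the Procrustes core and the generator.

Configurations are ``(k, 3)`` arrays of landmark coordinates; flattened shape
vectors use row-major order ``[x0, y0, z0, x1, ...]`` throughout the package.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "center",
    "centroid_size",
    "similarity_basis",
    "complement_project",
    "orthonormal_complement_directions",
    "kabsch_rotation",
    "random_rotation",
]


def centroid_size(coords: np.ndarray) -> float:
    """Square root of the summed squared landmark distances to their centroid.

    The standard size measure of geometric morphometrics: invariant to
    rotation and translation, and linear under isotropic scaling.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 2:
        raise ValueError("centroid size needs at least 2 landmarks")
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    centered = coords - coords.mean(axis=0)
    return float(np.sqrt((centered**2).sum()))


def center(coords: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    return coords - coords.mean(axis=0)


# Infinitesimal rotation generators about the three coordinate axes.
_SKEW = np.array(
    [
        [[0.0, 0.0, 0.0], [0.0, 0.0, -1.0], [0.0, 1.0, 0.0]],
        [[0.0, 0.0, 1.0], [0.0, 0.0, 0.0], [-1.0, 0.0, 0.0]],
        [[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 0.0]],
    ]
)


def similarity_basis(reference: np.ndarray) -> np.ndarray:
    """Orthonormal basis (rows) of the similarity-transform tangent space.

    At a centered reference shape the 7-dimensional subspace spanned by
    infinitesimal translations (3), rotations (3) and scaling (1) carries no
    shape information; tangent-space noise and planted effect directions must
    live in its orthogonal complement or superimposition would absorb them.
    """
    ref = center(np.asarray(reference, dtype=float))
    k = ref.shape[0]
    size = np.sqrt((ref**2).sum())
    if size == 0:
        raise ValueError("degenerate reference: all landmarks coincident")
    ref = ref / size
    rows = []
    for j in range(3):
        t = np.zeros((k, 3))
        t[:, j] = 1.0 / np.sqrt(k)
        rows.append(t.ravel())
    rows.append(ref.ravel())  # scaling direction
    for a in _SKEW:
        rows.append((ref @ a.T).ravel())
    basis = np.array(rows)
    # Translations/scale are already orthonormal; orthonormalize the rotation
    # generators against everything via QR on the transpose.
    q, r = np.linalg.qr(basis.T)
    keep = np.abs(np.diag(r)) > 1e-10
    basis = q.T[keep]
    # Fix signs so the basis is deterministic.
    for row in basis:
        j = np.argmax(np.abs(row))
        if row[j] < 0:
            row *= -1.0
    return basis


def complement_project(vectors: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Project flattened vectors onto the orthogonal complement of ``basis`` rows."""
    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    out = vectors - (vectors @ basis.T) @ basis
    return out


def orthonormal_complement_directions(
    reference: np.ndarray, n_dirs: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n_dirs`` orthonormal flattened directions orthogonal to the
    similarity subspace at ``reference`` (and to each other)."""
    basis = similarity_basis(reference)
    k3 = basis.shape[1]
    if n_dirs > k3 - basis.shape[0]:
        raise ValueError(
            f"requested {n_dirs} directions but only {k3 - basis.shape[0]} "
            "shape dimensions are available; increase the landmark count"
        )
    dirs = []
    stack = basis.copy()
    while len(dirs) < n_dirs:
        v = rng.standard_normal(k3)
        v = v - (stack @ v) @ stack
        norm = np.linalg.norm(v)
        if norm < 1e-8:
            continue
        v /= norm
        dirs.append(v)
        stack = np.vstack([stack, v])
    return np.array(dirs)


def kabsch_rotation(moving: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation ``R`` minimizing ``||target - moving @ R||_F``.

    Both inputs must be centered. The determinant is constrained to +1 so
    anatomical configurations are never silently mirrored.
    """
    m = np.asarray(moving, dtype=float)
    t = np.asarray(target, dtype=float)
    u, _, vt = np.linalg.svd(m.T @ t)
    d = np.sign(np.linalg.det(u @ vt))
    u[:, -1] *= d
    return u @ vt


def batched_rotations(moving: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotations aligning each configuration in ``moving`` (n,k,3) to ``target`` (k,3)."""
    m = np.einsum("nkj,kl->njl", moving, target)  # n x 3 x 3 cross products
    u, _, vt = np.linalg.svd(m)
    det = np.linalg.det(np.einsum("nij,njk->nik", u, vt))
    u[:, :, -1] *= det[:, None]
    return np.einsum("nij,njk->nik", u, vt)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (QR of a Gaussian matrix, det +1)."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1.0
    return q
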