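"""Superimposition core: closed forms, independent oracles and invariances."""

import itertools

import numpy as np
import pytest

from morphohybrid.geometry import random_rotation
from morphohybrid.procrustes import (
    DegenerateShapeError,
    centroid_size,
    gpa,
    ordinary_procrustes,
    procrustes_distance,
)
from tests.conftest import random_config


def quaternion_grid_distance(a, b, n_coarse=20000, n_refine=8):
    """Brute-force minimal Procrustes deviation over proper rotations,
    parameterized by unit quaternions: deterministic coarse covering of S^3
    followed by shrinking local grids around the incumbent.

    Independent of the SVD solution path: only evaluates the objective.
    """

    def unit_size(x):
        x = x - x.mean(axis=0)
        return x / np.sqrt((x**2).sum())

    a = unit_size(np.asarray(a, float))
    b = unit_size(np.asarray(b, float))
    m = b.T @ a  # d^2(R) = 2 - 2 * sum(R * m)

    def quat_to_mats(q):
        q = q / np.linalg.norm(q, axis=1, keepdims=True)
        w, x, y, z = q.T
        return np.stack(
            [
                np.stack([1 - 2 * (y**2 + z**2), 2 * (x * y - w * z), 2 * (x * z + w * y)], -1),
                np.stack([2 * (x * y + w * z), 1 - 2 * (x**2 + z**2), 2 * (y * z - w * x)], -1),
                np.stack([2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x**2 + y**2)], -1),
            ],
            axis=1,
        )

    def best(q):
        mats = quat_to_mats(q)
        scores = np.einsum("nij,ij->n", mats, m)
        i = int(np.argmax(scores))
        return q[i], scores[i]

    # deterministic low-discrepancy covering of the quaternion sphere
    i = np.arange(n_coarse, dtype=float) + 0.5
    alphas = 2 * np.pi * np.array([i * 0.5545497, i * 0.3080986, i / n_coarse]).T
    u = i / n_coarse
    q0 = np.stack(
        [
            np.sqrt(1 - u) * np.sin(alphas[:, 0]),
            np.sqrt(1 - u) * np.cos(alphas[:, 0]),
            np.sqrt(u) * np.sin(alphas[:, 1]),
            np.sqrt(u) * np.cos(alphas[:, 1]),
        ],
        axis=1,
    )
    q_best, score = best(q0)
    h = 0.2
    deltas = np.array(list(itertools.product(*[(-1, -0.5, 0, 0.5, 1)] * 3)))
    for _ in range(n_refine):
        perturbed = q_best[None, :] + h * (deltas @ _quat_frame(q_best))
        q_try = np.vstack([q_best, perturbed])
        q_best, score = best(q_try)
        h *= 0.35
    return float(np.sqrt(max(0.0, 2.0 - 2.0 * score)))


def _quat_frame(q):
    """Orthonormal frame of the tangent space of S^3 at q (rows)."""
    basis = np.eye(4)
    frame = []
    for e in basis:
        v = e - (e @ q) * q
        for f in frame:
            v = v - (v @ f) * f
        n = np.linalg.norm(v)
        if n > 1e-8:
            frame.append(v / n)
    return np.array(frame[:3] + [np.zeros(4)])[:3, :]


class TestCentroidSize:
    def test_unit_square_closed_form(self):
        square = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float)
        assert centroid_size(square) == pytest.approx(np.sqrt(2), abs=1e-12)

    def test_homogeneity_and_rigid_invariance(self, rng):
        cfg = random_config(rng, k=9)
        s = centroid_size(cfg)
        assert centroid_size(3.0 * cfg) == pytest.approx(3.0 * s, rel=1e-12)
        moved = cfg @ random_rotation(rng).T + rng.standard_normal(3)
        assert centroid_size(moved) == pytest.approx(s, rel=1e-10)

    def test_matches_brute_force_summation(self, rng):
        cfg = random_config(rng, k=10)
        centroid = cfg.mean(axis=0)
        brute = np.sqrt(sum(((p - centroid) ** 2).sum() for p in cfg))
        assert abs(centroid_size(cfg) - brute) < 1e-12

    def test_coincident_landmarks_flagged(self):
        from morphohybrid.geometry import centroid_size as cs

        assert cs(np.ones((4, 3))) == 0.0


class TestOrdinaryProcrustes:
    def test_rotated_copy_distance_zero(self, rng):
        a = random_config(rng, k=6)
        b = (a @ random_rotation(rng).T) * 2.5 + rng.standard_normal(3)
        _, _, d = ordinary_procrustes(a, b)
        assert d < 1e-9

    def test_reflection_not_absorbed(self, rng):
        a = random_config(rng, k=6)
        b = a.copy()
        b[:, 0] *= -1
        rot, _, d = ordinary_procrustes(a, b)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)
        assert d > 0.05

    def test_distance_symmetric(self, rng):
        a, b = random_config(rng, k=7), random_config(rng, k=7)
        assert procrustes_distance(a, b) == pytest.approx(
            procrustes_distance(b, a), abs=1e-12
        )

    def test_k_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            ordinary_procrustes(random_config(rng, k=5), random_config(rng, k=6))

    def test_matches_quaternion_grid_oracle(self, rng):
        for _ in range(5):
            a, b = random_config(rng, k=4), random_config(rng, k=4)
            d_svd = procrustes_distance(a, b)
            d_grid = quaternion_grid_distance(a, b)
            assert abs(d_svd - d_grid) < 1e-4

    def test_triangle_inequality(self, rng):
        for _ in range(10):
            a, b, c = (random_config(rng, k=5) for _ in range(3))
            dab, dbc, dac = (
                procrustes_distance(a, b),
                procrustes_distance(b, c),
                procrustes_distance(a, c),
            )
            assert dac <= dab + dbc + 1e-9


class TestGPA:
    def test_identical_up_to_similarity_collapses(self, rng):
        base = random_config(rng, k=8)
        configs = [
            (base @ random_rotation(rng).T) * rng.uniform(0.5, 2.0)
            + rng.standard_normal(3)
            for _ in range(6)
        ]
        aligned = gpa(configs)
        flat = aligned.aligned_coords.reshape(6, -1)
        d = np.linalg.norm(flat[:, None] - flat[None, :], axis=-1)
        assert d.max() < 1e-8

    def test_invariants_unit_size_and_consensus_mean(self, aligned_humerus):
        al = aligned_humerus
        for coords in al.aligned_coords:
            c = coords - coords.mean(axis=0)
            assert np.sqrt((c**2).sum()) == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(
            al.consensus, al.aligned_coords.mean(axis=0), atol=1e-9
        )
        assert np.abs(al.consensus.mean(axis=0)).max() < 1e-9

    def test_two_configurations_consensus_equidistant(self, rng):
        a, b = random_config(rng, k=6), random_config(rng, k=6)
        aligned = gpa([a, b])
        d = np.linalg.norm(
            aligned.aligned_coords - aligned.consensus[None], axis=(1, 2)
        )
        assert d[0] == pytest.approx(d[1], abs=1e-9)

    def test_consensus_optimality_probe(self, rng):
        configs = [random_config(rng, k=6) + 4 * np.eye(6, 3) for _ in range(20)]
        aligned = gpa(configs)
        ref = aligned.consensus
        at_consensus = sum(procrustes_distance(c, ref) ** 2 for c in configs)
        for _ in range(100):
            other = ref + 0.3 * rng.standard_normal(ref.shape)
            at_other = sum(procrustes_distance(c, other) ** 2 for c in configs)
            assert at_consensus <= at_other + 1e-9

    def test_order_independence(self, small_study):
        dataset, _ = small_study
        configs = dataset.configurations_for_bone("humerus")
        fwd = gpa(configs)
        rev = gpa(configs[::-1])
        np.testing.assert_allclose(fwd.consensus, rev.consensus, atol=1e-9)
        d_fwd = np.linalg.norm(
            fwd.shape_variables[0] - fwd.shape_variables[-1]
        )
        d_rev = np.linalg.norm(
            rev.shape_variables[-1] - rev.shape_variables[0]
        )
        assert d_fwd == pytest.approx(d_rev, abs=1e-9)

    def test_rigid_motion_of_inputs_changes_nothing(self, small_study, rng):
        dataset, _ = small_study
        configs = dataset.configurations_for_bone("humerus")
        ref = gpa(configs)
        moved = [
            (c.coords @ random_rotation(rng).T) * rng.uniform(0.2, 5.0)
            + 10 * rng.standard_normal(3)
            for c in configs
        ]
        out = gpa(moved)
        np.testing.assert_allclose(out.consensus, ref.consensus, atol=1e-8)
        np.testing.assert_allclose(
            out.shape_variables, ref.shape_variables, atol=1e-8
        )

    def test_degenerate_input_rejected(self):
        with pytest.raises(DegenerateShapeError):
            gpa([np.ones((4, 3)), np.zeros((4, 3))])


class TestTangentSpace:
    def test_mean_of_shape_variables_is_zero(self, aligned_humerus):
        assert np.abs(aligned_humerus.shape_variables.mean(axis=0)).max() < 1e-9

    def test_small_deviation_distances_match_procrustes(self, rng):
        base = random_config(rng, k=10)
        configs = [base + 0.01 * rng.standard_normal(base.shape) for _ in range(12)]
        aligned = gpa(configs)
        v = aligned.shape_variables
        for i, j in [(0, 1), (2, 7), (4, 11)]:
            d_t = np.linalg.norm(v[i] - v[j])
            d_p = procrustes_distance(
                aligned.aligned_coords[i], aligned.aligned_coords[j]
            )
            assert abs(d_t - d_p) / d_p < 0.01
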