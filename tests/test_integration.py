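"""Two-block PLS, permutation tests, effect sizes and covariation networks."""

import numpy as np
import pytest

import morphohybrid as mh
from morphohybrid.integration import (
    BonePairSet,
    compare_effect_sizes,
    covariation_network,
    default_pair_sets,
    pls_effect_size,
    pls_permutation_test,
    pls_shape_changes,
    two_block_pls,
)


def _coupled_blocks(rng, n=30, p=10, q=12, coupling=0.8):
    latent = rng.standard_normal(n)
    wa = np.zeros(p)
    wa[0] = 1.0
    wb = np.zeros(q)
    wb[0] = 1.0
    x = rng.standard_normal((n, p))
    y = rng.standard_normal((n, q))
    x[:, 0] = np.sqrt(coupling) * latent + np.sqrt(1 - coupling) * x[:, 0]
    y[:, 0] = np.sqrt(coupling) * latent + np.sqrt(1 - coupling) * y[:, 0]
    # give the coupled direction a dominant variance share
    x[:, 0] *= 3.0
    y[:, 0] *= 3.0
    return x, y


class TestTwoBlockPLS:
    def test_self_covariation_r_one(self, rng):
        x = rng.standard_normal((20, 6))
        res = two_block_pls(x, x)
        assert res.r_pls == pytest.approx(1.0, abs=1e-9)

    def test_rank_one_construction_concentrates_covariance(self, rng):
        latent = rng.standard_normal(500)
        x = np.outer(latent, rng.standard_normal(7))
        y = np.outer(latent, rng.standard_normal(9))
        res = two_block_pls(x, y)
        assert res.covariance_fractions[0] == pytest.approx(1.0, abs=1e-9)

    def test_singular_values_match_dense_eigen_oracle(self, rng):
        x = rng.standard_normal((6, 4))
        y = rng.standard_normal((6, 5))
        res = two_block_pls(x, y)
        xc, yc = x - x.mean(0), y - y.mean(0)
        c = xc.T @ yc / 5
        eig = np.linalg.eigvalsh(c @ c.T)[::-1]
        eig = np.sqrt(np.clip(eig, 0, None))
        np.testing.assert_allclose(res.singular_values, eig[: len(res.singular_values)],
                                   atol=1e-10)

    def test_r_symmetric_in_block_order(self, rng):
        x, y = _coupled_blocks(rng)
        assert two_block_pls(x, y).r_pls == pytest.approx(
            two_block_pls(y, x).r_pls, abs=1e-12
        )

    def test_invariant_to_blockwise_orthogonal_transform(self, rng):
        x, y = _coupled_blocks(rng)
        qx = np.linalg.qr(rng.standard_normal((x.shape[1],) * 2))[0]
        qy = np.linalg.qr(rng.standard_normal((y.shape[1],) * 2))[0]
        assert two_block_pls(x @ qx, y @ qy).r_pls == pytest.approx(
            two_block_pls(x, y).r_pls, abs=1e-9
        )

    def test_specimen_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            two_block_pls(rng.standard_normal((8, 3)), rng.standard_normal((9, 3)))


class TestPermutationTest:
    def test_seed_reproducible(self, rng):
        x, y = _coupled_blocks(rng)
        a = pls_permutation_test(x, y, n_perm=199, seed=11)
        b = pls_permutation_test(x, y, n_perm=199, seed=11)
        assert a.p_value == b.p_value
        np.testing.assert_array_equal(a.permuted_r, b.permuted_r)

    def test_coupled_blocks_detected(self, rng):
        hits = 0
        for _ in range(20):
            x, y = _coupled_blocks(rng, coupling=0.8)
            res = pls_permutation_test(x, y, n_perm=199, seed=rng)
            hits += res.p_value < 0.05
        assert hits >= 19

    def test_p_monotone_in_coupling(self, rng):
        ps = []
        for coupling in (0.0, 0.45, 0.9):
            p_here = []
            for _ in range(10):
                x, y = _coupled_blocks(rng, n=40, coupling=coupling)
                p_here.append(
                    pls_permutation_test(x, y, n_perm=199, seed=rng).p_value
                )
            ps.append(np.mean(p_here))
        assert ps[0] > ps[1] > ps[2]


class TestEffectSize:
    def test_observed_at_null_mean_gives_zero(self, rng):
        perm = 0.5 + 0.05 * rng.standard_normal(500)
        z, se = pls_effect_size(float(np.tanh(np.mean(np.arctanh(perm)))), perm)
        assert z == pytest.approx(0.0, abs=0.05)
        assert se == pytest.approx(1.0, abs=0.05)

    def test_tight_null_far_observation_large_z(self, rng):
        perm = 0.05 * rng.standard_normal(500)
        z, _ = pls_effect_size(0.9, perm)
        assert z > 3.0

    def test_zero_spread_rejected(self):
        with pytest.raises(ValueError, match="zero permutation spread"):
            pls_effect_size(0.5, np.full(200, 0.3))

    def test_null_z_scale_free_where_raw_r_is_not(self, rng):
        # The point of the standardized effect: the null expectation of raw
        # rPLS moves strongly with sample size (overfitting of the
        # cross-covariance), while the studentized z stays ~N(0, 1) at every
        # n, making uncoupled datasets of different size directly comparable.
        null_r, null_z = {}, {}
        for n in (20, 80):
            rs, zs = [], []
            for _ in range(30):
                x = rng.standard_normal((n, 10))
                y = rng.standard_normal((n, 12))
                res = pls_permutation_test(x, y, n_perm=199, seed=rng)
                rs.append(res.r_pls)
                zs.append(res.z_score)
            null_r[n], null_z[n] = np.mean(rs), np.mean(zs)
        assert null_r[20] - null_r[80] > 0.2  # raw r strongly n-dependent
        assert abs(null_z[20]) < 0.75 and abs(null_z[80]) < 0.75


class TestCompareEffectSizes:
    def test_identical_results_statistic_zero(self, rng):
        x, y = _coupled_blocks(rng)
        res = pls_permutation_test(x, y, n_perm=199, seed=3)
        stat, p = compare_effect_sizes(res, res)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_strong_vs_null_coupling_detected(self, rng):
        hits = 0
        for _ in range(15):
            x1, y1 = _coupled_blocks(rng, coupling=0.9)
            x0, y0 = _coupled_blocks(rng, coupling=0.0)
            ra = pls_permutation_test(x1, y1, n_perm=199, seed=rng)
            rb = pls_permutation_test(x0, y0, n_perm=199, seed=rng)
            _, p = compare_effect_sizes(ra, rb)
            hits += p < 0.05
        assert hits >= 13

    def test_missing_se_rejected(self, rng):
        x, y = _coupled_blocks(rng)
        res = two_block_pls(x, y)
        with pytest.raises(ValueError, match="effect size"):
            compare_effect_sizes(res, res)


class TestNetwork:
    def test_default_pair_sets_reference_known_bones(self):
        from morphohybrid.io import BONES

        for ps in default_pair_sets():
            for a, b in ps.pairs:
                assert a in BONES and b in BONES

    def test_duplicate_pair_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            BonePairSet("s", [("humerus", "femur"), ("femur", "humerus")])

    def test_too_few_shared_specimens_skipped(self, rng):
        shape_vars = {
            "humerus": rng.standard_normal((3, 6)),
            "femur": rng.standard_normal((3, 6)),
        }
        ids = {"humerus": ["a", "b", "c"], "femur": ["a", "b", "c"]}
        labels = {"a": "horse", "b": "horse", "c": "horse"}
        with pytest.warns(UserWarning, match="shared"):
            table = covariation_network(
                shape_vars, ids, labels,
                [BonePairSet("s", [("humerus", "femur")])],
                n_perm=99, seed=0,
            )
        assert table.empty

    def test_same_seed_identical_table(self, small_study):
        dataset, _ = small_study
        aligned = {
            b: mh.gpa(dataset.configurations_for_bone(b), bone_id=b)
            for b in dataset.bones
        }
        labels = {s.specimen_id: dataset.analysis_label(s) for s in dataset.specimens}
        kwargs = dict(
            shape_variables={b: a.shape_variables for b, a in aligned.items()},
            specimen_ids={b: a.specimen_ids for b, a in aligned.items()},
            labels=labels,
            pair_sets=[BonePairSet("s", [("humerus", "femur")])],
            n_perm=99,
            seed=21,
        )
        t1 = covariation_network(**kwargs)
        t2 = covariation_network(**kwargs)
        assert t1.equals(t2)


class TestShapeChanges:
    def _aligned_pair(self, rng, coupling=0.9):
        spec = mh.GeneratorSpec(
            bones={"humerus": 8, "femur": 8},
            n_per_group={"donkey": 40},
            n_mules=0,
            integration=[("humerus", "femur", coupling)],
            seed=9,
        )
        dataset, _ = mh.generate_study(spec)
        a1 = mh.gpa(dataset.configurations_for_bone("humerus"), bone_id="humerus")
        a2 = mh.gpa(dataset.configurations_for_bone("femur"), bone_id="femur")
        return a1, a2

    def test_median_quantile_is_consensus(self, rng):
        a1, a2 = self._aligned_pair(rng)
        res = two_block_pls(a1.shape_variables, a2.shape_variables)
        out = pls_shape_changes(res, a1, a2, quantile=0.5)
        np.testing.assert_allclose(out.block1_shapes[0], out.block1_shapes[1],
                                   atol=1e-12)
        np.testing.assert_allclose(
            out.block1_shapes[0], a1.consensus,
            atol=0.2 * np.abs(a1.consensus).max(),
        )

    def test_displacements_rotation_invariant(self, rng):
        a1, a2 = self._aligned_pair(rng)
        res = two_block_pls(a1.shape_variables, a2.shape_variables)
        out = pls_shape_changes(res, a1, a2, quantile=0.9)
        from morphohybrid.geometry import random_rotation

        rot = random_rotation(rng)
        import dataclasses

        a1_rot = dataclasses.replace(
            a1,
            consensus=a1.consensus @ rot.T,
            aligned_coords=np.einsum("nkj,lj->nkl", a1.aligned_coords, rot),
        )
        # the loading vector rotates with the frame: recompute PLS on rotated vars
        k = a1.consensus.shape[0]
        rot_block = np.kron(np.eye(k), rot)
        res_rot = two_block_pls(a1.shape_variables @ rot_block.T, a2.shape_variables)
        out_rot = pls_shape_changes(res_rot, a1_rot, a2, quantile=0.9)
        np.testing.assert_allclose(
            out.block1_displacements, out_rot.block1_displacements, atol=1e-8
        )

    def test_planted_landmarks_carry_largest_displacement(self, rng):
        # couple the blocks through one loading direction; the landmarks with
        # the largest loading norms must show the largest displacements
        a1, a2 = self._aligned_pair(rng, coupling=0.95)
        res = pls_permutation_test(a1.shape_variables, a2.shape_variables,
                                   n_perm=99, seed=0)
        out = pls_shape_changes(res, a1, a2, quantile=0.95)
        loading_norms = np.linalg.norm(res.block1_axes[0].reshape(-1, 3), axis=1)
        top_loaded = set(np.argsort(loading_norms)[-3:])
        top_displaced = set(np.argsort(out.block1_displacements)[-3:])
        assert top_loaded == top_displaced
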