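"""Ordination, MANOVA and disparity: closed forms, oracles, calibration."""

import numpy as np
import pytest
from scipy import stats as sps

from morphohybrid.shape_stats import (
    DegenerateDataError,
    disparity_pairwise,
    pairwise_manova,
    pca,
    procrustes_variance,
    retain_pcs,
    two_way_manova,
)


class TestPCA:
    def test_collinear_data_single_axis(self, rng):
        direction = rng.standard_normal(9)
        x = np.outer(rng.standard_normal(20), direction)
        res = pca(x)
        assert res.variance_fractions[0] == pytest.approx(1.0, abs=1e-12)
        assert res.n_axes == 1 or np.all(res.variance_fractions[1:] < 1e-12)

    def test_eigenvalue_sum_equals_total_variance(self, rng):
        x = rng.standard_normal((25, 12))
        res = pca(x)
        total = ((x - x.mean(0)) ** 2).sum() / (x.shape[0] - 1)
        assert res.eigenvalues.sum() == pytest.approx(total, rel=1e-12)

    def test_scores_preserve_pairwise_distances(self, rng):
        x = rng.standard_normal((15, 8))
        res = pca(x)
        d_data = np.linalg.norm(x[:, None] - x[None, :], axis=-1)
        d_scores = np.linalg.norm(res.scores[:, None] - res.scores[None, :], axis=-1)
        np.testing.assert_allclose(d_scores, d_data, atol=1e-9)

    def test_scores_invariant_to_ordering_up_to_sign(self, rng):
        x = rng.standard_normal((15, 6))
        perm = rng.permutation(15)
        a, b = pca(x), pca(x[perm])
        np.testing.assert_allclose(np.abs(a.scores[perm]), np.abs(b.scores), atol=1e-9)

    def test_degenerate_flagged(self):
        res = pca(np.ones((5, 6)))
        assert res.degenerate


class TestRetainPCs:
    @pytest.mark.parametrize(
        "fractions, threshold, expected",
        [
            ((0.5, 0.3, 0.15, 0.05), 0.90, 3),
            ((0.5, 0.3, 0.15, 0.05), 1.00, 4),
            ((0.95, 0.04, 0.01), 0.90, 1),
        ],
    )
    def test_smallest_leading_set(self, rng, fractions, threshold, expected):
        # construct data whose eigenvalue fractions match exactly
        n = 400
        x = np.zeros((n, len(fractions)))
        for j, f in enumerate(fractions):
            col = rng.standard_normal(n)
            col = (col - col.mean()) / col.std(ddof=1)
            x[:, j] = np.sqrt(f) * col
        x = np.linalg.qr(rng.standard_normal((len(fractions),) * 2))[0] @ x.T
        res = pca(x.T)
        assert len(retain_pcs(res, threshold)) == expected


class TestPairwiseMANOVA:
    def test_one_dimensional_reduces_to_anova(self, rng):
        y = np.concatenate([rng.standard_normal(15), 1.2 + rng.standard_normal(17)])
        labels = np.array(["a"] * 15 + ["b"] * 17)
        table = pairwise_manova(y[:, None], labels, correction="none")
        _, p_f = sps.f_oneway(y[:15], y[15:])
        assert table.loc[0, "p"] == pytest.approx(p_f, abs=1e-9)

    def test_zero_variance_flagged(self):
        scores = np.zeros((12, 2))
        labels = np.array(["a", "b"] * 6)
        with pytest.raises(DegenerateDataError, match="singular"):
            pairwise_manova(scores, labels)

    def test_small_group_directs_to_lower_threshold(self, rng):
        scores = rng.standard_normal((8, 5))
        labels = np.array(["a"] * 4 + ["b"] * 4)
        with pytest.raises(DegenerateDataError, match="threshold"):
            pairwise_manova(scores, labels)

    def test_type_one_error_calibrated(self, rng):
        rejections = 0
        reps = 200
        for _ in range(reps):
            scores = rng.standard_normal((40, 3))
            labels = np.array(["a"] * 20 + ["b"] * 20)
            table = pairwise_manova(scores, labels, correction="none")
            rejections += table.loc[0, "p"] < 0.05
        # 99% binomial band around 0.05 for 200 replicates
        assert 0.01 <= rejections / reps <= 0.09


class TestTwoWayMANOVA:
    def test_single_level_sex_rejected(self, rng):
        scores = rng.standard_normal((20, 2))
        species = np.array(["horse", "donkey"] * 10)
        sex = np.array(["female"] * 20)
        with pytest.raises(DegenerateDataError, match="levels"):
            two_way_manova(scores, species, sex)

    def test_empty_cell_listed(self, rng):
        scores = rng.standard_normal((20, 2))
        species = np.array(["horse"] * 10 + ["donkey"] * 10)
        sex = np.array(["female"] * 10 + ["male"] * 10)
        with pytest.raises(DegenerateDataError, match="empty cells"):
            two_way_manova(scores, species, sex)

    def test_geldings_excluded(self, rng):
        scores = rng.standard_normal((30, 2))
        species = np.array(["horse", "donkey"] * 15)
        sex = np.array(["female", "male", "gelding"] * 10)
        res = two_way_manova(scores, species, sex)
        assert res["n_used"] == 20

    def test_species_specific_sex_effect_detected(self, rng):
        # sex effect in one species only => interaction; a 1 sd shift in one
        # cell gives interaction noncentrality n*d^2/4 = 7.5 at n=30/cell,
        # i.e. ~0.7 power for the 2-response Wilks test (measured 0.69 over
        # 300 replicates); assert with binomial slack below that
        hits = 0
        reps = 60
        for _ in range(reps):
            cells = []
            species, sex = [], []
            for sp in ("horse", "donkey"):
                for sx in ("female", "male"):
                    block = rng.standard_normal((30, 2))
                    if sp == "horse" and sx == "male":
                        block[:, 0] += 1.0
                    cells.append(block)
                    species += [sp] * 30
                    sex += [sx] * 30
            res = two_way_manova(np.vstack(cells), species, sex)
            hits += res["interaction_p"] < 0.05
        assert hits / reps > 0.5


class TestDisparity:
    def test_identical_members_zero_variance(self):
        x = np.tile(np.arange(6.0), (5, 1))
        out = procrustes_variance(x, ["g"] * 5)
        assert out["g"] == 0.0

    def test_two_specimens_quarter_squared_distance(self, rng):
        a, b = rng.standard_normal(7), rng.standard_normal(7)
        d2 = ((a - b) ** 2).sum()
        out = procrustes_variance(np.vstack([a, b]), ["g", "g"])
        assert out["g"] == pytest.approx(d2 / 4, rel=1e-12)

    def test_matches_brute_force_double_loop(self, rng):
        x = rng.standard_normal((9, 5))
        out = procrustes_variance(x, ["g"] * 9)
        n = len(x)
        brute = sum(
            ((x[i] - x[j]) ** 2).sum() for i in range(n) for j in range(n)
        ) / (2 * n * n)
        assert out["g"] == pytest.approx(brute, abs=1e-12)

    def test_rotation_invariance(self, rng):
        x = rng.standard_normal((20, 6))
        q = np.linalg.qr(rng.standard_normal((6, 6)))[0]
        labels = ["a"] * 10 + ["b"] * 10
        v1 = procrustes_variance(x, labels)
        v2 = procrustes_variance(x @ q, labels)
        for g in v1:
            assert v1[g] == pytest.approx(v2[g], rel=1e-10)

    def test_singleton_group_flagged(self, rng):
        with pytest.raises(DegenerateDataError, match="singleton"):
            procrustes_variance(rng.standard_normal((3, 4)), ["a", "a", "b"])

    def test_extreme_observed_gives_minimal_p(self, rng):
        # variance ratio so large no permutation can reach it
        x = np.vstack([0.001 * rng.standard_normal((30, 4)),
                       10.0 * rng.standard_normal((30, 4))])
        labels = np.array(["a"] * 30 + ["b"] * 30)
        res = disparity_pairwise(x, labels, n_perm=99, seed=0, correction="none")
        assert res.pairwise_p[("a", "b")] == pytest.approx(0.01)

    def test_seed_reproducible(self, rng):
        x = rng.standard_normal((40, 5))
        labels = np.array(["a", "b"] * 20)
        r1 = disparity_pairwise(x, labels, n_perm=199, seed=7)
        r2 = disparity_pairwise(x, labels, n_perm=199, seed=7)
        assert r1.pairwise_p == r2.pairwise_p
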