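"""Evaluation statistics vs enumeration / second-implementation oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from photorecon import (LabelImage2D, VolumeTable, auroc,
                        contralateral_average, dice2d, errors, group_stats,
                        label_volumes, pearson_r, ranksum_p, residualize,
                        soft_dice, steiger_test)


# ---------------------------------------------------------------------------
# dice2d / label_volumes
# ---------------------------------------------------------------------------

class TestDice2D:
    def test_identical(self):
        a = np.zeros((10, 10), dtype=int)
        a[2:5, 2:5] = 1
        a[6:9, 6:9] = 2
        d = dice2d(a, a.copy(), [1, 2])
        assert d[1] == 1.0 and d[2] == 1.0

    def test_disjoint(self):
        a = np.zeros((8, 8), dtype=int)
        b = np.zeros((8, 8), dtype=int)
        a[:2, :2] = 1
        b[5:, 5:] = 1
        assert dice2d(a, b, [1])[1] == 0.0

    def test_partial_overlap(self):
        # 10-px region vs the same region shifted to overlap 6 px
        a = np.zeros((4, 16), dtype=int)
        b = np.zeros((4, 16), dtype=int)
        a[1, 0:10] = 1
        b[1, 4:14] = 1  # overlap = cols 4..9 -> 6 px
        assert dice2d(a, b, [1])[1] == pytest.approx(2 * 6 / 20)

    def test_absent_label_is_nan(self):
        a = np.zeros((5, 5), dtype=int)
        assert np.isnan(dice2d(a, a, [3])[3])

    def test_shape_mismatch_raises(self):
        with pytest.raises(errors.ShapeMismatch):
            dice2d(np.zeros((4, 4), dtype=int), np.zeros((5, 5), dtype=int), [1])

    def test_matches_soft_dice_on_binarized_rasters(self, rng):
        """2D Dice of one label equals soft Dice of the binarized rasters."""
        a = rng.integers(0, 3, (16, 16))
        b = rng.integers(0, 3, (16, 16))
        d = dice2d(a, b, [1])[1]
        assert d == pytest.approx(soft_dice((a == 1).astype(float),
                                            (b == 1).astype(float)), abs=1e-5)

    def test_label_image_wrapper(self):
        img = LabelImage2D(labels=np.ones((4, 4), dtype=np.int32),
                           pixel_size=0.5, names={1: "cortex"})
        assert dice2d(img, img, [1])[1] == 1.0


class TestLabelVolumes:
    def test_unit_voxels(self):
        seg = np.zeros((10, 10, 10), dtype=int)
        seg[:10, :10, :10] = 5
        assert label_volumes(seg, 1.0)[5] == pytest.approx(1000.0)

    def test_half_mm_voxels(self):
        seg = np.full((10, 10, 10), 5, dtype=int)
        assert label_volumes(seg, 0.5)[5] == pytest.approx(125.0)

    def test_phantom_ellipsoid_close_to_analytic(self, phantom):
        # ventricle: ellipsoid semi-axes (7, 3.5, 2.5) mm
        vols = label_volumes(phantom.labels, phantom.voxel_size)
        analytic = 4 / 3 * np.pi * 7.0 * 3.5 * 2.5
        assert vols[3] == pytest.approx(analytic, rel=0.03)


# ---------------------------------------------------------------------------
# residualize
# ---------------------------------------------------------------------------

def _table(rng, n=20, vol=None):
    df = pd.DataFrame({
        "group": rng.integers(0, 2, n),
        "age": rng.uniform(60, 90, n),
        "sex": rng.integers(0, 2, n),
    })
    df["hippocampus"] = vol if vol is not None else rng.uniform(2000, 4000, n)
    return VolumeTable(df)


class TestResidualize:
    def test_exact_covariate_dependence_vanishes(self, rng):
        t = _table(rng)
        t.data["hippocampus"] = 2.0 * t.data["age"]
        out = residualize(t)
        assert np.abs(out.data["hippocampus"]).max() < 1e-10

    def test_residuals_orthogonal_to_covariates(self, rng):
        out = residualize(_table(rng))
        r = out.data["hippocampus"].to_numpy()
        for cov in ("age", "sex"):
            c = out.data[cov].to_numpy().astype(float)
            assert abs(np.dot(r, c - c.mean())) < 1e-8 * np.linalg.norm(r) \
                * np.linalg.norm(c - c.mean() + 1e-30)

    def test_matches_normal_equations_oracle(self, rng):
        t = _table(rng)
        out = residualize(t)
        X = np.c_[np.ones(len(t.data)), t.data["age"], t.data["sex"]]
        y = t.data["hippocampus"].to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(out.data["hippocampus"], y - X @ beta,
                                   atol=1e-8)

    def test_rank_deficient_raises(self, rng):
        t = _table(rng)
        t.data["sex"] = t.data["age"]  # collinear covariates
        with pytest.raises(errors.RankDeficientDesign):
            residualize(t)


# ---------------------------------------------------------------------------
# auroc / ranksum
# ---------------------------------------------------------------------------

def brute_auroc(x, y):
    wins = ties = 0
    for xi in x:
        for yi in y:
            if yi > xi:
                wins += 1
            elif yi == xi:
                ties += 1
    return (wins + 0.5 * ties) / (len(x) * len(y))


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([1, 2, 3], [4, 5, 6]) == 1.0

    def test_all_ties(self):
        assert auroc([1, 2, 3], [1, 2, 3]) == 0.5

    def test_enumeration_example(self):
        assert auroc([1, 2, 3], [2, 3, 4]) == pytest.approx(7 / 9)

    def test_antisymmetry(self, rng):
        for _ in range(50):
            x = rng.integers(0, 5, rng.integers(2, 10)).astype(float)
            y = rng.integers(0, 5, rng.integers(2, 10)).astype(float)
            assert auroc(x, y) + auroc(y, x) == pytest.approx(1.0, abs=1e-12)

    def test_matches_bruteforce(self, rng):
        for _ in range(200):
            x = rng.normal(size=rng.integers(2, 12))
            y = rng.normal(size=rng.integers(2, 12)) + rng.normal()
            assert auroc(x, y) == pytest.approx(brute_auroc(x, y), abs=1e-12)

    def test_empty_group_raises(self):
        with pytest.raises(errors.EmptyGroup):
            auroc([], [1.0])


def brute_exact_ranksum(x, y):
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    ny = len(y)
    mu = len(x) * ny / 2.0
    u_obs = ranks[len(x):].sum() - ny * (ny + 1) / 2
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), ny):
        u = sum(ranks[i] for i in comb) - ny * (ny + 1) / 2
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return count / total


class TestRanksum:
    def test_most_extreme_small_sample(self):
        assert ranksum_p([1, 2], [3, 4]) == pytest.approx(2 / 6)

    def test_identical_multisets_p_one(self):
        assert ranksum_p([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(25):
            x = rng.normal(size=rng.integers(2, 6))
            y = rng.normal(size=rng.integers(2, 6))
            assert ranksum_p(x, y) == pytest.approx(
                brute_exact_ranksum(x, y), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(size=14) + 0.5
        p1 = ranksum_p(x, y)
        p2 = ranksum_p(np.exp(x), np.exp(y))  # strictly monotone transform
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(7)
        rej = 0
        reps = 1000
        for _ in range(reps):
            x = rng.normal(size=30)
            y = rng.normal(size=30)
            rej += ranksum_p(x, y) < 0.05
        assert 0.03 <= rej / reps <= 0.07


# ---------------------------------------------------------------------------
# pearson / steiger
# ---------------------------------------------------------------------------

class TestPearson:
    def test_identity(self):
        u = np.array([1.0, 2, 3, 5])
        assert pearson_r(u, u) == pytest.approx(1.0)

    def test_negative_affine(self):
        u = np.array([1.0, 2, 3, 5])
        assert pearson_r(u, -2 * u + 7) == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        u = np.array([1.0, 2, 3, 5])
        v = np.array([2.0, 2, 4, 5])
        num = np.sum((u - u.mean()) * (v - v.mean()))
        den = np.sqrt(np.sum((u - u.mean()) ** 2) * np.sum((v - v.mean()) ** 2))
        assert pearson_r(u, v) == pytest.approx(num / den, abs=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(errors.ZeroVariance):
            pearson_r([1, 1, 1], [1, 2, 3])


def steiger_oracle(r_jk, r_jh, r_kh, n):
    """Independent implementation of the dependent-correlation Z test."""
    import math
    z1 = 0.5 * math.log((1 + r_jk) / (1 - r_jk))
    z2 = 0.5 * math.log((1 + r_jh) / (1 - r_jh))
    rbar = (r_jk + r_jh) / 2
    psi = r_kh * (1 - 2 * rbar ** 2) - 0.5 * rbar ** 2 * (
        1 - 2 * rbar ** 2 - r_kh ** 2)
    c = psi / ((1 - rbar ** 2) ** 2)
    z = (z1 - z2) * math.sqrt((n - 3) / (2 - 2 * c))
    p = 2 * (1 - scipy.stats.norm.cdf(abs(z)))
    return z, p


class TestSteiger:
    def test_equal_correlations(self):
        z, p = steiger_test(0.8, 0.8, 0.5, 30)
        assert z == 0.0 and p == 1.0

    def test_antisymmetric_in_swap(self):
        z1, p1 = steiger_test(0.9, 0.6, 0.5, 25)
        z2, p2 = steiger_test(0.6, 0.9, 0.5, 25)
        assert z1 == pytest.approx(-z2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_matches_published_formula_oracle(self):
        z, p = steiger_test(0.9, 0.7, 0.6, 24)
        zo, po = steiger_oracle(0.9, 0.7, 0.6, 24)
        assert z == pytest.approx(zo, abs=1e-10)
        assert p == pytest.approx(po, abs=1e-10)

    def test_random_instances_match_oracle(self, rng):
        for _ in range(100):
            # draw a jointly feasible correlation triple from actual data
            n = int(rng.integers(5, 100))
            X = rng.normal(size=(max(n, 6), 3))
            X[:, 1] += rng.uniform(-1, 1) * X[:, 0]
            X[:, 2] += rng.uniform(-1, 1) * X[:, 0]
            C = np.corrcoef(X.T)
            r_jk, r_jh, r_kh = C[0, 1], C[0, 2], C[1, 2]
            z, p = steiger_test(r_jk, r_jh, r_kh, n)
            zo, po = steiger_oracle(r_jk, r_jh, r_kh, n)
            assert z == pytest.approx(zo, abs=1e-10)
            assert p == pytest.approx(po, abs=1e-10)

    def test_infeasible_triple_raises(self):
        # three strongly mutually negative correlations cannot coexist
        with pytest.raises(errors.InvalidCorrelation):
            steiger_test(-0.81, -0.68, -0.68, 10)

    def test_invalid_correlation_raises(self):
        with pytest.raises(errors.InvalidCorrelation):
            steiger_test(1.0, 0.5, 0.5, 20)


# ---------------------------------------------------------------------------
# table pipeline
# ---------------------------------------------------------------------------

class TestTablePipeline:
    def test_contralateral_average(self):
        df = pd.DataFrame({"group": [0, 1], "age": [70.0, 80.0],
                           "sex": [0, 1],
                           "left_hippocampus": [3000.0, 2000.0],
                           "right_hippocampus": [3200.0, 2200.0]})
        out = contralateral_average(VolumeTable(df))
        assert list(out.data["hippocampus"]) == [3100.0, 2100.0]

    def test_group_stats_excludes_unreliable_regions(self, rng):
        n = 24
        df = pd.DataFrame({"group": np.repeat([0, 1], n // 2),
                           "age": rng.uniform(60, 90, n),
                           "sex": rng.integers(0, 2, n),
                           "hippocampus": rng.uniform(2, 4, n),
                           "accumbens_area": rng.uniform(0.3, 0.6, n)})
        res = group_stats(VolumeTable(df))
        assert list(res["region"]) == ["hippocampus"]

    def test_residualized_auroc_removes_confound(self):
        """With a group difference driven purely by an age confound, GLM
        correction moves the AUROC back toward chance."""
        rng = np.random.default_rng(3)
        n = 40
        group = np.repeat([0, 1], n // 2)
        age = 70 + 10 * group + rng.normal(0, 2, n)  # confounded age
        vol = 3000 - 20 * (age - 70) + rng.normal(0, 20, n)  # age-driven only
        df = pd.DataFrame({"group": group, "age": age,
                           "sex": rng.integers(0, 2, n), "roi": vol})
        t = VolumeTable(df)
        raw = group_stats(t, correct_covariates=False)["auroc"][0]
        adj = group_stats(t, correct_covariates=True)["auroc"][0]
        assert abs(adj - 0.5) < abs(raw - 0.5)
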