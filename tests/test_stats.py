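"""Group statistics: smoothing, masking, effect sizes, clusters, labels.

Model-based statistics are checked against independent oracles: explicit
full-versus-reduced residual sums of squares, pingouin's ANCOVA, and
direct formula evaluation.
"""

import numpy as np
import pandas as pd
import pytest

from dtifitlab.io import CohortTable, LabelAtlas, ValidationError
from dtifitlab.stats import (
    AnalysisConfig,
    StatMap,
    ancova_eta2p,
    average_maps,
    bartlett_gate,
    extract_clusters,
    hedges_g,
    label_clusters,
    partial_spearman,
    smooth_map,
    wm_mask,
)


def _cohort(groups, ages=None, genders=None, seed=0, **scores):
    rng = np.random.default_rng(seed)
    n = len(groups)
    df = pd.DataFrame(
        {
            "id": [f"s{i}" for i in range(n)],
            "group": groups,
            "age": ages if ages is not None else rng.uniform(60, 85, n),
            "gender": genders if genders is not None else rng.integers(0, 2, n),
        }
    )
    for k, v in scores.items():
        df[k] = v
    return CohortTable(df)


class TestSmoothing:
    def test_sigma_zero_identity(self):
        rng = np.random.default_rng(0)
        m = rng.random((8, 8, 4))
        np.testing.assert_array_equal(smooth_map(m, 0.0, (2, 2, 2)), m)

    def test_constant_preserved_inside_mask(self):
        m = np.zeros((10, 10, 6))
        mask = np.zeros((10, 10, 6), bool)
        mask[2:8, 2:8, 1:5] = True
        m[mask] = 0.7
        sm = smooth_map(m, 3.0, (2, 2, 2), mask)
        np.testing.assert_allclose(sm[mask], 0.7, rtol=1e-10)
        np.testing.assert_array_equal(sm[~mask], 0.0)

    def test_impulse_center_equals_kernel_weight(self):
        m = np.zeros((17, 17, 17))
        m[8, 8, 8] = 1.0
        sm = smooth_map(m, 2.0, (1, 1, 1))  # sigma 2 voxels
        # central weight of a separable 3D Gaussian kernel
        x = np.arange(-8, 9)
        k1 = np.exp(-(x**2) / (2 * 4.0))
        k1 /= k1.sum()
        assert abs(sm[8, 8, 8] - k1[8] ** 3) < 1e-12


class TestWMmask:
    def test_zero_maps_empty(self):
        assert wm_mask(np.zeros((3, 4, 4, 2))).sum() == 0

    def test_threshold_one_empty(self):
        maps = np.random.default_rng(1).random((3, 4, 4, 2))
        assert wm_mask(maps, 1.0).sum() == 0

    def test_strict_mean_threshold(self):
        maps = np.stack([np.full((2, 2, 1), 0.1), np.full((2, 2, 1), 0.3)])
        assert wm_mask(maps, 0.20).sum() == 0  # mean exactly 0.2 excluded
        maps[1] += 0.01
        assert wm_mask(maps, 0.20).all()


class TestBartlett:
    def test_type_i_error_calibrated(self):
        rng = np.random.default_rng(5)
        rejections = 0
        reps = 600
        for _ in range(reps):
            a, b = rng.normal(size=(2, 50))
            _, p = bartlett_gate([a, b])
            rejections += p < 0.05
        assert 0.03 <= rejections / reps <= 0.07

    def test_power_against_sd_ratio_three(self):
        rng = np.random.default_rng(6)
        hits = sum(
            bartlett_gate([rng.normal(0, 1, 50), rng.normal(0, 3, 50)])[1] < 0.01
            for _ in range(100)
        )
        assert hits >= 95

    def test_identical_samples_statistic_zero(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        stat, p = bartlett_gate([a, a.copy()])
        assert abs(stat) < 1e-12

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValidationError, match="zero variance"):
            bartlett_gate([np.ones(5), np.array([1.0, 2.0, 3.0])])


def _eta2p_bruteforce(y, groups, age, gender):
    """Model-comparison oracle: explicit RSS of full vs reduced designs."""
    levels = sorted(set(groups), key=["HC", "MCI", "AD"].index)
    G = np.zeros((len(y), len(levels) - 1))
    for j, g in enumerate(levels[:-1]):
        G[np.asarray(groups) == g, j] = 1.0
    G[np.asarray(groups) == levels[-1]] = -1.0
    Xf = np.column_stack([np.ones(len(y)), G, age, gender])
    Xr = np.column_stack([np.ones(len(y)), age, gender])

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    ss_g = rss(Xr) - rss(Xf)
    return ss_g / (ss_g + rss(Xf))


class TestAncova:
    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            groups = ["HC"] * 5 + ["MCI"] * 4 + ["AD"] * 3
            n = len(groups)
            age = rng.uniform(60, 85, n)
            gender = rng.integers(0, 2, n).astype(float)
            y = rng.normal(size=(n, 4))
            cohort = _cohort(groups, age, gender)
            res = ancova_eta2p(y[:, :, None, None], cohort).data[:, 0, 0]
            for v in range(4):
                exp = _eta2p_bruteforce(y[:, v], groups, age, gender)
                assert abs(res[v] - exp) < 1e-10

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        groups = ["HC"] * 8 + ["MCI"] * 6 + ["AD"] * 5
        n = len(groups)
        cohort = _cohort(groups, seed=8)
        y = rng.normal(0.5, 0.1, size=n)
        df = cohort.table.copy()
        df["fa"] = y
        res = ancova_eta2p(y[:, None, None, None], cohort).data[0, 0, 0]
        tab = pg.ancova(data=df, dv="fa", between="group",
                        covar=["age", "gender"])
        exp = float(tab.loc[tab["Source"] == "group", "np2"].iloc[0])
        assert abs(res - exp) < 1e-10

    def test_null_zero_and_separated_one(self):
        groups = ["HC"] * 5 + ["MCI"] * 5 + ["AD"] * 5
        age = np.linspace(60, 80, 15)
        gender = np.array([0, 1] * 7 + [0], float)
        y0 = np.full(15, 0.5)
        cohort = _cohort(groups, age, gender)
        eta0 = ancova_eta2p(y0[:, None, None, None], cohort).data[0, 0, 0]
        assert eta0 == 0.0
        y1 = y0.copy()
        y1[10:] += 10.0
        eta1 = ancova_eta2p(y1[:, None, None, None], cohort).data[0, 0, 0]
        assert eta1 > 0.999

    def test_age_rescaling_invariance(self):
        rng = np.random.default_rng(9)
        groups = ["HC"] * 6 + ["MCI"] * 5 + ["AD"] * 4
        age = rng.uniform(60, 85, 15)
        gender = rng.integers(0, 2, 15).astype(float)
        y = rng.normal(size=(15, 3))
        a = ancova_eta2p(y[..., None, None], _cohort(groups, age, gender)).data
        b = ancova_eta2p(
            y[..., None, None], _cohort(groups, 10 * age - 300, gender)
        ).data
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_single_gender_dropped_with_warning(self):
        rng = np.random.default_rng(10)
        groups = ["HC"] * 5 + ["MCI"] * 4 + ["AD"] * 4
        y = rng.normal(size=(13, 2))
        cohort = _cohort(groups, genders=np.zeros(13, int))
        with pytest.warns(UserWarning, match="gender"):
            res = ancova_eta2p(y[..., None, None], cohort)
        assert np.isfinite(res.data).all()


class TestHedgesG:
    def test_identical_groups_zero(self):
        groups = ["AD"] * 6 + ["HC"] * 6
        y = np.full((12, 2), 0.4)
        res = hedges_g(y[..., None, None], _cohort(groups, seed=1), ("AD", "HC"))
        np.testing.assert_array_equal(res.data, 0.0)

    def test_small_sample_correction_factor(self):
        groups = ["AD"] * 10 + ["HC"] * 10
        rng = np.random.default_rng(11)
        y = rng.normal(size=(20, 1))
        res = hedges_g(y[..., None, None], _cohort(groups, seed=2), ("AD", "HC"))
        assert abs(res.thresholds["J"] - (1 - 3 / 71)) < 1e-12

    def test_sign_convention_ad_deficit_negative(self):
        groups = ["AD"] * 6 + ["HC"] * 8
        y = np.concatenate([np.full(6, 0.3), np.full(8, 0.5)])
        y = y + np.random.default_rng(12).normal(0, 0.01, 14)
        res = hedges_g(y[:, None, None, None], _cohort(groups, seed=3),
                       ("AD", "HC"))
        assert res.data[0, 0, 0] < -3

    def test_recovers_true_standardized_difference(self):
        # simulated true standardized difference of 1.0 at the published
        # unbalanced sizes (41 vs 12); reps vectorized as voxels
        rng = np.random.default_rng(13)
        n1, n2, reps = 41, 12, 600
        groups = ["HC"] * n1 + ["AD"] * n2
        y = rng.normal(0, 1, size=(n1 + n2, reps))
        y[:n1] += 1.0
        cohort = _cohort(groups, seed=4)
        res = hedges_g(y[..., None, None], cohort, ("HC", "AD"))
        ghat = res.data[:, 0, 0]
        se = ghat.std(ddof=1) / np.sqrt(reps)
        assert abs(ghat.mean() - 1.0) < 3 * se + 0.02

    def test_raw_matches_textbook_formula(self):
        rng = np.random.default_rng(14)
        a, b = rng.normal(0.6, 0.1, 9), rng.normal(0.5, 0.1, 7)
        y = np.concatenate([a, b])
        groups = ["AD"] * 9 + ["HC"] * 7
        res = hedges_g(y[:, None, None, None], _cohort(groups, seed=5),
                       ("AD", "HC"), adjusted=False)
        sp = np.sqrt(
            ((9 - 1) * a.var(ddof=1) + (7 - 1) * b.var(ddof=1)) / (9 + 7 - 2)
        )
        expected = (1 - 3 / (4 * 16 - 9)) * (a.mean() - b.mean()) / sp
        assert abs(res.data[0, 0, 0] - expected) < 1e-12


class TestPartialSpearman:
    def test_antisymmetry_under_score_negation(self):
        rng = np.random.default_rng(15)
        groups = ["HC"] * 12
        y = rng.normal(size=(12, 3))
        score = rng.normal(size=12)
        cohort = _cohort(groups, seed=6)
        a = partial_spearman(y[..., None, None], score, cohort).data
        b = partial_spearman(y[..., None, None], -score, cohort).data
        np.testing.assert_allclose(a, -b, atol=1e-12)

    def test_monotone_coupling_approaches_one(self):
        rng = np.random.default_rng(16)
        y = rng.normal(0.5, 0.05, size=(30, 1))
        score = 3 * y[:, 0] + rng.normal(0, 1e-6, 30)
        cohort = _cohort(["HC"] * 30, seed=7)
        rho = partial_spearman(y[..., None, None], score, cohort).data[0, 0, 0]
        assert rho > 0.95

    def test_confound_removal_beats_plain_spearman(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(17)
        wins = 0
        reps = 200
        for _ in range(reps):
            n = 40
            age = rng.uniform(60, 85, n)
            fa = 0.01 * age + rng.normal(0, 0.05, n)
            score = 0.5 * age + rng.normal(0, 1.0, n)
            cohort = _cohort(["HC"] * n, ages=age,
                             genders=rng.integers(0, 2, n))
            partial = partial_spearman(
                fa[:, None, None, None], score, cohort
            ).data[0, 0, 0]
            plain = spearmanr(fa, score).statistic
            wins += abs(partial) < abs(plain)
        assert wins / reps >= 0.95

    def test_constant_score_flagged_zero(self):
        rng = np.random.default_rng(18)
        y = rng.normal(size=(8, 2))
        cohort = _cohort(["HC"] * 8, seed=8)
        res = partial_spearman(y[..., None, None], np.full(8, 3.0), cohort)
        np.testing.assert_array_equal(res.data, 0.0)
        assert res.diagnostics["constant_score"]

    def test_missing_scores_dropped_pairwise(self):
        rng = np.random.default_rng(19)
        y = rng.normal(size=(10, 1))
        score = rng.normal(size=10)
        score[[2, 5]] = np.nan
        cohort = _cohort(["HC"] * 10, seed=9)
        res = partial_spearman(y[..., None, None], score, cohort)
        assert res.diagnostics["n_used"] == 8
        assert res.diagnostics["n_dropped"] == 2


class TestClusters:
    def _map(self, data):
        return StatMap(data=data, kind="g")

    def test_single_box_cluster(self):
        data = np.zeros((12, 12, 6))
        data[2:7, 2:8, 1:6] = 1.0  # 5*6*5 = 150 voxels
        cl = extract_clusters(self._map(data), 0.85, min_size=100)
        assert len(cl) == 1 and cl[0].size == 150

    def test_corner_touching_boxes_connectivity(self):
        data = np.zeros((20, 20, 8))
        data[2:7, 2:7, 1:7] = 1.0   # 125 voxels
        data[7:12, 7:12, 1:7] = 1.0  # touches only along the diagonal edge
        c26 = extract_clusters(self._map(data), 0.5, min_size=100,
                               connectivity=26)
        c6 = extract_clusters(self._map(data), 0.5, min_size=100,
                              connectivity=6)
        assert len(c26) == 1 and c26[0].size == 300
        assert len(c6) == 2 and {c.size for c in c6} == {150}

    def test_strict_size_threshold(self):
        data = np.zeros((12, 12, 6))
        data[2:7, 2:7, 1:5] = 1.0  # 5*5*4 = 100 voxels exactly
        assert extract_clusters(self._map(data), 0.5, min_size=100) == []
        data[7, 6, 4] = 1.0  # 101st voxel, 26-connected at a corner
        cl = extract_clusters(self._map(data), 0.5, min_size=100)
        assert len(cl) == 1 and cl[0].size == 101

    def test_two_sided_keeps_signs_separate(self):
        data = np.zeros((20, 10, 6))
        data[1:6, 1:8, 1:5] = 1.2
        data[10:15, 1:8, 1:5] = -1.2
        cl = extract_clusters(self._map(data), 0.85, min_size=100,
                              two_sided=True)
        assert sorted(c.sign for c in cl) == [-1, 1]
        one_sided = extract_clusters(self._map(data), 0.85, min_size=100,
                                     two_sided=False)
        assert len(one_sided) == 1

    def test_partition_property(self):
        rng = np.random.default_rng(20)
        data = rng.normal(size=(16, 16, 8))
        cl = extract_clusters(self._map(data), 1.5, min_size=0,
                              two_sided=True)
        assert sum(c.size for c in cl) == np.count_nonzero(np.abs(data) > 1.5)


class TestLabeling:
    def _atlas(self):
        labels = np.zeros((12, 12, 6), int)
        labels[2:7, 2:7, 1:5] = 1  # 100-voxel region
        labels[8:11, 8:11, 1:4] = 2
        return LabelAtlas(labels=labels, names={1: "fornix", 2: "splenium"})

    def test_full_coverage_both_ways(self):
        atlas = self._atlas()
        data = np.zeros((12, 12, 6))
        data[2:7, 2:7, 1:5] = 1.0
        cl = extract_clusters(StatMap(data=data, kind="g"), 0.5, min_size=50)
        cl = label_clusters(cl, atlas)
        assert cl[0].label_overlaps == [("fornix", 100.0, 100.0)]

    def test_partial_coverage_percentages(self):
        atlas = self._atlas()
        data = np.zeros((12, 12, 6))
        data[2:7, 2:7, 1:5] = 1.0
        data[2:7, 7:10, 1:5] = 1.0  # extends outside the region
        cl = label_clusters(
            extract_clusters(StatMap(data=data, kind="g"), 0.5, min_size=50),
            atlas,
        )
        (name, pct_region, pct_cluster), = cl[0].label_overlaps
        assert name == "fornix"
        assert abs(pct_region - 100.0) < 1e-12
        assert abs(pct_cluster - 100.0 * 100 / 160) < 1e-12

    def test_disjoint_cluster_empty_overlaps(self):
        atlas = self._atlas()
        data = np.zeros((12, 12, 6))
        data[0:2, 0:12, 0:6] = 1.0
        cl = label_clusters(
            extract_clusters(StatMap(data=data, kind="g"), 0.5, min_size=50),
            atlas,
        )
        assert cl[0].label_overlaps == []


class TestAverageMaps:
    def test_identity_and_cancellation(self):
        rng = np.random.default_rng(21)
        v = rng.normal(size=(4, 4, 2))
        m = StatMap(data=v, kind="g", contrast="AD vs HC")
        same = average_maps([m, StatMap(data=v.copy(), kind="g",
                                        contrast="AD vs HC")])
        np.testing.assert_array_equal(same.data, v)
        opp = average_maps([m, StatMap(data=-v, kind="g", contrast="AD vs HC")])
        np.testing.assert_allclose(opp.data, 0.0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(22)
        maps = [StatMap(data=rng.normal(size=(3, 3, 2)), kind="eta2p",
                        contrast="x") for _ in range(4)]
        a = average_maps(maps).data
        b = average_maps(maps[::-1]).data
        np.testing.assert_allclose(a, b, atol=1e-15)

    def test_mixed_kinds_rejected(self):
        a = StatMap(data=np.zeros((2, 2, 2)), kind="g", contrast="x")
        b = StatMap(data=np.zeros((2, 2, 2)), kind="rho", contrast="x")
        with pytest.raises(ValidationError, match="mixed kinds"):
            average_maps([a, b])


def test_analysis_config_validation():
    with pytest.raises(ValidationError):
        AnalysisConfig(connectivity=10)
    with pytest.raises(ValidationError):
        AnalysisConfig(eta2p_threshold=0.0)
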