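"""Model-neural correlation, Mantel inference, thresholding, partials."""

import itertools

import numpy as np
import pytest
from scipy.stats import rankdata, spearmanr

from isrsa import (
    DegenerateDataError,
    GridSpec,
    InputError,
    SearchlightMap,
    build_model,
    build_searchlights,
    compare_maps,
    isrsa_correlation,
    lower_triangle,
    mantel_test,
    normalize_scores,
    partial_spearman,
    pattern_rdm,
    searchlight_isrsa,
    threshold_map,
)
from isrsa.stats import MantelEngine, bh_fdr
from conftest import make_betas


def random_symmetric(n, rng, zero_diag=True):
    a = rng.random((n, n))
    m = (a + a.T) / 2
    if zero_diag:
        np.fill_diagonal(m, 0.0)
    return m


class TestLowerTriangle:
    def test_lengths(self, rng):
        assert lower_triangle(random_symmetric(30, rng)).size == 435
        m2 = random_symmetric(2, rng)
        assert lower_triangle(m2) == pytest.approx([m2[1, 0]])

    def test_matches_enumeration_oracle(self, rng):
        m = random_symmetric(5, rng)
        expected = [m[i, j] for i in range(5) for j in range(i)]
        assert np.array_equal(lower_triangle(m), expected)

    def test_asymmetric_rejected(self, rng):
        m = rng.random((4, 4))
        with pytest.raises(InputError):
            lower_triangle(m)


class TestIsrsaCorrelation:
    def test_identity_and_reversal(self, rng):
        m = random_symmetric(8, rng)
        assert isrsa_correlation(m, m) == 1.0
        v = lower_triangle(m)
        # build a symmetric matrix whose LT is the rank reversal of m's
        rev = np.zeros_like(m)
        rev[np.tril_indices(8, -1)] = -v
        rev = rev + rev.T
        assert isrsa_correlation(m, rev) == pytest.approx(-1.0)

    def test_matches_scipy_oracle(self, rng):
        a, b = random_symmetric(10, rng), random_symmetric(10, rng)
        expected = spearmanr(lower_triangle(a), lower_triangle(b)).statistic
        assert isrsa_correlation(a, b) == pytest.approx(expected, rel=1e-12)

    def test_zero_variance_rejected(self, rng):
        with pytest.raises(DegenerateDataError):
            isrsa_correlation(np.ones((5, 5)), random_symmetric(5, rng))

    def test_subject_order_mismatch_rejected(self, small_scores):
        a = build_model(small_scores, "nn_abs")
        b = build_model(small_scores, "nn_abs")
        b.subject_order = list(reversed(b.subject_order))
        with pytest.raises(InputError):
            isrsa_correlation(a, b)


def exhaustive_mantel_oracle(model, neural, tol=1e-9):
    """Enumerate all n! joint row/column shuffles with scipy spearman.

    At small n the rank statistic is discrete, so permuted values exactly
    tied with the observed one are common and the strict comparison is
    decided by float rounding; the oracle therefore returns the p range
    [strictly-greater, strictly-greater + ties] that any correct strict-
    inequality implementation must fall into.
    """
    n = model.shape[0]
    obs = spearmanr(lower_triangle(model), lower_triangle(neural)).statistic
    greater, ties, total = 0, 0, 0
    for perm in itertools.permutations(range(n)):
        pm = model[np.ix_(perm, perm)]
        r = spearmanr(lower_triangle(pm), lower_triangle(neural)).statistic
        if r > obs + tol:
            greater += 1
        elif r > obs - tol:
            ties += 1
        total += 1
    return obs, greater / total, (greater + ties) / total


class TestMantel:
    def test_self_correlation_p_zero(self, rng):
        m = random_symmetric(10, rng)  # distinct entries a.s.
        res = mantel_test(m, m, B=1000, seed=0)
        assert res.rho == 1.0
        assert res.p == 0.0

    def test_exhaustive_matches_enumeration_oracle(self, rng):
        m = random_symmetric(5, rng)
        r = random_symmetric(5, rng)
        obs, p_lo, p_hi = exhaustive_mantel_oracle(m, r)
        res = mantel_test(m, r, exhaustive=True)
        assert res.B == 120
        assert res.rho == pytest.approx(obs, rel=1e-12)
        assert p_lo - 1e-15 <= res.p <= p_hi + 1e-15

    def test_seeded_determinism(self, rng):
        m, r = random_symmetric(8, rng), random_symmetric(8, rng)
        a = mantel_test(m, r, B=200, seed=42)
        b = mantel_test(m, r, B=200, seed=42)
        assert (a.rho, a.p) == (b.rho, b.p)
        c = mantel_test(m, r, B=200, seed=43)
        assert c.B == 200  # different seed still valid, p may differ

    def test_joint_relabeling_invariance(self):
        # exhaustive mode makes the null identical, so p is exactly invariant
        # (fixed matrices keep every permuted statistic clear of the strict
        # comparison boundary, where float summation order could flip a count)
        local = np.random.default_rng(123)
        m, r = random_symmetric(5, local), random_symmetric(5, local)
        perm = local.permutation(5)
        a = mantel_test(m, r, exhaustive=True)
        b = mantel_test(m[np.ix_(perm, perm)], r[np.ix_(perm, perm)],
                        exhaustive=True)
        assert a.rho == pytest.approx(b.rho, rel=1e-12)
        assert a.p == pytest.approx(b.p, abs=1e-15)

    def test_negative_direction_alternative(self, rng):
        m = random_symmetric(8, rng)
        v = lower_triangle(m)
        rev = np.zeros_like(m)
        rev[np.tril_indices(8, -1)] = -v
        rev = rev + rev.T
        res = mantel_test(m, rev, B=500, seed=1, alternative="auto")
        assert res.rho == pytest.approx(-1.0)
        assert res.alternative == "less"
        assert res.p == 0.0

    def test_smoothed_p_never_zero(self, rng):
        m = random_symmetric(6, rng)
        res = mantel_test(m, m, B=100, seed=0, smoothing=True)
        assert res.p == pytest.approx(1 / 101)

    def test_small_n_rejected(self, rng):
        m = random_symmetric(3, rng)
        with pytest.raises(InputError):
            mantel_test(m, m, B=10, seed=0)

    def test_monte_carlo_converges_to_exhaustive(self, rng):
        m, r = random_symmetric(5, rng), random_symmetric(5, rng)
        p_ex = mantel_test(m, r, exhaustive=True).p
        p_mc = mantel_test(m, r, B=10_000, seed=7).p
        se = np.sqrt(p_ex * (1 - p_ex) / 10_000)
        assert abs(p_mc - p_ex) <= 3 * se + 1e-12


@pytest.fixture(scope="module")
def toy_map():
    grid = GridSpec.isotropic((8, 8, 8))
    rho = np.full(grid.shape, np.nan)
    p = np.full(grid.shape, np.nan)
    r = np.random.default_rng(5)
    rho[1:7, 1:7, 1:7] = r.uniform(-0.3, 0.3, (6, 6, 6))
    p[1:7, 1:7, 1:7] = r.uniform(0.2, 1.0, (6, 6, 6))
    # one 15-voxel positive blob at p=.001 plus isolated voxels
    blob = [(i, j, k) for i in (2, 3, 4) for j in (2, 3) for k in (2, 3)]
    blob += [(2, 2, 4), (3, 2, 4), (4, 2, 4)]
    for v in blob[:15]:
        p[v] = 0.001
        rho[v] = 0.4
    for v in [(6, 6, 6), (1, 6, 1), (6, 1, 1), (1, 1, 6), (6, 6, 1)]:
        p[v] = 0.001
        rho[v] = 0.3
    return SearchlightMap(rho_volume=rho, p_volume=p, grid=grid,
                          condition="baseline", model_kind="nn_abs")


class TestSearchlightMapOps:
    def test_blob_survives_extent_isolated_do_not(self, toy_map):
        table = threshold_map(toy_map, p_cluster_forming=0.005, k_min=10)
        surviving = table.surviving()
        assert len(surviving) == 1
        assert surviving.iloc[0]["extent"] == 15
        assert surviving.iloc[0]["sign"] == "positive"
        # the five isolated voxels appear as non-surviving clusters
        assert (table.frame["extent"] < 10).sum() >= 5

    def test_all_p_one_gives_empty_table(self):
        grid = GridSpec.isotropic((4, 4, 4))
        rho = np.full(grid.shape, 0.1)
        p = np.ones(grid.shape)
        smap = SearchlightMap(rho, p, grid, "baseline", "nn_abs")
        assert len(threshold_map(smap).frame) == 0

    def test_bh_matches_stepup_oracle(self, rng):
        pvals = rng.uniform(0, 1, 500) ** 2
        got = bh_fdr(pvals, q=0.05)
        # independently coded step-up procedure
        order = np.argsort(pvals)
        m = len(pvals)
        thresh = 0.05 * (np.arange(1, m + 1)) / m
        passing = np.flatnonzero(pvals[order] <= thresh)
        expected = np.zeros(m, bool)
        if len(passing):
            expected[order[: passing.max() + 1]] = True
        assert np.array_equal(got, expected)

    def test_extents_invariant_to_connectivity_labeling(self, toy_map):
        a = threshold_map(toy_map, connectivity=18)
        b = threshold_map(toy_map, connectivity=18)
        assert sorted(a.frame["extent"]) == sorted(b.frame["extent"])

    def test_peak_coordinates_in_mm(self, toy_map):
        table = threshold_map(toy_map)
        row = table.surviving().iloc[0]
        vox = np.array([row["peak_x_mm"], row["peak_y_mm"],
                        row["peak_z_mm"]]) / 3.0
        assert np.allclose(vox, np.round(vox))

    def test_compare_maps_identity_and_symmetry(self, toy_map, rng):
        assert compare_maps(toy_map, toy_map) == 1.0
        other = SearchlightMap(
            rho_volume=rng.uniform(-1, 1, toy_map.grid.shape),
            p_volume=np.ones(toy_map.grid.shape),
            grid=toy_map.grid, condition="baseline", model_kind="nn_euclid")
        assert compare_maps(toy_map, other) == pytest.approx(
            compare_maps(other, toy_map))

    def test_compare_maps_matches_intersection_oracle(self, toy_map, rng):
        rho2 = np.full(toy_map.grid.shape, np.nan)
        p2 = np.full(toy_map.grid.shape, np.nan)
        rho2[0:5] = rng.uniform(-1, 1, (5, 8, 8))
        p2[0:5] = 0.5
        other = SearchlightMap(rho2, p2, toy_map.grid, "baseline", "nn_euclid")
        both = np.isfinite(toy_map.p_volume) & np.isfinite(p2)
        expected = spearmanr(toy_map.rho_volume[both], rho2[both]).statistic
        assert compare_maps(toy_map, other) == pytest.approx(expected, rel=1e-12)

    def test_disjoint_maps_rejected(self, toy_map):
        empty = SearchlightMap(
            rho_volume=np.full(toy_map.grid.shape, np.nan),
            p_volume=np.full(toy_map.grid.shape, np.nan),
            grid=toy_map.grid, condition="x", model_kind="y")
        with pytest.raises(InputError):
            compare_maps(toy_map, empty)


class TestSearchlightPipeline:
    def test_single_searchlight_equals_direct_mantel(self, small_scores):
        betas = make_betas(n_subjects=12, shape=(5, 5, 5), seed=9)
        betas.subject_order = list(small_scores.subject_order)
        mask = np.ones((5, 5, 5), bool)
        lights = build_searchlights(mask, V=30)
        model = build_model(small_scores, "nn_abs")
        smap = searchlight_isrsa(betas, model, lights[:3], B=300, seed=4)
        sl = lights[1]
        rdm = pattern_rdm(betas, sl.members)
        eng = MantelEngine(model, B=300, seed=4)
        res = eng.test(rdm, alternative="auto")
        assert smap.rho_volume[sl.center] == pytest.approx(res.rho, rel=1e-12)
        assert smap.p_volume[sl.center] == res.p

    def test_degenerate_searchlight_recorded_not_fatal(self, small_scores):
        betas = make_betas(n_subjects=12, shape=(5, 5, 5), seed=10)
        betas.subject_order = list(small_scores.subject_order)
        betas.data[3, :3] = 0.0  # constant corner pattern for one subject
        mask = np.ones((5, 5, 5), bool)
        lights = build_searchlights(mask, V=25)
        model = build_model(small_scores, "nn_abs")
        smap = searchlight_isrsa(betas, model, lights, B=100, seed=0)
        assert len(smap.failures) > 0
        assert np.isnan(smap.p_volume[next(iter(smap.failures))])
        assert np.isfinite(smap.p_volume).sum() == len(lights) - len(smap.failures)


class TestPartialSpearman:
    def test_y_equals_x(self, rng):
        x = rng.standard_normal(40)
        cov = rng.standard_normal((40, 3))
        rho, p = partial_spearman(x, x.copy(), cov)
        assert rho == pytest.approx(1.0)
        assert p == 0.0

    def test_covariate_driven_association_removed(self, rng):
        # y depends only on a covariate; partial rho ~ 0 in expectation
        rhos = []
        for _ in range(200):
            c = rng.standard_normal(30)
            y = 2 * c + 0.1 * rng.standard_normal(30)
            x = rng.standard_normal(30)
            rhos.append(partial_spearman(x, y, c[:, None])[0])
        assert abs(np.mean(rhos)) < 0.05

    def test_matches_residualize_oracle(self, rng):
        x = rng.standard_normal(25)
        y = rng.standard_normal(25)
        C = rng.standard_normal((25, 3))
        rho, p = partial_spearman(x, y, C)
        # independent oracle: normal equations on ranks, then correlate
        rx, ry = rankdata(x), rankdata(y)
        D = np.column_stack([np.ones(25)] + [rankdata(C[:, j]) for j in range(3)])
        ex = rx - D @ np.linalg.solve(D.T @ D, D.T @ rx)
        ey = ry - D @ np.linalg.solve(D.T @ D, D.T @ ry)
        r_oracle = (ex @ ey) / np.sqrt((ex @ ex) * (ey @ ey))
        assert rho == pytest.approx(r_oracle, rel=1e-12)
        from scipy.stats import t as t_dist
        df = 25 - 2 - 3
        t_o = r_oracle * np.sqrt(df / (1 - r_oracle**2))
        assert p == pytest.approx(2 * t_dist.sf(abs(t_o), df), rel=1e-12)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        x = rng.standard_normal(30)
        y = 0.5 * x + rng.standard_normal(30)
        C = rng.standard_normal((30, 2))
        df = pd.DataFrame({"x": x, "y": y, "c1": C[:, 0], "c2": C[:, 1]})
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["c1", "c2"],
                                    method="spearman")
        rho, p = partial_spearman(x, y, C)
        assert rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-6)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-6)

    def test_rank_deficient_covariates_rejected(self, rng):
        x, y = rng.standard_normal(20), rng.standard_normal(20)
        c = rng.standard_normal(20)
        with pytest.raises(InputError):
            partial_spearman(x, y, np.column_stack([c, 2 * c]))
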