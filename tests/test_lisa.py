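from itertools import combinations
from math import comb

import numpy as np
import pytest

import fieldlisa as fl
from fieldlisa.errors import InvalidInputError, InvalidParameterError, NoNeighborsError
from tests.conftest import brute_force_global_moran


class TestWeights:
    def test_chain_neighbors_and_s0(self, chain_weights):
        w = chain_weights
        assert [nb.tolist() for nb in w.neighbors] == [[1], [0, 2], [1]]
        assert w.s0 == 4.0

    def test_threshold_below_min_distance_raises(self):
        with pytest.raises(NoNeighborsError):
            fl.build_weights([(0, 0), (5, 0), (10, 0)], threshold=1.0)

    def test_binary_weights_symmetric(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 10, size=(40, 2))
        w = fl.build_weights(pts, threshold=2.0)
        pairs = {(i, j) for i in range(40) for j in w.neighbors[i]}
        assert all((j, i) in pairs for i, j in pairs)

    def test_no_self_neighbors(self):
        w = fl.build_weights([(0, 0), (0.5, 0), (1, 0)], threshold=2.0)
        assert all(i not in w.neighbors[i] for i in range(w.n))

    def test_inverse_distance_values(self):
        w = fl.build_weights([(0, 0), (2, 0)], threshold=2.0, style="inverse_distance")
        assert w.weights[0][0] == pytest.approx(0.5)

    def test_isolated_points_flagged_not_dropped(self):
        w = fl.build_weights([(0, 0), (1, 0), (50, 50)], threshold=2.0)
        assert w.islands.tolist() == [2]
        assert w.n == 3


class TestLocalMoran:
    def test_hand_computed_chain_values(self, chain_weights, chain_z):
        res = fl.local_moran(chain_z, chain_weights)
        np.testing.assert_allclose(res.I, [0.5, -0.5, -1.0])
        np.testing.assert_allclose(res.lag, [-2 / 3, 2 / 3, -2 / 3])
        assert res.m == pytest.approx(8 / 9)
        assert res.quadrant.tolist() == ["LL", "LH", "HL"]

    @pytest.mark.parametrize("seed", range(50))
    def test_sum_of_local_equals_s0_times_global(self, seed):
        """Additivity: sum_i I_i = S0 * global Moran's I (brute-force oracle)."""
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 10, size=(30, 2))
        z = rng.standard_normal(30)
        z = z - z.mean()
        w = fl.build_weights(pts, threshold=3.0)
        res = fl.local_moran(z, w)
        I_global, s0 = brute_force_global_moran(z, pts, 3.0)
        assert res.I.sum() == pytest.approx(s0 * I_global, rel=1e-9)

    def test_order_invariance_of_statistics(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 10, size=(25, 2))
        z = rng.standard_normal(25)
        z -= z.mean()
        order = rng.permutation(25)
        res1 = fl.local_moran(z, fl.build_weights(pts, 3.0))
        res2 = fl.local_moran(z[order], fl.build_weights(pts[order], 3.0))
        np.testing.assert_allclose(res1.I[order], res2.I, rtol=1e-12)

    def test_zero_ties_classified_high(self):
        # z=0 at a point -> 'H' side by the >= 0 rule
        w = fl.build_weights([(0, 0), (1, 0), (2, 0)], threshold=1.0)
        z = np.array([0.0, -1.0, 1.0])
        res = fl.local_moran(z - z.mean(), w)
        assert res.quadrant[0] in ("HH", "HL")

    def test_length_mismatch_rejected(self, chain_weights):
        with pytest.raises(InvalidInputError):
            fl.local_moran(np.array([1.0, -1.0]), chain_weights)


def exhaustive_conditional_pvalue(z, w, i):
    """Enumerate all neighbor-value subsets for point i (binary weights).

    Under conditional permutation every k-subset of the other N-1 values
    is equally likely to fill i's neighbor slots, so the exact upper-tail
    p-value is the fraction of subsets whose statistic reaches the
    observed one.
    """
    z = np.asarray(z, dtype=float)
    n = len(z)
    k = len(w.neighbors[i])
    m = float(z @ z) / n
    others = np.delete(z, i)
    obs_I = z[i] / m * z[w.neighbors[i]].sum()
    all_I = np.array([z[i] / m * sum(c) for c in combinations(others, k)])
    return (all_I >= obs_I - 1e-12).sum() / comb(n - 1, k)


class TestPermutations:
    def test_minimum_pseudo_p(self):
        # a tight clique of huge values in a sea of noise: redrawing the
        # clique's exact neighbor set is essentially impossible, so the
        # clique center hits the (0 + 1)/(M + 1) floor
        rng = np.random.default_rng(0)
        noise_pts = rng.uniform(5, 40, size=(200, 2))
        clique = np.array([(0.0, 0.0), (0.4, 0.0), (0.0, 0.4), (0.4, 0.4)])
        pts = np.vstack([clique, noise_pts])
        z = np.concatenate([[10.0] * 4, rng.standard_normal(200)])
        z -= z.mean()
        w = fl.build_weights(pts, threshold=1.0)
        p = fl.permutation_pvalues(z, w, n_permutations=999, seed=1)
        assert p[0] == pytest.approx(1 / 1000)
        assert np.nanmin(p) >= 1 / 1000 and np.nanmax(p) <= 1.0

    def test_degenerate_permutation_distribution_gives_p_one(self):
        # all non-self values equal: every permuted I equals the observed one
        pts = np.array([(0, 0), (1, 0), (2, 0), (3, 0)], dtype=float)
        z = np.array([3.0, -1.0, -1.0, -1.0])
        w = fl.build_weights(pts, threshold=1.0)
        p = fl.permutation_pvalues(z, w, n_permutations=99, seed=1)
        assert p[0] == pytest.approx(1.0)

    def test_seed_determinism(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(0, 10, size=(30, 2))
        z = rng.standard_normal(30)
        z -= z.mean()
        w = fl.build_weights(pts, 2.5)
        p1 = fl.permutation_pvalues(z, w, 199, seed=42)
        p2 = fl.permutation_pvalues(z, w, 199, seed=42)
        np.testing.assert_array_equal(p1, p2)

    def test_isolated_point_gets_nan_and_ns(self):
        pts = np.array([(0, 0), (1, 0), (50, 50)], dtype=float)
        z = np.array([1.0, -1.0, 0.0])
        w = fl.build_weights(pts, threshold=2.0)
        res = fl.local_moran(z, w)
        res.pseudo_p = fl.permutation_pvalues(z, w, 99, seed=0)
        assert np.isnan(res.pseudo_p[2])
        res = fl.classify(res, alpha=0.5)
        assert res.class_label[2] == "NS"

    @pytest.mark.parametrize("i", [0, 2, 5])
    def test_exhaustive_enumeration_oracle_small_n(self, i):
        """Monte Carlo pseudo-p matches exact subset enumeration for N=6."""
        rng = np.random.default_rng(7)
        pts = rng.uniform(0, 3, size=(6, 2))
        z = rng.standard_normal(6)
        z -= z.mean()
        w = fl.build_weights(pts, threshold=2.0)
        M = 9999
        p_mc = fl.permutation_pvalues(z, w, n_permutations=M, seed=11)
        p_exact = exhaustive_conditional_pvalue(z, w, i)
        se = np.sqrt(p_exact * (1 - p_exact) / M)
        assert p_mc[i] == pytest.approx(p_exact, abs=max(4 * se + 2 / M, 0.01))

    def test_directed_alternative_flags_low_tail(self):
        """The "directed" option tests toward the observed side, so a
        strong negative-I spatial outlier becomes significant there while
        the default positive-autocorrelation test leaves it at p ~ 1."""
        rng = np.random.default_rng(10)
        noise_pts = rng.uniform(5, 40, size=(200, 2))
        clique = np.array([(0.0, 0.0), (0.4, 0.0), (0.0, 0.4), (0.4, 0.4)])
        pts = np.vstack([clique, noise_pts])
        # clique center high among very low neighbors: H-L outlier
        z = np.concatenate([[10.0, -8.0, -8.0, -8.0], rng.standard_normal(200)])
        z -= z.mean()
        w = fl.build_weights(pts, threshold=1.0)
        p_greater = fl.permutation_pvalues(z, w, 999, seed=2, alternative="greater")
        p_directed = fl.permutation_pvalues(z, w, 999, seed=2, alternative="directed")
        assert p_greater[0] > 0.9
        assert p_directed[0] == pytest.approx(1 / 1000)

    def test_null_calibration_quick(self):
        """Flagged fraction under exchangeable z tracks alpha (0.05 level)."""
        rng = np.random.default_rng(9)
        fracs = []
        for rep in range(10):
            pts = rng.uniform(0, 20, size=(150, 2))
            z = rng.standard_normal(150)
            z -= z.mean()
            est = fl.LocalMoran(threshold=1.75, n_permutations=199, alpha=0.05, seed=rep).fit(pts, z)
            fracs.append(np.mean(est.significant_))
        mean = np.mean(fracs)
        se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
        assert abs(mean - 0.05) <= max(3 * se, 0.02)


class TestClassify:
    def test_significant_keeps_quadrant(self):
        res = fl.LisaResult(
            I=np.array([1.0]), lag=np.array([-1.0]), quadrant=np.array(["LL"], dtype=object),
            pseudo_p=np.array([0.001]),
        )
        assert fl.classify(res, alpha=0.01).class_label[0] == "LL"

    def test_boundary_is_inclusive_at_alpha_exclusive_above(self):
        res = fl.LisaResult(
            I=np.array([1.0, 1.0]), lag=np.array([1.0, 1.0]),
            quadrant=np.array(["HH", "HH"], dtype=object),
            pseudo_p=np.array([0.01, 0.011]),
        )
        out = fl.classify(res, alpha=0.01)
        assert out.class_label.tolist() == ["HH", "NS"]

    def test_alpha_one_keeps_all_quadrants(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 5, size=(15, 2))
        z = rng.standard_normal(15)
        z -= z.mean()
        est = fl.LocalMoran(threshold=3.0, n_permutations=99, alpha=0.999999, seed=0).fit(pts, z)
        assert not (est.labels_ == "NS").any()


class TestScatterplot:
    def test_chain_scatter_signs(self, chain_weights, chain_z):
        df = fl.moran_scatterplot_data(chain_z, chain_weights, row_standardize=False)
        assert df["quadrant"].tolist() == ["LL", "LH", "HL"]
        np.testing.assert_allclose(df["lag"], [-2 / 3, 2 / 3, -2 / 3])

    def test_all_positive_is_all_hh(self):
        w = fl.build_weights([(0, 0), (1, 0), (2, 0)], threshold=1.5)
        df = fl.moran_scatterplot_data(np.array([0.1, 0.2, 0.3]), w)
        assert (df["quadrant"] == "HH").all()

    @pytest.mark.parametrize("seed", range(20))
    def test_ols_slope_equals_global_moran_row_standardized(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 8, size=(25, 2))
        z = rng.standard_normal(25)
        z -= z.mean()
        w = fl.build_weights(pts, threshold=3.0)
        df = fl.moran_scatterplot_data(z, w, row_standardize=True)
        slope = float(np.polyfit(df["z"], df["lag"], 1)[0])
        I_global, _ = brute_force_global_moran(z, pts, 3.0, row_standardize=True)
        assert slope == pytest.approx(I_global, rel=1e-6)

    def test_quadrants_invariant_to_row_scaling(self):
        """Positive row scaling preserves lag signs, hence H/L membership."""
        rng = np.random.default_rng(6)
        pts = rng.uniform(0, 8, size=(30, 2))
        z = rng.standard_normal(30)
        z -= z.mean()
        w = fl.build_weights(pts, threshold=3.0)
        raw = fl.moran_scatterplot_data(z, w, row_standardize=False)["quadrant"]
        rs = fl.moran_scatterplot_data(z, w, row_standardize=True)["quadrant"]
        non_island = np.setdiff1d(np.arange(30), w.islands)
        assert (raw.iloc[non_island] == rs.iloc[non_island]).all()


class TestEstimatorApi:
    def test_get_set_params_roundtrip(self):
        est = fl.LocalMoran(threshold=2.0, alpha=0.05)
        params = est.get_params()
        assert params["threshold"] == 2.0
        est.set_params(threshold=1.75)
        assert est.threshold == 1.75

    def test_fit_predict_returns_labels(self):
        rng = np.random.default_rng(8)
        pts = rng.uniform(0, 5, size=(20, 2))
        z = rng.standard_normal(20)
        z -= z.mean()
        labels = fl.LocalMoran(threshold=2.0, n_permutations=99, seed=0).fit_predict(pts, z)
        assert set(labels) <= {"HH", "LL", "LH", "HL", "NS"}

    def test_bad_permutation_count_rejected(self, chain_weights, chain_z):
        with pytest.raises(InvalidParameterError):
            fl.permutation_pvalues(chain_z, chain_weights, n_permutations=0)
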