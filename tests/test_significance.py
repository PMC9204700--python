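import math

import numpy as np
import pytest
from scipy import stats

from hdxkit.cluster_io import Species, UptakeCurve
from hdxkit.significance import (ComparisonResult, DistributionSet,
                                 GlobalThreshold, SignificanceError,
                                 build_distribution, enumerate_assignments,
                                 global_threshold_bootstrap,
                                 global_threshold_pairwise,
                                 global_threshold_sd, hybrid_test,
                                 remove_outliers, welch_test)

SP = Species("p", 1, 10, "KLSAMGTRAV", max_uptake=8)


def _curve(times, reps, noise=0.0, seed=0, k=0.1, beta=0.9, n=5.0):
    rng = np.random.default_rng(seed)
    ts, us, rs = [], [], []
    for r in range(1, reps + 1):
        t = np.asarray(times, float)
        u = n * -np.expm1(-((k * t) ** beta))
        if noise:
            u = u + noise * rng.standard_normal(len(t))
        ts.append(t), us.append(u), rs.append(np.full(len(t), r))
    return UptakeCurve(SP, "apo", np.concatenate(ts), np.concatenate(us),
                       np.concatenate(rs))


TIMES = (0.5, 2.0, 10.0, 50.0, 250.0)


class TestDistributions:
    def test_per_replicate_count_contract(self):
        dist = build_distribution(_curve(TIMES, 3, noise=0.02), "per_replicate")
        assert len(dist.samples) == 3

    def test_zero_noise_degenerates_for_every_method(self):
        curve = _curve(TIMES, 3, noise=0.0)
        for method in ("per_replicate", "random", "bootstrap"):
            dist = build_distribution(curve, method, seed=1, n_samples_s=8,
                                      bootstrap_b=200)
            assert dist.sd == pytest.approx(0.0, abs=1e-9)

    def test_single_replicate_rejected(self):
        with pytest.raises(SignificanceError, match="single replicate"):
            build_distribution(_curve(TIMES, 1), "per_replicate")

    def test_bootstrap_pool_enumeration_2x2(self):
        # 2 time points x 2 replicates -> exactly 4 assignments
        curve = _curve((1.0, 10.0), 2, noise=0.01)
        pool = enumerate_assignments(curve)
        assert len(pool) == 4
        expected = {tuple(sorted(d.items()))
                    for d in ({1.0: a, 10.0: b}
                              for a in (1, 2) for b in (1, 2))}
        assert {tuple(sorted(d.items())) for d in pool} == expected

    def test_bootstrap_deterministic_under_seed(self):
        curve = _curve(TIMES, 3, noise=0.05)
        d1 = build_distribution(curve, "bootstrap", seed=42, n_samples_s=10,
                                bootstrap_b=500)
        d2 = build_distribution(curve, "bootstrap", seed=42, n_samples_s=10,
                                bootstrap_b=500)
        assert np.array_equal(d1.samples, d2.samples)

    def test_uptake_metric_reads_experimental_points(self):
        curve = _curve(TIMES, 3, noise=0.05, seed=3)
        dist = build_distribution(curve, "per_replicate", metric="uptake",
                                  time=10.0)
        expected = curve.uptakes[curve.times == 10.0]
        assert np.allclose(np.sort(dist.samples), np.sort(expected))

    def test_missing_replicate_skipped_in_per_replicate(self):
        curve = _curve(TIMES, 3, noise=0.02)
        mask = ~((curve.times == 10.0) & (curve.replicates == 2))
        curve = UptakeCurve(SP, "apo", curve.times[mask], curve.uptakes[mask],
                            curve.replicates[mask])
        dist = build_distribution(curve, "per_replicate")
        assert len(dist.samples) == 3  # replicate 2 fitted from its 4 times


class TestOutliers:
    @pytest.mark.parametrize("method",
                             ["mean", "median", "quartiles", "grubbs", "gesd"])
    def test_identical_values_untouched(self, method):
        x = np.ones(10)
        assert len(remove_outliers(x, method)) == 10

    def test_quartiles_zero_iqr_drops_extreme(self):
        x = np.array([0.0] * 9 + [100.0])
        out = remove_outliers(x, "quartiles")
        assert 100.0 not in out and len(out) == 9

    @pytest.mark.parametrize("method",
                             ["mean", "median", "quartiles", "grubbs", "gesd"])
    def test_clean_gaussian_mostly_kept(self, method):
        x = np.random.default_rng(1).standard_normal(100)
        out = remove_outliers(x, method)
        assert len(out) >= 90

    def test_obvious_outlier_removed_by_all(self):
        x = np.concatenate([np.random.default_rng(2).standard_normal(30),
                            [40.0]])
        for method in ("mean", "median", "quartiles", "grubbs", "gesd"):
            assert 40.0 not in remove_outliers(x, method)

    def test_too_few_values_returned_unchanged(self):
        x = np.array([1.0, 2.0])
        assert np.array_equal(remove_outliers(x, "grubbs"), x)


def _dist(samples, method="per_replicate", metric="uptake_area", state="apo"):
    return DistributionSet(SP, state, metric, np.asarray(samples, float),
                           method)


class TestThresholds:
    def test_sd_formula(self):
        # equal per-species sd sigma with n=3 per state
        sigma = 0.4
        a = sigma * np.array([-1.0, 0.0, 1.0])   # sample sd exactly sigma
        dists = [_dist(a), _dist(a + 5.0)]
        thr = global_threshold_sd(dists, 0.95, n_a=3, n_b=3)
        expected = stats.norm.ppf(0.975) * sigma * math.sqrt(2.0 / 3.0)
        assert thr.value == pytest.approx(expected, rel=1e-9)

    def test_all_zero_sds_give_zero_threshold(self):
        dists = [_dist([1.0, 1.0, 1.0]), _dist([2.0, 2.0, 2.0])]
        assert global_threshold_sd(dists, 0.95, 3, 3).value == 0.0

    def test_confidence_monotonicity(self):
        rng = np.random.default_rng(0)
        dists = [_dist(rng.standard_normal(3)) for _ in range(10)]
        t95 = global_threshold_sd(dists, 0.95, 3, 3).value
        t99 = global_threshold_sd(dists, 0.99, 3, 3).value
        assert t99 > t95

    def test_pairwise_count_and_zero_noise(self):
        d = _dist([1.0, 1.0, 1.0])
        thr = global_threshold_pairwise([d, d], 0.95)
        assert thr.value == 0.0
        assert thr.pool_size == 2 * math.comb(3, 2)

    def test_pairwise_matches_sqrt2_sigma(self):
        # differences of two iid N(0, sigma) have sd sigma*sqrt(2)
        rng = np.random.default_rng(5)
        sigma = 0.3
        dists = [_dist(rng.normal(0, sigma, 3)) for _ in range(2000)]
        thr = global_threshold_pairwise(dists, 0.95)
        expected = stats.norm.ppf(0.975) * sigma * math.sqrt(2)
        assert thr.value == pytest.approx(expected, rel=0.05)

    def test_pairwise_rejects_bootstrap(self):
        d = _dist([1.0, 2.0], method="bootstrap")
        with pytest.raises(SignificanceError, match="bootstrap"):
            global_threshold_pairwise([d], 0.95)

    def test_bootstrap_percentile_matches_z_sd_for_normal_pool(self):
        rng = np.random.default_rng(7)
        sigma = 0.2
        dists = [_dist(rng.normal(5.0, sigma, 2000), method="bootstrap")
                 for _ in range(5)]
        thr = global_threshold_bootstrap(dists, 0.95)
        assert thr.value == pytest.approx(stats.norm.ppf(0.975) * sigma,
                                          rel=0.05)

    def test_bootstrap_zero_noise_and_monotonicity(self):
        flat = _dist(np.full(100, 3.7), method="bootstrap")
        assert global_threshold_bootstrap([flat], 0.95).value == 0.0
        rng = np.random.default_rng(8)
        dists = [_dist(rng.standard_normal(500), method="bootstrap")]
        assert global_threshold_bootstrap(dists, 0.99).value >= \
            global_threshold_bootstrap(dists, 0.95).value

    def test_bootstrap_requires_bootstrap_dists(self):
        with pytest.raises(SignificanceError, match="bootstrap"):
            global_threshold_bootstrap([_dist([1.0, 2.0])], 0.95)


def _welch_oracle(a, b):
    """Textbook Welch formula, written independently of the implementation."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va = np.sum((a - a.mean()) ** 2) / (na - 1)
    vb = np.sum((b - b.mean()) ** 2) / (nb - 1)
    t = (a.mean() - b.mean()) / math.sqrt(va / na + vb / nb)
    df = (va / na + vb / nb) ** 2 / (
        (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, df, p


class TestWelch:
    def test_identical_groups(self):
        t, _df, p = welch_test([1.0, 2.0, 3.0], [2.0, 1.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_textbook_oracle(self):
        a, b = [1.0, 1.1, 0.9], [2.0, 2.1, 1.9]
        t, df, p = welch_test(a, b)
        to, dfo, po = _welch_oracle(a, b)
        assert t == pytest.approx(to, abs=1e-12)
        assert df == pytest.approx(dfo, abs=1e-12)
        assert p == pytest.approx(po, abs=1e-12)

    def test_random_samples_match_oracle_to_1e10(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a = rng.normal(0, 1 + rng.random(), rng.integers(2, 9))
            b = rng.normal(rng.random(), 1.0, rng.integers(2, 9))
            t, df, p = welch_test(a, b)
            to, dfo, po = _welch_oracle(a, b)
            assert abs(p - po) < 1e-10 and abs(t - to) < 1e-10

    def test_swapping_groups_flips_sign(self):
        a, b = [1.0, 1.2, 0.8], [2.0, 2.4, 1.6]
        t1, _, p1 = welch_test(a, b)
        t2, _, p2 = welch_test(b, a)
        assert t1 == -t2 and p1 == p2

    def test_degenerate_conventions(self):
        assert welch_test([1.0, 1.0], [1.0, 1.0])[2] == 1.0
        assert welch_test([1.0, 1.0], [2.0, 2.0])[2] == 0.0


class TestHybrid:
    def _comp(self, diff, p):
        return ComparisonResult(SP, "a", "b", "uptake_area", diff, p)

    def test_conjunction_required(self):
        thr = GlobalThreshold("uptake_area", "sd_ci", 0.95, 1.0)
        out = hybrid_test([self._comp(2.0, 0.2),    # above thr, p too big
                           self._comp(0.5, 0.001),  # p small, below thr
                           self._comp(2.0, 0.001)], thr)
        assert [c.significant for c in out] == [False, False, True]

    def test_threshold_is_strict(self):
        thr = GlobalThreshold("uptake_area", "sd_ci", 0.95, 1.0)
        out = hybrid_test([self._comp(1.0, 0.001)], thr)
        assert out[0].significant is False

    def test_metric_mismatch_rejected(self):
        thr = GlobalThreshold("uptake", "sd_ci", 0.95, 1.0)
        with pytest.raises(SignificanceError, match="mismatch"):
            hybrid_test([self._comp(1.0, 0.5)], thr)
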