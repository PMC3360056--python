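import numpy as np
import pandas as pd
import pytest
from scipy import stats

from miccea.errors import ValidationError
from miccea.uncertainty import (
    BootstrapSpec,
    abc_interval,
    bca_interval,
    bootstrap_ce_pairs,
    bootstrap_difference,
    jackknife_acceleration,
    percentile_interval,
)


class TestBootstrapDifference:
    def test_same_seed_identical_replicate_stream(self, rng):
        a, b = rng.gamma(1, 100, 40), rng.gamma(1, 90, 35)
        r1 = bootstrap_difference(a, b, BootstrapSpec(B=500, seed=9))
        r2 = bootstrap_difference(a, b, BootstrapSpec(B=500, seed=9))
        assert np.array_equal(r1.replicates, r2.replicates)
        r3 = bootstrap_difference(a, b, BootstrapSpec(B=500, seed=10))
        assert not np.array_equal(r1.replicates, r3.replicates)

    def test_constant_arms_collapse_to_point(self):
        res = bootstrap_difference([5.0] * 10, [3.0] * 8, BootstrapSpec(B=200, seed=0))
        assert res.degenerate
        assert np.all(res.replicates == 2.0)
        assert res.interval == (2.0, 2.0)

    def test_percentile_endpoints_are_order_statistics(self, rng):
        a, b = rng.gamma(1, 100, 30), rng.gamma(1, 90, 30)
        res = bootstrap_difference(
            a, b, BootstrapSpec(B=1000, seed=4, ci_method="percentile")
        )
        # oracle: direct sort + linear interpolation
        expected = np.quantile(np.sort(res.replicates), [0.025, 0.975])
        assert res.interval == pytest.approx(tuple(expected))

    def test_missing_values_rejected(self):
        with pytest.raises(ValidationError, match="imputed"):
            bootstrap_difference([1.0, np.nan], [1.0, 2.0], BootstrapSpec(B=200, seed=0))

    def test_cluster_resampling_differs_from_patient_resampling(self, rng):
        a, b = rng.gamma(1, 100, 60), rng.gamma(1, 90, 60)
        ca = np.repeat(np.arange(6), 10)
        spec = BootstrapSpec(B=400, seed=3)
        r_pat = bootstrap_difference(a, b, spec)
        r_clu = bootstrap_difference(
            a, b, spec.replace(cluster_resample=True), clusters_mic=ca, clusters_uc=ca
        )
        assert r_pat.point == pytest.approx(r_clu.point)
        assert not np.array_equal(r_pat.replicates, r_clu.replicates)


class TestIntervals:
    def test_bca_reduces_to_percentile_when_corrections_vanish(self, rng):
        reps = rng.normal(0, 1, 4001)
        point = float(np.median(reps))  # z0 = 0 by construction
        (lo, hi), z0 = bca_interval(reps, point, acceleration=0.0)
        assert abs(z0) < 1e-6
        assert (lo, hi) == pytest.approx(percentile_interval(reps), abs=1e-9)

    def test_jackknife_acceleration_matches_exhaustive_oracle(self):
        a = np.array([1.0, 2.0, 4.5, 7.0, 11.0])
        b = np.array([0.5, 2.5, 3.0, 9.0, 10.0])
        # oracle: literal leave-one-out recomputation + skewness formula
        loo = []
        for i in range(5):
            loo.append(np.delete(a, i).mean() - b.mean())
        for j in range(5):
            loo.append(a.mean() - np.delete(b, j).mean())
        loo = np.array(loo)
        d = loo.mean() - loo
        expected = (d**3).sum() / (6 * ((d**2).sum()) ** 1.5)
        assert jackknife_acceleration(a, b) == pytest.approx(expected, rel=1e-12)

    def test_bca_agrees_with_scipy_reference(self, rng):
        a = rng.gamma(0.7, 150, 80)
        b = rng.gamma(0.7, 120, 70)
        res = bootstrap_difference(a, b, BootstrapSpec(B=4000, seed=12, ci_method="bca"))
        ref = stats.bootstrap(
            (a, b),
            lambda x, y, axis=-1: x.mean(axis=axis) - y.mean(axis=axis),
            n_resamples=4000,
            method="BCa",
            random_state=np.random.default_rng(12),
        )
        lo, hi = ref.confidence_interval
        width = hi - lo
        assert res.interval[0] == pytest.approx(lo, abs=0.15 * width)
        assert res.interval[1] == pytest.approx(hi, abs=0.15 * width)

    def test_abc_near_symmetric_matches_normal_theory(self, rng):
        a = rng.normal(10, 2, 200)
        b = rng.normal(8, 2, 200)
        (lo, hi), z0, acc = abc_interval(a, b)
        point = a.mean() - b.mean()
        se = np.sqrt(a.var() / len(a) + b.var() / len(b))
        assert abs(acc) < 0.05
        assert lo == pytest.approx(point - 1.96 * se, abs=0.3 * se)
        assert hi == pytest.approx(point + 1.96 * se, abs=0.3 * se)


def _toy_datasets(rng, m=3, n=40, effect_cost=0.0, effect_eff=0.0):
    out = []
    for _ in range(m):
        arm = np.array(["MIC"] * n + ["UC"] * n)
        cost = np.concatenate([rng.gamma(1, 100, n) + effect_cost, rng.gamma(1, 100, n)])
        eff = np.concatenate([rng.normal(effect_eff, 1, n), rng.normal(0, 1, n)])
        out.append(pd.DataFrame({"arm": arm, "total_cost": cost, "qaly": eff}))
    return out


class TestCEPairs:
    def test_stacked_count_is_m_times_B(self, rng):
        ds = _toy_datasets(rng, m=4)
        pairs = bootstrap_ce_pairs(ds, BootstrapSpec(B=150, seed=0), "qaly")
        assert len(pairs.replicates) == 4 * 150
        assert set(pairs.replicates["imputation"]) == {0, 1, 2, 3}

    def test_zero_variance_data_gives_identical_pairs(self):
        df = pd.DataFrame(
            {"arm": ["MIC"] * 5 + ["UC"] * 5, "total_cost": [10.0] * 5 + [4.0] * 5, "qaly": [1.0] * 5 + [0.5] * 5}
        )
        pairs = bootstrap_ce_pairs([df], BootstrapSpec(B=100, seed=0), "qaly")
        assert np.all(pairs.delta_cost == 6.0)
        assert np.all(pairs.delta_effect == 0.5)

    def test_null_model_cloud_centered_at_origin(self, rng):
        ds = _toy_datasets(rng, m=2, n=400)
        pairs = bootstrap_ce_pairs(ds, BootstrapSpec(B=400, seed=1), "qaly")
        se_c = pairs.delta_cost.std()
        se_e = pairs.delta_effect.std()
        assert abs(pairs.delta_cost.mean()) < 3 * se_c
        assert abs(pairs.delta_effect.mean()) < 3 * se_e

    def test_pair_means_near_point_estimates(self, rng):
        ds = _toy_datasets(rng, m=3, n=150, effect_cost=50.0, effect_eff=0.4)
        pairs = bootstrap_ce_pairs(ds, BootstrapSpec(B=500, seed=2), "qaly")
        assert pairs.delta_cost.mean() == pytest.approx(
            pairs.point_delta_cost, abs=3 * pairs.delta_cost.std() / np.sqrt(len(pairs.replicates))
        + 0.02 * abs(pairs.point_delta_cost) + 1.0)
        assert pairs.delta_effect.mean() == pytest.approx(pairs.point_delta_effect, abs=0.05)

    def test_missing_values_are_hard_error(self):
        df = pd.DataFrame(
            {"arm": ["MIC", "MIC", "UC", "UC"], "total_cost": [1, np.nan, 2, 3], "qaly": [1, 2, 3, 4]}
        )
        with pytest.raises(ValidationError, match="missing"):
            bootstrap_ce_pairs([df], BootstrapSpec(B=100, seed=0), "qaly")

    def test_cost_effect_correlation_preserved(self, rng):
        # cost and effect strongly correlated within patients -> replicate
        # pairs must inherit the correlation (joint resampling)
        n = 100
        base = rng.gamma(2, 50, 2 * n)
        df = pd.DataFrame(
            {
                "arm": ["MIC"] * n + ["UC"] * n,
                "total_cost": base,
                "qaly": base / 100 + rng.normal(0, 0.05, 2 * n),
            }
        )
        pairs = bootstrap_ce_pairs([df], BootstrapSpec(B=500, seed=3), "qaly")
        r = np.corrcoef(pairs.delta_cost, pairs.delta_effect)[0, 1]
        assert r > 0.8
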