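"""Unit and property tests for the estimation-statistics core."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from axenic.estimation_stats import (
    EffectBands,
    EffectEstimate,
    EstimationError,
    _bca_adjusted_levels,
    bca_ci,
    classify_effect,
    hedges_g,
    mean_difference,
    proforma_p,
    silverman_bandwidth,
    smoothed_bootstrap_median,
    two_sample_estimate,
)

SEED = 1234

finite_floats = st.floats(-1e6, 1e6, allow_nan=False)
samples = st.lists(finite_floats, min_size=2, max_size=30)


class TestMeanDifference:
    def test_equal_means_give_zero(self):
        assert mean_difference([1.0, 2.0, 3.0], [3.0, 2.0, 1.0]) == 0.0

    def test_direct_value(self):
        assert mean_difference([5.0, 7.0], [1.0, 3.0]) == pytest.approx(4.0)

    @given(samples, samples)
    @settings(max_examples=50, deadline=None)
    def test_antisymmetry(self, a, b):
        assert mean_difference(a, b) == pytest.approx(-mean_difference(b, a), abs=1e-6)

    def test_empty_sample_rejected(self):
        with pytest.raises(EstimationError):
            mean_difference([], [1.0])


class TestHedgesG:
    def test_identical_groups_zero(self):
        assert hedges_g([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_hand_computed_example(self):
        # raw d = -1 with pooled SD 1; J = 1 - 3/15 = 0.8
        assert hedges_g([0, 1, 2], [1, 2, 3]) == pytest.approx(-0.8)

    @given(samples, samples, st.floats(0.1, 100.0))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance_and_antisymmetry(self, a, b, c):
        a, b = np.asarray(a), np.asarray(b)
        if _degenerate(a, b):
            return
        g = hedges_g(a, b)
        assert hedges_g(c * a, c * b) == pytest.approx(g, rel=1e-6, abs=1e-9)
        assert hedges_g(b, a) == pytest.approx(-g, rel=1e-6, abs=1e-9)

    @given(samples, samples, finite_floats)
    @settings(max_examples=50, deadline=None)
    def test_shift_invariance_of_magnitude(self, a, b, shift):
        a, b = np.asarray(a), np.asarray(b)
        if _degenerate(a, b):
            return
        assert abs(hedges_g(a + shift, b + shift)) == pytest.approx(
            abs(hedges_g(a, b)), rel=1e-5, abs=1e-7
        )

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(EstimationError):
            hedges_g([1.0, 1.0], [1.0, 1.0])

    def test_small_sample_bias_removed(self):
        # J-corrected g is centred on the true standardized effect
        rng = np.random.default_rng(SEED)
        gs = [
            hedges_g(rng.normal(0.5, 1, 10), rng.normal(0, 1, 10))
            for _ in range(4000)
        ]
        assert np.mean(gs) == pytest.approx(0.5, abs=0.03)


def _degenerate(a, b):
    sp = np.sqrt(
        ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
        / (a.size + b.size - 2)
    )
    return sp < 1e-9 * max(1.0, np.abs(a).max(), np.abs(b).max())


class TestBcaCi:
    def test_degenerate_data_zero_width(self):
        with pytest.warns(UserWarning, match="degenerate"):
            lo, hi = bca_ci([2.0, 2.0, 2.0], [2.0, 2.0, 2.0], mean_difference,
                            n_boot=200, seed=SEED)
        assert (lo, hi) == (0.0, 0.0)

    def test_reduces_to_percentile_when_unadjusted(self):
        # analytic reduction: z0 = 0 and a = 0 leave the nominal levels intact
        lo, hi = _bca_adjusted_levels(0.0, 0.0, 0.95)
        assert lo == pytest.approx(0.025, abs=1e-12)
        assert hi == pytest.approx(0.975, abs=1e-12)

    def test_contains_point_estimate(self, rng):
        x, y = rng.normal(1, 1, 30), rng.normal(0, 1, 30)
        est = mean_difference(x, y)
        lo, hi = bca_ci(x, y, mean_difference, n_boot=2000, seed=SEED)
        assert lo <= est <= hi

    def test_width_shrinks_with_sample_size(self, rng):
        widths = []
        for n in (10, 40, 160):
            w = []
            for _ in range(30):
                x, y = rng.normal(1, 1, n), rng.normal(0, 1, n)
                lo, hi = bca_ci(x, y, mean_difference, n_boot=500, seed=rng)
                w.append(hi - lo)
            widths.append(np.mean(w))
        assert widths[0] > widths[1] > widths[2]

    def test_generic_statistic_path_matches_fast_path(self, rng):
        x, y = rng.normal(1, 1, 25), rng.normal(0, 1, 25)

        def md(a, b):  # same statistic, not the fast-pathed object
            return float(np.mean(a) - np.mean(b))

        assert bca_ci(x, y, md, n_boot=800, seed=SEED) == pytest.approx(
            bca_ci(x, y, mean_difference, n_boot=800, seed=SEED)
        )

    def test_agrees_with_scipy_bca_reference(self, rng):
        # independent reference implementation of the BCa construction
        from scipy.stats import bootstrap as scipy_bootstrap

        x, y = rng.normal(0.7, 1.2, 45), rng.normal(0.0, 1.0, 40)
        lo, hi = bca_ci(x, y, mean_difference, n_boot=8000, seed=SEED)
        ref = scipy_bootstrap(
            (x, y),
            lambda a, b, axis=-1: a.mean(axis=axis) - b.mean(axis=axis),
            n_resamples=8000, confidence_level=0.95, method="BCa",
            vectorized=True, rng=np.random.default_rng(SEED),
        ).confidence_interval
        scale = np.std(x) / np.sqrt(x.size)
        assert lo == pytest.approx(ref.low, abs=0.15 * scale)
        assert hi == pytest.approx(ref.high, abs=0.15 * scale)

    def test_works_for_hedges_g(self, rng):
        x, y = rng.normal(0.6, 1, 40), rng.normal(0, 1, 40)
        lo, hi = bca_ci(x, y, hedges_g, n_boot=1000, seed=SEED)
        assert lo <= hedges_g(x, y) <= hi


class TestSmoothedBootstrapMedian:
    def test_constant_sample(self):
        assert smoothed_bootstrap_median([3.0] * 10, n_boot=100, seed=SEED) == (3.0, 3.0, 3.0)

    def test_zero_bandwidth_recovers_plain_bootstrap(self, rng):
        # independent unsmoothed implementation with the same resampling scheme
        x = rng.normal(0, 1, 25)
        med, lo, hi = smoothed_bootstrap_median(x, n_boot=4000, seed=SEED, bandwidth=0.0)
        r2 = np.random.default_rng(SEED)
        idx = r2.integers(0, x.size, size=(4000, x.size))
        meds = np.median(np.sort(x)[idx], axis=1)
        plo, phi = np.quantile(meds, [0.025, 0.975])
        assert med == np.median(x)
        assert (lo, hi) == pytest.approx((plo, phi))

    def test_ci_roughly_symmetric_for_symmetric_sample(self, rng):
        x = np.concatenate([rng.normal(5, 1, 200), 10 - rng.normal(5, 1, 200)])
        med, lo, hi = smoothed_bootstrap_median(x, n_boot=4000, seed=SEED)
        assert (med - lo) == pytest.approx(hi - med, abs=0.15)

    def test_bandwidth_widens_support(self, rng):
        # lattice-valued data: smoothing de-granularizes the median distribution
        x = rng.integers(0, 3, 40).astype(float)
        _, lo0, hi0 = smoothed_bootstrap_median(x, n_boot=2000, seed=SEED, bandwidth=0.0)
        _, lo1, hi1 = smoothed_bootstrap_median(x, n_boot=2000, seed=SEED)
        assert hi1 - lo1 >= hi0 - lo0

    def test_silverman_zero_for_constant(self):
        assert silverman_bandwidth([2.0, 2.0, 2.0]) == 0.0


class TestClassifyEffect:
    @pytest.mark.parametrize(
        "g,label",
        [
            (0.68, "moderate"),
            (-0.04, "trivial"),
            (0.2, "trivial"),  # boundary goes to the lower band
            (0.5, "small"),
            (0.8, "moderate"),
            (-0.81, "large"),
            (0.0, "trivial"),
        ],
    )
    def test_bands(self, g, label):
        assert classify_effect(g) == label

    def test_custom_bands_validated(self):
        with pytest.raises(ValueError):
            EffectBands(0.5, 0.4, 0.8)

    def test_nonfinite_rejected(self):
        with pytest.raises(EstimationError):
            classify_effect(float("nan"))


class TestProformaP:
    def test_identical_groups_near_one(self):
        assert proforma_p([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0]) == pytest.approx(1.0)

    def test_monotone_in_separation(self, rng):
        x = rng.normal(0, 1, 40)
        y = rng.normal(0, 1, 40)
        ps = [proforma_p(x + d, y) for d in (0.0, 0.5, 1.0, 2.0)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_permutation_matches_exhaustive_enumeration(self):
        # oracle: complete enumeration of the 8-choose-4 group relabellings
        x = np.array([1.2, 0.3, 2.1, 0.9])
        y = np.array([-0.5, 0.4, -1.1, 0.2])
        pooled = np.concatenate([x, y])
        obs = abs(x.mean() - y.mean())
        count = 0
        total = 0
        for pick in itertools.combinations(range(8), 4):
            rest = [i for i in range(8) if i not in pick]
            stat = abs(pooled[list(pick)].mean() - pooled[rest].mean())
            count += stat >= obs - 1e-12
            total += 1
        expected = count / total
        p = proforma_p(x, y, method="permutation", n_perm=100_000, seed=SEED)
        assert p == pytest.approx(expected, abs=1e-9)


class TestEffectEstimate:
    def test_ci_must_contain_estimate(self):
        with pytest.raises(EstimationError):
            EffectEstimate(kind="hedges_g", estimate=1.0, ci_low=1.5, ci_high=2.0)

    def test_two_sample_estimate_record(self, rng):
        x, y = rng.normal(0.8, 1, 30), rng.normal(0, 1, 30)
        est = two_sample_estimate(x, y, kind="hedges_g", n_boot=500, seed=SEED)
        assert est.n1 == est.n2 == 30
        assert est.ci_low <= est.estimate <= est.ci_high
        assert est.label in ("trivial", "small", "moderate", "large")
        assert est.p_value is not None

    def test_low_n_flagged(self):
        est = two_sample_estimate([1.0, 2.0, 3.0], [2.0, 3.0, 4.0],
                                  kind="mean_difference", n_boot=200, seed=SEED)
        assert "low_n" in est.flags
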