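import math

import numpy as np
import pytest
from scipy import optimize, stats

from meahazard import cutoff_calibration as cc
from meahazard.io_formats import ScoringConfig, ValidationError


def howe_k_oracle(n, p, gamma):
    """Independent numeric route: quantiles via root-finding on the CDFs."""
    z = optimize.brentq(lambda x: stats.norm.cdf(x) - (1 + p) / 2, 0, 20)
    chi2 = optimize.brentq(
        lambda x: stats.chi2.cdf(x, n - 1) - (1 - gamma), 1e-9, 10 * n + 100
    )
    return z * math.sqrt((n - 1) * (1 + 1 / n) / chi2)


class TestHoweKFactor:
    def test_n30_reference_value(self):
        k = cc.howe_k_factor(30, 0.95, 0.95)
        assert k == pytest.approx(howe_k_oracle(30, 0.95, 0.95), abs=1e-10)
        assert k == pytest.approx(2.55, abs=0.01)

    def test_asymptotic_limit(self):
        assert cc.howe_k_factor(10**6, 0.95, 0.95) == pytest.approx(
            1.96, abs=0.01
        )

    def test_monotone_in_n_p_gamma(self):
        ns = [5, 10, 30, 100, 1000]
        ks = [cc.howe_k_factor(n, 0.95, 0.95) for n in ns]
        assert all(a > b for a, b in zip(ks, ks[1:]))
        ps = [0.80, 0.90, 0.95, 0.99]
        kp = [cc.howe_k_factor(30, p, 0.95) for p in ps]
        assert all(a < b for a, b in zip(kp, kp[1:]))
        gs = [0.80, 0.90, 0.95, 0.99]
        kg = [cc.howe_k_factor(30, 0.95, g) for g in gs]
        assert all(a < b for a, b in zip(kg, kg[1:]))

    def test_monte_carlo_coverage_cross_check(self, rng):
        """k(n=30) gives >= 95% of TIs covering >= 95% of a known normal."""
        n, reps = 30, 2000
        k = cc.howe_k_factor(n, 0.95, 0.95)
        draws = rng.normal(0.0, 1.0, size=(reps, n))
        means = draws.mean(axis=1)
        sds = draws.std(axis=1, ddof=1)
        cover = stats.norm.cdf(means + k * sds) - stats.norm.cdf(
            means - k * sds
        )
        frac = np.mean(cover >= 0.95)
        se = math.sqrt(0.95 * 0.05 / reps)
        assert frac >= 0.95 - 3 * se


class TestNormalToleranceInterval:
    def test_structure(self, rng):
        ti = cc.normal_tolerance_interval(rng.normal(5, 2, 50))
        assert ti.lower < ti.upper
        assert ti.n == 50
        assert ti.method == "normal"

    def test_insufficient_data(self):
        with pytest.raises(ValidationError):
            cc.normal_tolerance_interval([1.0])

    def test_zero_variance_degenerate(self):
        with pytest.warns(cc.CalibrationWarning):
            ti = cc.normal_tolerance_interval([3.0, 3.0, 3.0])
        assert ti.lower == ti.upper == 3.0

    def test_large_sample_k_limit(self, rng):
        ti = cc.normal_tolerance_interval(rng.normal(0, 1, 10**6))
        assert ti.k_factor == pytest.approx(1.96, abs=0.01)

    def test_scale_equivariance(self, rng):
        x = rng.normal(0, 10, 40)
        t1 = cc.normal_tolerance_interval(x)
        t2 = cc.normal_tolerance_interval(3.0 * x)
        assert t2.lower == pytest.approx(3.0 * t1.lower, rel=1e-9)
        assert t2.upper == pytest.approx(3.0 * t1.upper, rel=1e-9)


class TestNonparametricTI:
    def test_coverage_guarantee(self, rng):
        hits = 0
        reps = 500
        for _ in range(reps):
            x = rng.exponential(1.0, size=200)
            ti = cc.nonparametric_tolerance_interval(x, 0.90, 0.90)
            cover = stats.expon.cdf(ti.upper) - stats.expon.cdf(ti.lower)
            hits += cover >= 0.90
        se = math.sqrt(0.9 * 0.1 / reps)
        assert hits / reps >= 0.90 - 3 * se

    def test_small_n_range_warning(self, rng):
        with pytest.warns(cc.CalibrationWarning, match="too small"):
            ti = cc.nonparametric_tolerance_interval(rng.normal(0, 1, 10))
        assert ti.method == "nonparametric"

    def test_auto_switches_on_skew(self, rng):
        x = rng.lognormal(0.0, 1.5, size=500)
        ti = cc.tolerance_interval(x, method="auto")
        assert ti.method == "nonparametric"

    def test_auto_keeps_normal_on_gaussian(self, rng):
        x = rng.normal(0.0, 1.0, size=500)
        ti = cc.tolerance_interval(x, method="auto")
        assert ti.method == "normal"


class TestDeriveCutoffs:
    def test_plugin_k_factor_geometry(self, rng):
        veh = rng.normal(0.0, 10.0, 200)
        pos = rng.normal(80.0, 15.0, 200)
        z = cc.derive_cutoffs_for_parameter(
            "wmfr_hz", veh, pos, ti_method="normal"
        )
        k_v = cc.howe_k_factor(200, 0.95, 0.95)
        assert z.mild_up_edge == pytest.approx(
            veh.mean() + k_v * veh.std(ddof=1), rel=1e-9
        )
        assert z.mild_down_edge == pytest.approx(
            veh.mean() - k_v * veh.std(ddof=1), rel=1e-9
        )
        k_p = cc.howe_k_factor(200, 0.95, 0.95)
        assert z.strong_up_edge == pytest.approx(
            pos.mean() - k_p * pos.std(ddof=1), abs=1e-9
        )
        # all five zones non-empty on the up side
        assert z.mild_down_edge < z.mild_up_edge < z.strong_up_edge

    def test_identical_distributions_collapse(self, rng):
        x = rng.normal(0, 5, 100)
        with pytest.warns(cc.CalibrationWarning, match="overlap"):
            z = cc.derive_cutoffs_for_parameter(
                "aucc", x, x, ti_method="normal"
            )
        assert z.strong_up_edge == z.mild_up_edge  # mild zone empty
        assert z.strong_down_edge == z.mild_down_edge

    def test_zero_in_no_effect_zone(self, rng):
        veh = rng.normal(0.0, 10.0, 100)
        pos = rng.normal(-80.0, 10.0, 100)
        z = cc.derive_cutoffs_for_parameter("x", veh, pos, ti_method="normal")
        assert z.mild_down_edge < 0.0 < z.mild_up_edge

    def test_monotone_boundaries(self, rng):
        veh = rng.normal(0.0, 10.0, 150)
        pos = rng.normal(-70.0, 12.0, 150)
        z = cc.derive_cutoffs_for_parameter("x", veh, pos, ti_method="normal")
        assert (
            z.strong_down_edge
            < z.mild_down_edge
            < z.mild_up_edge
            < z.strong_up_edge
        )

    def test_scale_equivariance(self, rng):
        veh = rng.normal(0.0, 10.0, 80)
        pos = rng.normal(60.0, 10.0, 80)
        z1 = cc.derive_cutoffs_for_parameter("x", veh, pos, ti_method="normal")
        c = 2.5
        z2 = cc.derive_cutoffs_for_parameter(
            "x", c * veh, c * pos, ti_method="normal"
        )
        for attr in (
            "mild_down_edge",
            "mild_up_edge",
            "strong_down_edge",
            "strong_up_edge",
        ):
            assert getattr(z2, attr) == pytest.approx(
                c * getattr(z1, attr), rel=1e-9
            )

    def test_derive_cutoffs_driver(self, rng, cfg):
        veh = {"wmfr_hz": rng.normal(0, 10, 50), "aucc": rng.normal(0, 5, 50)}
        pos = {
            "wmfr_hz": rng.normal(-80, 10, 50),
            "aucc": rng.normal(-60, 5, 50),
        }
        cutoffs = cc.derive_cutoffs(veh, pos, cfg)
        assert set(cutoffs) == {"wmfr_hz", "aucc"}

    def test_round_trip_dict(self, rng, cfg):
        veh = {"wmfr_hz": rng.normal(0, 10, 50)}
        pos = {"wmfr_hz": rng.normal(-80, 10, 50)}
        cutoffs = cc.derive_cutoffs(veh, pos, cfg)
        back = cc.cutoffs_from_dict(cc.cutoffs_to_dict(cutoffs))
        assert back == cutoffs


class TestMonteCarloCalibration:
    def test_ti_coverage_n60(self, rng):
        """95/95 TI from n=60 normal draws covers >= 95% of the population
        in >= 95% - 3 SE of 2000 replications."""
        n, reps = 60, 2000
        k = cc.howe_k_factor(n, 0.95, 0.95)
        draws = rng.normal(3.0, 7.0, size=(reps, n))
        means = draws.mean(axis=1)
        sds = draws.std(axis=1, ddof=1)
        cover = stats.norm.cdf((means + k * sds - 3.0) / 7.0) - stats.norm.cdf(
            (means - k * sds - 3.0) / 7.0
        )
        frac = float(np.mean(cover >= 0.95))
        se = math.sqrt(0.95 * 0.05 / reps)
        assert frac >= 0.95 - 3 * se
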