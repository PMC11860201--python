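"""Distribution primitives: seeded sampling, analytic CDFs, truncation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mprisk import (
    ConfigurationError,
    DistributionSpec,
    ValidationError,
    cdf,
    power_law_cdf,
    power_law_normalizer,
    power_law_quantile,
    sample,
)
from mprisk.distributions import EULER_GAMMA

FAMILIES = {
    "uniform": {"low": 1.0, "high": 3.0},
    "triangular": {"min": 0.0, "mode": 0.0, "max": 79.23},
    "truncated_normal": {"mean": 16.67, "sd": 5.987, "lower_bound": 0.0},
    "minimum_extreme": {
        "mode": 0.29,
        "scale": 0.08,
        "lower_bound": 0.0,
        "upper_bound": 1.0,
    },
    "power_law": {"alpha": 1.74, "x_min": 20.0, "x_max": 5000.0},
}


class TestSpecValidation:
    def test_unknown_family_is_a_configuration_error(self):
        with pytest.raises(ConfigurationError, match="family"):
            DistributionSpec("weibull", {"shape": 1.0})

    @pytest.mark.parametrize(
        "family, params, field",
        [
            ("uniform", {"low": 3.0, "high": 1.0}, "low"),
            ("triangular", {"min": 2.0, "mode": 1.0, "max": 3.0}, "mode"),
            ("truncated_normal", {"mean": 0.0, "sd": -1.0}, "sd"),
            ("minimum_extreme", {"mode": 0.0, "scale": 0.0}, "scale"),
            ("power_law", {"alpha": 1.74, "x_min": 30.0, "x_max": 20.0}, "x_min"),
            ("power_law", {"alpha": -0.5, "x_min": 1.0, "x_max": 2.0}, "alpha"),
            ("power_law", {"alpha": 1.0, "x_min": 1.0, "x_max": 2.0}, "alpha"),
        ],
    )
    def test_invariant_violation_names_the_field(self, family, params, field):
        with pytest.raises(ValidationError, match=field):
            DistributionSpec(family, params)

    def test_missing_parameter_is_reported(self):
        with pytest.raises(ValidationError, match="high"):
            DistributionSpec("uniform", {"low": 0.0})


class TestSampling:
    @pytest.mark.parametrize("family", sorted(FAMILIES))
    def test_same_seed_gives_identical_draws(self, family):
        spec = DistributionSpec(family, FAMILIES[family])
        a = sample(spec, 1000, seed=7)
        b = sample(spec, 1000, seed=7)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, sample(spec, 1000, seed=8))

    @pytest.mark.parametrize("family", sorted(FAMILIES))
    def test_empirical_cdf_matches_analytic(self, family):
        """KS distance of 1e5 seeded draws against the analytic CDF < 0.01."""
        spec = DistributionSpec(family, FAMILIES[family])
        x = sample(spec, 100_000, seed=42)
        stat = stats.kstest(x, lambda v: cdf(spec, v)).statistic
        assert stat < 0.01

    def test_triangular_mean_matches_analytic(self):
        # mean of triangular(a, c, b) is (a + b + c) / 3 = 26.41 here
        spec = DistributionSpec("triangular", {"min": 0, "mode": 0, "max": 79.23})
        x = sample(spec, 400_000, seed=1)
        assert x.mean() == pytest.approx(26.41, abs=0.15)

    def test_degenerate_triangular_support(self):
        spec = DistributionSpec("triangular", {"min": 1.0, "mode": 1.0, "max": 1.0})
        assert np.all(sample(spec, 50, seed=0) == 1.0)

    def test_minimum_extreme_mean_is_mode_minus_gamma_scale(self):
        spec = DistributionSpec("minimum_extreme", {"mode": 0.29, "scale": 0.08})
        x = sample(spec, 400_000, seed=2)
        assert x.mean() == pytest.approx(0.29 - EULER_GAMMA * 0.08, abs=5e-4)
        assert 0.29 - EULER_GAMMA * 0.08 == pytest.approx(0.24382, abs=1e-5)

    def test_truncated_normal_far_bound_barely_perturbs_mean(self):
        # truncation 5 sd below the mean removes negligible mass
        spec = DistributionSpec(
            "truncated_normal", {"mean": 70.0, "sd": 14.0, "lower_bound": 0.0}
        )
        x = sample(spec, 200_000, seed=3)
        assert np.all(x >= 0)
        assert x.mean() == pytest.approx(70.0, rel=1e-3)

    def test_truncated_normal_agrees_with_rejection_oracle(self, rng):
        """Our resampling draws match a brute-force rejection oracle."""
        spec = DistributionSpec(
            "truncated_normal", {"mean": 16.67, "sd": 5.987, "lower_bound": 0.0}
        )
        ours = sample(spec, 10_000, seed=11)
        raw = rng.normal(16.67, 5.987, 40_000)
        oracle = raw[raw >= 0][:10_000]
        assert stats.ks_2samp(ours, oracle).pvalue > 0.01

    @pytest.mark.parametrize(
        "family",
        ["truncated_normal", "minimum_extreme", "power_law"],
    )
    def test_truncated_families_respect_bounds(self, family):
        spec = DistributionSpec(family, FAMILIES[family])
        x = sample(spec, 50_000, seed=5)
        p = FAMILIES[family]
        lo = p.get("lower_bound", p.get("x_min", -np.inf))
        hi = p.get("upper_bound", p.get("x_max", np.inf))
        assert np.all(x >= lo) and np.all(x <= hi)

    def test_impossible_truncation_raises(self):
        spec = DistributionSpec(
            "truncated_normal",
            {"mean": 0.0, "sd": 1.0, "lower_bound": 40.0},
        )
        with pytest.raises(ValidationError, match="mass"):
            sample(spec, 10, seed=0)

    def test_n_below_one_rejected(self):
        with pytest.raises(ValidationError, match="n"):
            sample(DistributionSpec("point", {"value": 1.0}), 0)


class TestPowerLaw:
    A, LO, HI = 1.74, 20.0, 5000.0

    def test_quantile_endpoints(self):
        assert power_law_quantile(0.0, self.A, self.LO, self.HI) == pytest.approx(20.0)
        assert power_law_quantile(1.0, self.A, self.LO, self.HI) == pytest.approx(5000.0)

    def test_median_matches_quadrature_oracle(self):
        # frozen from bisection on the quadrature CDF of b*x^-alpha
        assert power_law_quantile(0.5, self.A, self.LO, self.HI) == pytest.approx(
            49.8936, abs=1e-3
        )

    def test_quantile_cdf_identity(self):
        u = np.linspace(0.0, 1.0, 2001)
        x = power_law_quantile(u, self.A, self.LO, self.HI)
        np.testing.assert_allclose(
            power_law_cdf(x, self.A, self.LO, self.HI), u, rtol=1e-9, atol=1e-9
        )

    def test_quantile_strictly_increasing(self):
        u = np.linspace(0.0, 1.0, 513)
        x = power_law_quantile(u, self.A, self.LO, self.HI)
        assert np.all(np.diff(x) > 0)

    def test_quantile_domain_error(self):
        with pytest.raises(ValidationError, match="u"):
            power_law_quantile(1.5, self.A, self.LO, self.HI)
        with pytest.raises(ValidationError, match="u"):
            power_law_quantile(-0.1, self.A, self.LO, self.HI)

    def test_sampler_agrees_with_rejection_oracle(self, rng):
        """Inverse-CDF sampling vs accept/reject under a uniform envelope."""
        spec = DistributionSpec(
            "power_law", {"alpha": self.A, "x_min": self.LO, "x_max": self.HI}
        )
        ours = sample(spec, 10_000, seed=21)
        accepted = []
        while sum(len(a) for a in accepted) < 10_000:
            prop = rng.uniform(self.LO, self.HI, 500_000)
            keep = rng.uniform(size=prop.size) < (prop / self.LO) ** -self.A
            accepted.append(prop[keep])
        oracle = np.concatenate(accepted)[:10_000]
        assert stats.ks_2samp(ours, oracle).pvalue > 0.01

    @pytest.mark.parametrize(
        "alpha, x_min, expected",
        [(2.0, 1.0, 1.0), (2.0, 20.0, 20.0), (1.74, 20.0, 0.74 * 20.0**0.74)],
    )
    def test_normalizer_values(self, alpha, x_min, expected):
        assert power_law_normalizer(alpha, x_min) == pytest.approx(expected)

    def test_normalizer_yields_unit_integral(self):
        from scipy.integrate import quad

        b = power_law_normalizer(1.74, 20.0)
        integral = quad(lambda x: b * x**-1.74, 20.0, np.inf)[0]
        assert integral == pytest.approx(1.0, rel=1e-6)

    def test_normalizer_rejects_alpha_at_or_below_one(self):
        with pytest.raises(ValidationError, match="alpha"):
            power_law_normalizer(1.0, 20.0)
        with pytest.raises(ValidationError, match="alpha"):
            power_law_normalizer(0.99, 20.0)


@settings(derandomize=True, max_examples=50)
@given(
    alpha=st.floats(0.2, 4.0).filter(lambda a: abs(a - 1.0) > 1e-3),
    u=st.floats(0.0, 1.0),
)
def test_quantile_stays_in_support(alpha, u):
    x = power_law_quantile(u, alpha, 20.0, 5000.0)
    assert 20.0 <= x <= 5000.0 + 1e-9
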