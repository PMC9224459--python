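"""Derived kinetic quantities: t1/2, D, z, t_R, z', log-logistic b(T)."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from thermokin.exceptions import DomainError, InputError
from thermokin.kinetics import (
    d_value,
    fit_log_logistic,
    first_order_summary,
    half_life,
    log_logistic,
    reliable_life,
    weibull_summary,
    z_prime,
    z_value,
)
from thermokin.models import evaluate_model

TEMPS = [40.0, 50.0, 60.0, 70.0]


class TestPerTemperature:
    def test_half_life_identity(self):
        assert half_life(np.log(2)) == pytest.approx(1.0)

    @pytest.mark.parametrize("k, expected", [(0.0136, 50.97), (0.0289, 23.98)])
    def test_half_life_published_rates(self, k, expected):
        assert half_life(k) == pytest.approx(expected, abs=5e-3)

    def test_d_value_identity(self):
        assert d_value(2.303) == pytest.approx(1.0)

    @pytest.mark.parametrize("k, expected", [(0.0136, 169.3), (0.0440, 52.3)])
    def test_d_value_published_rates(self, k, expected):
        assert d_value(k) == pytest.approx(expected, abs=0.05)

    def test_reliable_life_identity(self):
        assert reliable_life(2.303, 1.0) == pytest.approx(1.0)

    def test_reliable_life_matches_direct_formula(self):
        b, n = 9.37e-5, 2.981
        assert reliable_life(b, n) == pytest.approx((2.303 / b) ** (1 / n), rel=1e-15)

    @given(b=st.floats(1e-8, 1e-2), n=st.floats(0.5, 6.0))
    def test_activity_at_reliable_life_is_ten_percent(self, b, n):
        t_r = reliable_life(b, n)
        assert evaluate_model("weibull", {"b": b, "n": n}, t_r) == pytest.approx(
            np.exp(-2.303), rel=1e-12
        )

    @pytest.mark.parametrize("func", [half_life, d_value])
    def test_rate_domain_errors(self, func):
        with pytest.raises(DomainError):
            func(0.0)
        with pytest.raises(DomainError):
            func(-0.1)


class TestZValues:
    def test_tenfold_per_ten_degrees(self):
        d = [1000.0, 100.0, 10.0, 1.0]
        assert z_value(TEMPS, d) == pytest.approx(10.0)

    def test_constructed_slope(self):
        d = [10 ** (3 - t / 25) for t in TEMPS]
        assert z_value(TEMPS, d) == pytest.approx(25.0)

    def test_scale_invariance(self):
        d = [169.0, 117.0, 80.0, 52.0]
        assert z_value(TEMPS, [7.3 * x for x in d]) == pytest.approx(
            z_value(TEMPS, d), rel=1e-12
        )

    def test_z_same_from_d_and_half_life(self):
        ks = [0.0136, 0.0197, 0.0289, 0.0440]
        assert z_value(TEMPS, [d_value(k) for k in ks]) == pytest.approx(
            z_value(TEMPS, [half_life(k) for k in ks]), rel=1e-12
        )

    def test_z_prime_bases(self):
        t_r = [41.97, 31.57, 29.70, 20.07]
        assert z_prime(TEMPS, t_r, "ln") == pytest.approx(43.9, abs=0.2)
        assert z_prime(TEMPS, t_r, "log10") == pytest.approx(101.0, abs=1.0)
        # definitional case: tenfold drop per 10 degC
        assert z_prime(TEMPS, [1000.0, 100.0, 10.0, 1.0], "log10") == pytest.approx(10.0)

    def test_input_validation(self):
        with pytest.raises(InputError):
            z_value([40.0], [100.0])
        with pytest.raises(DomainError):
            z_value(TEMPS, [100.0, -1.0, 10.0, 1.0])
        with pytest.raises(InputError):
            z_prime(TEMPS, [1.0] * 4, "log2")


class TestLogLogistic:
    def test_value_at_critical_temperature(self):
        assert log_logistic(100.0, 0.25, 100.0) == pytest.approx(np.log(2.0))

    def test_exact_recovery_from_noiseless_curve(self):
        k_prime, t_c = 0.25, 100.0
        b = log_logistic(np.array(TEMPS), k_prime, t_c)
        fit = fit_log_logistic(TEMPS, b)
        assert fit.converged
        assert fit.k_prime == pytest.approx(k_prime, rel=1e-6)
        assert fit.T_c == pytest.approx(t_c, rel=1e-6)

    def test_published_weibull_scales(self):
        b = [1.97e-7, 1.54e-5, 9.37e-5, 4.22e-4]
        fit = fit_log_logistic(TEMPS, b)
        assert fit.converged
        assert fit.k_prime == pytest.approx(0.2483, rel=0.01)
        assert fit.T_c == pytest.approx(98.89, rel=0.01)
        assert fit.r2 == pytest.approx(0.93, abs=0.01)

    def test_decreasing_b_flagged_not_raised(self):
        fit = fit_log_logistic(TEMPS, [1e-3, 1e-4, 1e-5, 1e-6])
        assert not fit.converged


class TestSummaries:
    def test_first_order_summary(self):
        ks = [0.0136, 0.0197, 0.0289, 0.0440]
        summary = first_order_summary(TEMPS, ks)
        assert summary.model_id == "first_order"
        assert len(summary.records) == 4
        rec40 = summary.records[0]
        assert rec40.t_half == pytest.approx(50.97, abs=5e-3)
        assert rec40.d == pytest.approx(169.3, abs=0.05)
        # D/t_half is the fixed ratio 2.303/ln2 for every first-order record
        for rec in summary.records:
            assert rec.d / rec.t_half == pytest.approx(2.303 / np.log(2), rel=1e-12)
        assert summary.z == pytest.approx(58.8, rel=0.005)

    def test_first_order_quantities_decrease_with_temperature(self):
        summary = first_order_summary(TEMPS, [0.0136, 0.0197, 0.0289, 0.0440])
        t_halves = [r.t_half for r in summary.records]
        ds = [r.d for r in summary.records]
        assert all(a > b > 0 for a, b in zip(t_halves, t_halves[1:]))
        assert all(a > b > 0 for a, b in zip(ds, ds[1:]))

    def test_weibull_summary(self):
        bs = [1.97e-7, 1.54e-5, 9.37e-5, 4.22e-4]
        ns = [4.357, 3.461, 2.981, 2.869]
        summary = weibull_summary(TEMPS, bs, ns, z_prime_base="ln")
        assert summary.model_id == "weibull"
        t_rs = [r.t_r for r in summary.records]
        alphas = [r.alpha for r in summary.records]
        assert all(a > b > 0 for a, b in zip(t_rs, t_rs[1:]))
        assert all(a > b > 0 for a, b in zip(alphas, alphas[1:]))
        assert summary.z_prime_base == "ln"
        assert summary.z_prime == pytest.approx(44.3, abs=0.1)
        assert summary.log_logistic.converged
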