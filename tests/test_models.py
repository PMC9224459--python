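"""Closed-form model bank: catalogue, evaluation, reductions, conversions."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from thermokin.exceptions import (
    ConfigurationError,
    DomainError,
    SingularParameterizationError,
)
from thermokin.models import (
    MODEL_IDS,
    alpha_to_weibull_scale,
    evaluate_model,
    get_model_spec,
    model_catalog,
    weibull_to_alpha,
)

T_GRID = np.linspace(0.0, 240.0, 25)


class TestCatalog:
    def test_eight_models_in_equation_order(self):
        catalog = model_catalog()
        assert len(catalog) == 8
        assert [s.model_id for s in catalog] == list(MODEL_IDS)
        assert catalog[0].model_id == "first_order"
        assert catalog[1].model_id == "weibull"
        assert catalog[1].n_params == 2

    def test_n_params_matches_param_names(self):
        for spec in model_catalog():
            assert spec.n_params == len(spec.param_names)
            assert set(spec.param_bounds) == set(spec.param_names)

    def test_unknown_model_id_rejected(self):
        with pytest.raises(ConfigurationError):
            get_model_spec("zeroth_order")
        with pytest.raises(ConfigurationError):
            evaluate_model("zeroth_order", {"k": 0.1}, 1.0)


class TestEvaluate:
    @pytest.mark.parametrize(
        "model_id, params, t, expected, tol",
        [
            # half-life consistency of the published first-order rate at 40 degC
            ("first_order", {"k": 0.0136}, 50.97, 0.500, 5e-4),
            # reliable-life consistency of the published Weibull pair at 70 degC
            ("weibull", {"b": 4.22e-4, "n": 2.869}, 20.07, 0.100, 1e-3),
        ],
    )
    def test_published_consistency_points(self, model_id, params, t, expected, tol):
        assert evaluate_model(model_id, params, t) == pytest.approx(expected, abs=tol)

    def test_normalisation_at_t0(self, reference_params):
        for model_id, params in reference_params.items():
            assert evaluate_model(model_id, params, 0.0) == pytest.approx(1.0, abs=1e-12)

    def test_series_general_form_offset_at_t0(self):
        params = {"alpha_1": 0.4, "k_1": 0.05, "k_2": 0.005, "alpha_2": 0.1}
        assert evaluate_model("series_type", params, 0.0) == pytest.approx(1.1, abs=1e-12)

    def test_vectorises_over_time(self, reference_params):
        for model_id, params in reference_params.items():
            out = evaluate_model(model_id, params, T_GRID)
            assert out.shape == T_GRID.shape
            assert np.all(np.isfinite(out))

    @pytest.mark.parametrize(
        "model_id, params",
        [
            ("weibull", {"b": 0.02, "n": 1.0}),
            ("two_fraction", {"a": 1.0, "k_L": 0.02, "k_R": 0.31}),
            ("fractional_conversion", {"A_r": 0.0, "k": 0.02}),
            ("multicomponent", {"k_1": 0.02, "k_2": 0.47, "r": 0.0}),
            ("distinct_isoenzymes", {"A_L": 1.0, "A_S": 0.0, "k_L": 0.02, "k_R": 0.3}),
        ],
    )
    def test_reduction_cases_equal_first_order(self, model_id, params):
        expected = evaluate_model("first_order", {"k": 0.02}, T_GRID)
        np.testing.assert_allclose(
            evaluate_model(model_id, params, T_GRID), expected, atol=1e-12
        )

    def test_nth_order_limits_to_first_order(self):
        k = 0.0136
        expected = np.exp(-k * T_GRID)
        for n in (1.0 - 1e-6, 1.0 + 1e-6):
            out = evaluate_model("nth_order", {"k": k, "n": n}, T_GRID)
            np.testing.assert_allclose(out, expected, atol=1e-4)

    @pytest.mark.parametrize(
        "model_id, params",
        [("first_order", {"k": 0.02}), ("weibull", {"b": 9.37e-5, "n": 2.981})],
    )
    def test_strictly_decreasing_in_time(self, model_id, params):
        grid = np.linspace(0.0, 240.0, 200)
        out = evaluate_model(model_id, params, grid)
        # strict decrease wherever the value is still representable as > 0
        positive = out > 1e-300
        assert np.all(np.diff(out[positive]) < 0)

    def test_series_equal_rates_singular(self):
        with pytest.raises(SingularParameterizationError):
            evaluate_model("series_type", {"alpha_1": 0.4, "k_1": 0.02, "k_2": 0.02}, 1.0)

    def test_nth_order_nonpositive_base_rejected(self):
        # n < 1 makes the base hit zero at finite time
        with pytest.raises(DomainError):
            evaluate_model("nth_order", {"k": 0.1, "n": 0.5}, 100.0)
        with pytest.raises(DomainError):
            evaluate_model("nth_order", {"k": 0.1, "n": 1.0}, 10.0)

    def test_missing_parameter_rejected(self):
        with pytest.raises(ConfigurationError):
            evaluate_model("weibull", {"b": 1e-4}, 10.0)

    def test_negative_time_rejected(self):
        with pytest.raises(DomainError):
            evaluate_model("first_order", {"k": 0.02}, -1.0)


class TestWeibullAlpha:
    @pytest.mark.parametrize(
        "b, n, expected",
        [
            (1.97e-7, 4.357, 34.6),
            (4.22e-4, 2.869, 15.0),
            (1.0, 3.0, 1.0),
        ],
    )
    def test_alpha_values(self, b, n, expected):
        assert weibull_to_alpha(b, n) == pytest.approx(expected, rel=2e-3)

    @given(
        b=st.floats(1e-9, 1e-1), n=st.floats(0.3, 6.0),
    )
    def test_round_trip(self, b, n):
        alpha = weibull_to_alpha(b, n)
        assert alpha_to_weibull_scale(alpha, n) == pytest.approx(b, rel=1e-12)

    @pytest.mark.parametrize("b, n", [(0.0, 2.0), (-1e-4, 2.0), (1e-4, 0.0)])
    def test_domain_errors(self, b, n):
        with pytest.raises(DomainError):
            weibull_to_alpha(b, n)
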