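"""Model-selection screen on constructed fit sets.

Each rejection rule is exercised with hand-built FitResult sets so the
verdicts are independent of the optimizer.
"""

import pytest

from thermokin.exceptions import InputError
from thermokin.fitting import FitResult, SelectionVerdict, select_model

TEMPS = (40.0, 50.0, 60.0, 70.0)


def make_fit(
    model_id,
    temperature,
    estimates,
    *,
    standard_errors=None,
    r2=0.99,
    chi2=1e-3,
    sem=1e-3,
    converged=True,
    m=39,
):
    p = len(estimates)
    if standard_errors is None:
        standard_errors = {k: 0.01 for k in estimates}
    return FitResult(
        model_id, temperature, estimates, standard_errors,
        r2, chi2, sem, converged, None, m, p, chi2 * (m - p),
    )


def first_order_fits(chi2=1e-3, r2=0.99):
    ks = {40.0: 0.0136, 50.0: 0.0197, 60.0: 0.0289, 70.0: 0.0440}
    return [
        make_fit("first_order", t, {"k": ks[t]}, chi2=chi2, r2=r2) for t in TEMPS
    ]


def verdict_of(verdicts, model_id):
    return next(v for v in verdicts if v.model_id == model_id)


class TestRejectionReasons:
    def test_equal_rate_constants(self):
        fits = {
            "first_order": first_order_fits(),
            "distinct_isoenzymes": [
                make_fit(
                    "distinct_isoenzymes", t,
                    {"A_L": 0.5, "A_S": 0.5, "k_L": 0.02, "k_R": 0.02},
                    chi2=5e-4,
                )
                for t in TEMPS
            ],
        }
        v = verdict_of(select_model(fits), "distinct_isoenzymes")
        assert v.status == "rejected"
        assert v.reason == "equal_rate_constants"

    def test_negative_fraction(self):
        fits = {
            "first_order": first_order_fits(),
            "two_fraction": [
                make_fit("two_fraction", t, {"a": -0.2, "k_L": 0.05, "k_R": 0.01})
                for t in TEMPS
            ],
        }
        v = verdict_of(select_model(fits), "two_fraction")
        assert (v.status, v.reason) == ("rejected", "negative_params")

    def test_fraction_above_one_is_negative_complement(self):
        fits = {
            "first_order": first_order_fits(),
            "two_fraction": [
                make_fit("two_fraction", t, {"a": 1.3, "k_L": 0.05, "k_R": 0.01})
                for t in TEMPS
            ],
        }
        v = verdict_of(select_model(fits), "two_fraction")
        assert (v.status, v.reason) == ("rejected", "negative_params")

    def test_no_convergence_at_any_temperature(self):
        bad = [
            make_fit("nth_order", t, {"k": 0.02, "n": 1.2}) for t in TEMPS[:-1]
        ] + [make_fit("nth_order", 70.0, {}, converged=False)]
        fits = {"first_order": first_order_fits(), "nth_order": bad}
        v = verdict_of(select_model(fits), "nth_order")
        assert (v.status, v.reason) == ("rejected", "no_convergence")

    def test_weibull_shape_within_se_of_one(self):
        fits = {
            "first_order": first_order_fits(chi2=1e-3),
            "weibull": [
                make_fit(
                    "weibull", t, {"b": 0.015, "n": 1.02},
                    standard_errors={"b": 1e-3, "n": 0.05},
                    chi2=1e-3,
                )
                for t in TEMPS
            ],
        }
        verdicts = select_model(fits)
        v = verdict_of(verdicts, "weibull")
        assert (v.status, v.reason) == ("rejected", "reduces_to_first_order")
        assert verdict_of(verdicts, "first_order").status == "accepted"


class TestAcceptance:
    def test_sole_survivor_accepted(self):
        fits = {
            "first_order": first_order_fits(r2=0.7, chi2=0.05),
            "weibull": [make_fit("weibull", t, {}, converged=False) for t in TEMPS],
        }
        verdicts = select_model(fits)
        assert verdict_of(verdicts, "first_order").reason == "best_statistics"
        assert sum(v.status == "accepted" for v in verdicts) == 1

    def test_clear_statistical_winner(self):
        # weibull chi2 ~40x smaller: no tie, weibull accepted outright
        fits = {
            "first_order": first_order_fits(chi2=0.045, r2=0.75),
            "weibull": [
                make_fit(
                    "weibull", t, {"b": 1e-5 * (i + 1) ** 3, "n": 3.0},
                    standard_errors={"b": 1e-6, "n": 0.05},
                    chi2=1.2e-3, r2=0.99,
                )
                for i, t in enumerate(TEMPS)
            ],
        }
        verdicts = select_model(fits)
        assert verdict_of(verdicts, "weibull").status == "accepted"
        assert verdict_of(verdicts, "first_order").reason == "low_r2_high_error"

    def test_tie_broken_by_temperature_dependence_fit(self):
        # statistically indistinguishable fits; the first-order rates follow
        # the Arrhenius law essentially exactly while the Weibull scale is
        # erratic in temperature, so first_order wins the secondary fit
        fits = {
            "first_order": first_order_fits(chi2=1.00e-3),
            "weibull": [
                make_fit(
                    "weibull", t, {"b": b, "n": 2.5},
                    standard_errors={"b": 1e-6, "n": 0.02},
                    chi2=0.95e-3,
                )
                for t, b in zip(TEMPS, (1e-4, 5e-5, 2e-4, 8e-5))
            ],
        }
        verdicts = select_model(fits)
        assert verdict_of(verdicts, "first_order").status == "accepted"

    def test_single_temperature_tie_prefers_parsimony(self):
        fits = {
            "first_order": [make_fit("first_order", 40.0, {"k": 0.0136}, chi2=1.0e-3)],
            "fractional_conversion": [
                make_fit(
                    "fractional_conversion", 40.0, {"A_r": 0.01, "k": 0.014},
                    chi2=0.98e-3,
                )
            ],
        }
        verdicts = select_model(fits)
        assert verdict_of(verdicts, "first_order").status == "accepted"

    def test_all_rejected_yields_no_acceptance(self):
        fits = {
            "nth_order": [make_fit("nth_order", t, {}, converged=False) for t in TEMPS],
            "series_type": [make_fit("series_type", t, {}, converged=False) for t in TEMPS],
        }
        verdicts = select_model(fits)
        assert all(v.status == "rejected" for v in verdicts)
        assert {v.reason for v in verdicts} == {"no_convergence"}

    def test_empty_fit_set_rejected(self):
        with pytest.raises(InputError):
            select_model({})

    def test_reason_vocabulary(self):
        assert set(SelectionVerdict.REASONS) == {
            "negative_params", "equal_rate_constants", "no_convergence",
            "reduces_to_first_order", "low_r2_high_error", "best_statistics",
        }
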