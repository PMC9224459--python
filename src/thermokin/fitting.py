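"""Nonlinear least-squares estimation and model selection.

Each candidate model is fitted to each temperature's residual-activity curve
by unconstrained Levenberg–Marquardt least squares with multi-start
initialisation. Goodness of fit is summarised by r^2, the reduced chi-square

    chi2 = SS_res / (m - p)

and the mean squared error

    SEM = SS_res / m

where m is the number of observations and p the number of parameters
(so chi2 * (m - p) == SEM * m identically).

Model selection follows a physical-then-statistical screen:

1. a model is rejected outright if any temperature's fit failed to converge
   (or produced a singular parameter covariance — "did not generate
   parameter answers");
2. rejected if any estimated parameter is negative (rates, fractions,
   amplitudes, shapes and scales are all physically nonnegative; a
   two-fraction labile fraction a > 1 is equivalent to a negative stable
   fraction and is rejected on the same ground);
3. the distinct-isoenzymes model is rejected when its two rate constants
   coincide (within 1% relative) at every temperature — it has then
   degenerated to first order;
4. the Weibull model is flagged as reducing to first order when its shape
   factor n lies within one standard error of 1 at every temperature;
5. survivors are ranked by reduced chi-square (the only statistic of the
   three that accounts for parameter count), ties by SEM then r^2;
6. survivors whose chi-square is statistically indistinguishable from the
   best (within 25% relative) form a tie group, resolved by the r^2 of the
   secondary temperature-dependence regression — Arrhenius for rate-type
   models, log-logistic for the Weibull scale b — and, failing that (single
   temperature, or secondary r^2 within 0.005), by parsimony.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .exceptions import (
    DegreesOfFreedomError,
    DomainError,
    InputError,
    SingularParameterizationError,
)
from .models import ModelSpec, evaluate_model, get_model_spec, model_catalog

__all__ = [
    "ActivityCurve",
    "FitResult",
    "SelectionVerdict",
    "goodness_of_fit",
    "fit_model",
    "fit_all_models",
    "select_model",
]

#: relative tolerance under which k_L and k_R are considered equal (rule 3)
EQUAL_RATE_TOL = 0.01
#: relative chi-square band defining "statistically indistinguishable" (rule 6)
TIE_REL_CHI2 = 0.25
#: minimum secondary-regression r^2 margin needed to decide a tie
SECONDARY_R2_TOL = 0.005

_PENALTY = 1e3  # residual magnitude assigned outside a model's domain


@dataclass
class ActivityCurve:
    """Observed residual-activity fractions versus time at one temperature.

    ``replicates`` carries one integer id per observation; replicate
    observations enter the fit individually (no averaging) unless the
    fitting routine is asked otherwise.
    """

    temperature: float  # degC
    times: np.ndarray  # min
    activities: np.ndarray  # fraction of unheated activity
    replicates: np.ndarray | None = None
    label: str | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.activities = np.asarray(self.activities, dtype=float)
        if self.times.shape != self.activities.shape or self.times.ndim != 1:
            raise InputError("times and activities must be 1-D arrays of equal length")
        if self.replicates is None:
            self.replicates = np.zeros(self.times.shape, dtype=int)
        else:
            self.replicates = np.asarray(self.replicates, dtype=int)
            if self.replicates.shape != self.times.shape:
                raise InputError("replicates must match times in length")
        if not np.all(np.isfinite(self.activities)):
            raise InputError(
                f"non-finite activity in curve at {self.temperature} degC"
            )
        if not np.all(np.isfinite(self.times)) or np.any(self.times < 0):
            raise InputError("times must be finite and nonnegative")

    @property
    def n_obs(self) -> int:
        return self.times.size

    def replicate_means(self) -> tuple[np.ndarray, np.ndarray]:
        """Unique times and the mean activity across replicates at each."""
        t_unique = np.unique(self.times)
        y_mean = np.array(
            [self.activities[self.times == t].mean() for t in t_unique]
        )
        return t_unique, y_mean


@dataclass
class FitResult:
    """Least-squares estimates of one model on one temperature's curve."""

    model_id: str
    temperature: float
    estimates: dict[str, float]
    standard_errors: dict[str, float]
    r2: float
    chi2: float
    sem: float
    converged: bool
    residuals: np.ndarray | None
    m: int
    p: int
    ss_res: float = float("nan")

    def predict(self, t):
        return evaluate_model(self.model_id, self.estimates, t)


@dataclass
class SelectionVerdict:
    """Accept/reject outcome for one model across all temperatures."""

    model_id: str
    status: str  # "accepted" | "rejected"
    reason: str  # see REASONS
    criteria: dict[str, tuple[float, float] | None] = field(default_factory=dict)

    REASONS = (
        "negative_params",
        "equal_rate_constants",
        "no_convergence",
        "reduces_to_first_order",
        "low_r2_high_error",
        "best_statistics",
    )


# ---------------------------------------------------------------------------
# goodness of fit
# ---------------------------------------------------------------------------

def goodness_of_fit(y_exp, y_pred, p: int) -> tuple[float, float, float]:
    """Return (r2, chi2, SEM) for observations ``y_exp`` vs ``y_pred``.

    chi2 = SS_res/(m-p), SEM = SS_res/m, r2 = 1 - SS_res/SS_tot with SS_tot
    taken about the mean of ``y_exp``.
    """
    y_exp = np.asarray(y_exp, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_exp.shape != y_pred.shape:
        raise InputError("y_exp and y_pred must have the same length")
    m = y_exp.size
    if m <= p:
        raise DegreesOfFreedomError(
            f"need more observations ({m}) than parameters ({p})"
        )
    ss_res = float(np.sum((y_exp - y_pred) ** 2))
    ss_tot = float(np.sum((y_exp - y_exp.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res == 0.0 else -float("inf")
    else:
        r2 = 1.0 - ss_res / ss_tot
    return r2, ss_res / (m - p), ss_res / m


# ---------------------------------------------------------------------------
# initial values
# ---------------------------------------------------------------------------

def _loglinear_rate(t, y, fallback=0.01):
    """First-order rate from the log-linear regression of ln(A) on t."""
    mask = y > 1e-3
    if mask.sum() < 2 or np.ptp(t[mask]) == 0:
        return fallback
    slope = np.polyfit(t[mask], np.log(y[mask]), 1)[0]
    return float(np.clip(-slope, 1e-5, 10.0))


def _weibull_init(t, y):
    """(b, n) from the log-log regression of ln(-ln A) on ln t."""
    mask = (t > 0) & (y > 1e-6) & (y < 1.0 - 1e-9)
    if mask.sum() < 2 or np.ptp(np.log(t[mask])) == 0:
        return 1e-3, 1.0
    n, ln_b = np.polyfit(np.log(t[mask]), np.log(-np.log(y[mask])), 1)
    return float(np.exp(ln_b)), float(np.clip(n, 0.05, 12.0))


def _base_guess(spec: ModelSpec, t, y) -> dict[str, float]:
    k0 = _loglinear_rate(t, y)
    positive_t = t[t > 0]
    t_mid = float(np.median(positive_t)) if positive_t.size else 1.0
    early, late = t <= t_mid, t > t_mid
    k_fast = _loglinear_rate(t[early], y[early], 2 * k0) if early.sum() >= 2 else 2 * k0
    k_slow = _loglinear_rate(t[late], y[late], 0.5 * k0) if late.sum() >= 2 else 0.5 * k0
    # a split producing near-equal rates gives a degenerate two-phase start
    if abs(k_fast - k_slow) < 0.2 * max(k_fast, k_slow):
        k_fast, k_slow = 2.0 * k0, 0.5 * k0
    b0, n0 = _weibull_init(t, y)
    guesses = {
        "first_order": {"k": k0},
        "weibull": {"b": b0, "n": n0},
        "distinct_isoenzymes": {"A_L": 0.5, "A_S": 0.5, "k_L": k_fast, "k_R": k_slow},
        "two_fraction": {"a": 0.5, "k_L": k_fast, "k_R": k_slow},
        "multicomponent": {"k_1": k_fast, "k_2": k_slow, "r": 1.0},
        "series_type": {"alpha_1": 0.5, "k_1": k_fast, "k_2": k_slow},
        "nth_order": {"k": k0, "n": 1.1},
        "fractional_conversion": {
            "A_r": float(np.clip(np.min(y), 0.0, 0.5)),
            "k": k0,
        },
    }
    return guesses[spec.model_id]


_FRACTION_LIKE = {"a", "alpha_1", "A_L", "A_S", "A_r"}


def _jitter(spec: ModelSpec, guess: dict[str, float], rng) -> dict[str, float]:
    out = {}
    for name, v in guess.items():
        lo, hi = spec.param_bounds.get(name, (1e-6, 10.0))
        if name in _FRACTION_LIKE:
            out[name] = float(np.clip(v + rng.normal(0.0, 0.15), 0.01, max(hi, 1.0) - 0.01))
        else:
            out[name] = float(np.clip(v * np.exp(rng.normal(0.0, 0.35)), lo, hi))
    return out


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _safe_predict(spec, params, t):
    try:
        with np.errstate(all="ignore"):
            pred = evaluate_model(spec, params, t)
    except (DomainError, SingularParameterizationError, OverflowError):
        return None
    pred = np.asarray(pred, dtype=float)
    if not np.all(np.isfinite(pred)):
        return None
    return pred


def fit_model(
    curve: ActivityCurve,
    spec: ModelSpec | str,
    *,
    n_starts: int = 10,
    fit_replicate_means: bool = False,
    seed: int = 1234,
) -> FitResult:
    """Fit one model to one curve; never raises on optimizer failure.

    Estimation is unconstrained Levenberg–Marquardt from ``n_starts``
    jittered initial points (first start un-jittered, jitter stream fixed by
    ``seed`` for reproducibility); the lowest residual sum of squares wins.
    ``converged`` is False when every start fails or the winning solution
    has a singular parameter covariance.
    """
    if isinstance(spec, str):
        spec = get_model_spec(spec)
    if fit_replicate_means:
        t, y = curve.replicate_means()
    else:
        t, y = curve.times, curve.activities
    m, p = t.size, spec.n_params
    if m < p + 1:
        raise DegreesOfFreedomError(
            f"curve at {curve.temperature} degC has {m} observations; "
            f"model {spec.model_id} needs at least {p + 1}"
        )

    names = spec.param_names

    def residual(x):
        pred = _safe_predict(spec, dict(zip(names, x)), t)
        if pred is None:
            return np.full(m, _PENALTY)
        return y - pred

    rng = np.random.default_rng(seed)
    guess = _base_guess(spec, t, y)
    starts = [guess] + [_jitter(spec, guess, rng) for _ in range(max(n_starts - 1, 0))]

    best_x, best_ss, best_jac = None, np.inf, None
    for start in starts:
        x0 = np.array([start[name] for name in names], dtype=float)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sol = least_squares(
                    residual, x0, method="lm",
                    xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=1200,
                )
        except Exception:
            continue
        pred = _safe_predict(spec, dict(zip(names, sol.x)), t)
        if pred is None or not np.all(np.isfinite(sol.x)):
            continue
        ss = float(np.sum((y - pred) ** 2))
        if ss < best_ss:
            best_x, best_ss, best_jac = sol.x, ss, sol.jac

    nan_se = {name: float("nan") for name in names}
    if best_x is None:
        return FitResult(
            spec.model_id, curve.temperature, {}, nan_se,
            float("nan"), float("nan"), float("nan"),
            False, None, m, p,
        )

    estimates = {name: float(v) for name, v in zip(names, best_x)}
    pred = _safe_predict(spec, estimates, t)
    residuals = y - pred
    r2, chi2, sem = goodness_of_fit(y, pred, p)

    # parameter covariance from the Jacobian at the optimum; a rank-deficient
    # J^T J means the data cannot pin down the parameters ("no answer")
    converged, ses = True, nan_se
    u, s, vt = np.linalg.svd(best_jac, full_matrices=False)
    if s.size == 0 or s[-1] <= s[0] * 1e-10:
        converged = False
    elif m > p:
        cov = (vt.T / s**2) @ vt * (best_ss / (m - p))
        diag = np.clip(np.diag(cov), 0.0, None)
        ses = {name: float(np.sqrt(d)) for name, d in zip(names, diag)}

    return FitResult(
        spec.model_id, curve.temperature, estimates, ses,
        r2, chi2, sem, converged, residuals, m, p, best_ss,
    )


def fit_all_models(
    curves: list[ActivityCurve],
    specs: list[ModelSpec] | None = None,
    **fit_kwargs,
) -> dict[str, list[FitResult]]:
    """Fit every model in ``specs`` (default: the full catalogue) to every
    curve; returns {model_id: [FitResult per curve, in input order]}."""
    if not curves:
        raise InputError("no activity curves to fit")
    if specs is None:
        specs = model_catalog()
    return {
        spec.model_id: [fit_model(c, spec, **fit_kwargs) for c in curves]
        for spec in specs
    }


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------

def _stat_ranges(fits: list[FitResult]) -> dict[str, tuple[float, float] | None]:
    out = {}
    for stat in ("r2", "chi2", "sem"):
        vals = [getattr(f, stat) for f in fits if f.converged]
        vals = [v for v in vals if np.isfinite(v)]
        out[stat] = (min(vals), max(vals)) if vals else None
    return out


def _has_negative_params(fits: list[FitResult]) -> bool:
    tol = -1e-9
    for f in fits:
        for name, v in f.estimates.items():
            if v < tol:
                return True
            if name == "a" and v > 1.0 + 1e-9:  # stable fraction 1-a negative
                return True
    return False


def _rates_equal_everywhere(fits: list[FitResult], tol: float) -> bool:
    for f in fits:
        k_l, k_r = f.estimates.get("k_L"), f.estimates.get("k_R")
        if k_l is None or k_r is None:
            return False
        scale = max(abs(k_l), abs(k_r), 1e-30)
        if abs(k_l - k_r) / scale > tol:
            return False
    return True


def _weibull_reduces_to_first_order(fits: list[FitResult]) -> bool:
    for f in fits:
        n = f.estimates.get("n")
        se = f.standard_errors.get("n", float("nan"))
        if n is None or not np.isfinite(se) or abs(n - 1.0) > se:
            return False
    return True


def _ols_r2(x, y) -> float:
    coeffs = np.polyfit(x, y, 1)
    pred = np.polyval(coeffs, x)
    ss_res = np.sum((y - pred) ** 2)
    ss_tot = np.sum((y - np.mean(y)) ** 2)
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else -np.inf


def _secondary_r2(model_id: str, fits: list[FitResult]) -> float:
    """r^2 of the temperature-dependence regression used to break ties:
    Arrhenius (ln rate vs 1/T) for rate-type models, log-logistic for the
    Weibull scale b."""
    temps = np.array([f.temperature for f in fits], dtype=float)
    if model_id == "weibull":
        from .kinetics import fit_log_logistic

        b = np.array([f.estimates.get("b", np.nan) for f in fits])
        if np.any(~np.isfinite(b)) or np.any(b <= 0):
            return -np.inf
        ll = fit_log_logistic(temps, b)
        return ll.r2 if ll.converged else -np.inf
    rate_name = get_model_spec(model_id).primary_rate
    if rate_name is None:
        return -np.inf
    rates = np.array([f.estimates.get(rate_name, np.nan) for f in fits])
    if np.any(~np.isfinite(rates)) or np.any(rates <= 0):
        return -np.inf
    return _ols_r2(1.0 / (temps + 273.15), np.log(rates))


def select_model(
    fits_by_model: dict[str, list[FitResult]],
    *,
    equal_rate_tol: float = EQUAL_RATE_TOL,
    tie_rel_chi2: float = TIE_REL_CHI2,
    secondary_r2_tol: float = SECONDARY_R2_TOL,
) -> list[SelectionVerdict]:
    """Apply the physical and statistical screen; at most one model is
    accepted (exactly one whenever any model survives the rejections)."""
    if not fits_by_model:
        raise InputError("empty fit set")

    catalog_order = [s.model_id for s in model_catalog()]
    order = [mid for mid in catalog_order if mid in fits_by_model]
    order += [mid for mid in fits_by_model if mid not in catalog_order]

    verdicts: dict[str, SelectionVerdict] = {}
    survivors: list[str] = []
    for mid in order:
        fits = fits_by_model[mid]
        ranges = _stat_ranges(fits)
        if any(not f.converged for f in fits):
            verdicts[mid] = SelectionVerdict(mid, "rejected", "no_convergence", ranges)
        elif _has_negative_params(fits):
            verdicts[mid] = SelectionVerdict(mid, "rejected", "negative_params", ranges)
        elif mid == "distinct_isoenzymes" and _rates_equal_everywhere(fits, equal_rate_tol):
            verdicts[mid] = SelectionVerdict(mid, "rejected", "equal_rate_constants", ranges)
        elif mid == "weibull" and _weibull_reduces_to_first_order(fits):
            verdicts[mid] = SelectionVerdict(mid, "rejected", "reduces_to_first_order", ranges)
        else:
            survivors.append(mid)
            verdicts[mid] = SelectionVerdict(mid, "rejected", "low_r2_high_error", ranges)

    if survivors:
        mean_chi2 = {
            mid: float(np.mean([f.chi2 for f in fits_by_model[mid]]))
            for mid in survivors
        }
        mean_sem = {
            mid: float(np.mean([f.sem for f in fits_by_model[mid]]))
            for mid in survivors
        }
        mean_r2 = {
            mid: float(np.mean([f.r2 for f in fits_by_model[mid]]))
            for mid in survivors
        }
        survivors.sort(key=lambda mid: (mean_chi2[mid], mean_sem[mid], -mean_r2[mid]))
        best = survivors[0]
        best_chi2 = mean_chi2[best]
        tie_group = [
            mid for mid in survivors
            if mean_chi2[mid] - best_chi2 <= tie_rel_chi2 * max(best_chi2, 0.0) + 1e-300
        ]
        accepted = best
        if len(tie_group) > 1:
            temps = {f.temperature for f in fits_by_model[best]}
            decided = False
            if len(temps) >= 2:
                sec = {mid: _secondary_r2(mid, fits_by_model[mid]) for mid in tie_group}
                ranked = sorted(tie_group, key=lambda mid: -sec[mid])
                if np.isfinite(sec[ranked[0]]) and (
                    sec[ranked[0]] - sec[ranked[1]] > secondary_r2_tol
                ):
                    accepted, decided = ranked[0], True
            if not decided:
                # parsimony: fewest parameters, then catalogue order
                accepted = min(
                    tie_group,
                    key=lambda mid: (
                        get_model_spec(mid).n_params
                        if mid in catalog_order else np.inf,
                        catalog_order.index(mid) if mid in catalog_order else np.inf,
                    ),
                )
        verdicts[accepted] = SelectionVerdict(
            accepted, "accepted", "best_statistics", verdicts[accepted].criteria
        )

    return [verdicts[mid] for mid in order]
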