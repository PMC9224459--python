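"""Model/Results interface tying the pipeline together.

:class:`ThermalInactivation` holds the residual-activity curves; ``fit()``
runs the whole analysis — all eight candidate models at every temperature,
the physical/statistical selection screen, and the derived-parameter branch
appropriate to the accepted model:

* first-order (or any other rate-type model): half-life, D-value, z-value,
  Arrhenius Ea and per-temperature Eyring dH/dG/dS;
* Weibull: reliable life t_R, time scale alpha, z'-value, the log-logistic
  b(T) model, then Ea and *apparent* Eyring parameters from the 1/alpha
  rate surrogate.

The returned :class:`InactivationResults` exposes the estimates, selection
verdicts and derived summaries as DataFrames, a text ``summary()``, a
deterministic JSON report (stable key order, fixed float precision) and a
diagnostic plot.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .exceptions import InputError
from .fitting import (
    ActivityCurve,
    FitResult,
    SelectionVerdict,
    fit_all_models,
    select_model,
)
from .io import dataframe_to_curves, read_activity_table
from .kinetics import KineticSummary, first_order_summary, weibull_summary
from .models import get_model_spec, weibull_to_alpha
from .thermo import ThermoSummary, build_thermo_summary

__all__ = ["AnalysisOptions", "ThermalInactivation", "InactivationResults", "run_pipeline"]


@dataclass(frozen=True)
class AnalysisOptions:
    """Tunable pipeline options (defaults reproduce the standard analysis)."""

    zprime_base: str = "log10"  # 'log10' | 'ln' (compatibility)
    eyring_units: str = "si"  # 'si' | 'paper-compat'
    fit_replicate_means: bool = False
    n_starts: int = 10
    jitter_seed: int = 1234

    def as_dict(self) -> dict[str, Any]:
        return {
            "zprime_base": self.zprime_base,
            "eyring_units": self.eyring_units,
            "fit_replicate_means": self.fit_replicate_means,
            "n_starts": self.n_starts,
            "jitter_seed": self.jitter_seed,
        }


class ThermalInactivation:
    """Thermal-inactivation analysis of residual-activity decay curves.

    Parameters
    ----------
    curves
        One :class:`~thermokin.fitting.ActivityCurve` per temperature.
    label
        Optional dataset/enzyme label carried into reports.

    Examples
    --------
    >>> from thermokin import ThermalInactivation, synthetic
    >>> curves = synthetic.generate_dataset(synthetic.paper_presets("lipase_ps", seed=7))
    >>> res = ThermalInactivation(curves, label="lipase_ps").fit()
    >>> res.accepted_model_id
    'first_order'
    """

    def __init__(self, curves: list[ActivityCurve], label: str | None = None):
        if not curves:
            raise InputError("need at least one activity curve")
        self.curves = sorted(curves, key=lambda c: c.temperature)
        self.label = label or next(
            (c.label for c in curves if c.label is not None), None
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label: str | None = None, **norm_opts):
        return cls(dataframe_to_curves(df, **norm_opts), label=label)

    @classmethod
    def from_csv(cls, path, label: str | None = None, **norm_opts):
        return cls(read_activity_table(path, **norm_opts), label=label)

    @property
    def temperatures(self) -> list[float]:
        return [c.temperature for c in self.curves]

    def fit(self, options: AnalysisOptions | None = None, **option_kwargs) -> "InactivationResults":
        """Run fitting, selection and the derived-parameter branch."""
        if options is None:
            options = AnalysisOptions(**option_kwargs)
        elif option_kwargs:
            raise InputError("pass either an AnalysisOptions or keyword options, not both")

        fits = fit_all_models(
            self.curves,
            n_starts=options.n_starts,
            fit_replicate_means=options.fit_replicate_means,
            seed=options.jitter_seed,
        )
        verdicts = select_model(fits)
        accepted = next((v.model_id for v in verdicts if v.status == "accepted"), None)

        warnings_: list[str] = []
        kinetics_: KineticSummary | None = None
        thermo_: ThermoSummary | None = None
        if accepted is None:
            warnings_.append("no model accepted: every candidate was rejected")
        else:
            kinetics_, thermo_, extra = self._derived_branch(
                accepted, fits[accepted], options
            )
            warnings_.extend(extra)

        return InactivationResults(
            model=self,
            options=options,
            fits_by_model=fits,
            verdicts=verdicts,
            accepted_model_id=accepted,
            kinetics=kinetics_,
            thermo=thermo_,
            warnings=warnings_,
        )

    def _derived_branch(self, accepted, fits, options):
        warnings_ = []
        temps = [f.temperature for f in fits]
        r2s = [f.r2 for f in fits]
        multi_T = len(set(temps)) >= 2
        if accepted == "weibull":
            bs = [f.estimates["b"] for f in fits]
            ns = [f.estimates["n"] for f in fits]
            kin = weibull_summary(temps, bs, ns, r2s, options.zprime_base)
            thermo_ = None
            if multi_T:
                alpha_inv = [1.0 / weibull_to_alpha(b, n) for b, n in zip(bs, ns)]
                thermo_ = build_thermo_summary(
                    temps, alpha_inv,
                    arrhenius_rate_unit="per_h",  # 1/alpha enters Arrhenius in h^-1
                    unit_mode=options.eyring_units,
                    apparent=True,
                )
            else:
                warnings_.append("single temperature: no z', Arrhenius or Eyring analysis")
            return kin, thermo_, warnings_

        rate_name = get_model_spec(accepted).primary_rate
        if rate_name is None:
            warnings_.append(
                f"accepted model {accepted!r} has no principal rate; "
                "no derived kinetic parameters"
            )
            return None, None, warnings_
        ks = [f.estimates[rate_name] for f in fits]
        if accepted != "first_order":
            warnings_.append(
                f"derived parameters use {rate_name!r} of model {accepted!r} "
                "as the principal first-order rate"
            )
        kin = first_order_summary(temps, ks, r2s)
        kin = KineticSummary(accepted, kin.records, z=kin.z)
        thermo_ = None
        if multi_T:
            thermo_ = build_thermo_summary(
                temps, ks,
                arrhenius_rate_unit="per_min",
                unit_mode=options.eyring_units,
                apparent=(accepted != "first_order"),
            )
        else:
            warnings_.append("single temperature: no z, Arrhenius or Eyring analysis")
        return kin, thermo_, warnings_


def run_pipeline(data, label: str | None = None, *, already_normalized=False,
                 normalize_by=None, **option_kwargs) -> "InactivationResults":
    """Convenience wrapper: read -> fit -> select -> derive in one call.

    ``data`` may be a path to a delimited activity table, a DataFrame with
    the standard columns, or a list of ActivityCurve.
    """
    norm = {"already_normalized": already_normalized, "normalize_by": normalize_by}
    if isinstance(data, pd.DataFrame):
        model = ThermalInactivation.from_dataframe(data, label=label, **norm)
    elif isinstance(data, (list, tuple)):
        model = ThermalInactivation(list(data), label=label)
    else:
        model = ThermalInactivation.from_csv(data, label=label, **norm)
    return model.fit(**option_kwargs)


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

def _round(value):
    """Fixed 10-significant-digit float representation for stable reports."""
    if isinstance(value, float):
        if math.isnan(value):
            return None
        if math.isinf(value):
            return "inf" if value > 0 else "-inf"
        return float(f"{value:.10g}")
    return value


def _sanitize(obj):
    if isinstance(obj, dict):
        return {str(k): _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return _round(float(obj))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


@dataclass
class InactivationResults:
    """Everything the analysis produced, with table/JSON/plot accessors."""

    model: ThermalInactivation
    options: AnalysisOptions
    fits_by_model: dict[str, list[FitResult]]
    verdicts: list[SelectionVerdict]
    accepted_model_id: str | None
    kinetics: KineticSummary | None
    thermo: ThermoSummary | None
    warnings: list[str] = field(default_factory=list)

    # -- tables -------------------------------------------------------------

    def fit_table(self) -> pd.DataFrame:
        """One row per model x temperature with estimates, SEs and statistics."""
        rows = []
        for mid, fits in self.fits_by_model.items():
            for f in fits:
                row = {
                    "model": mid,
                    "temperature_C": f.temperature,
                    "converged": f.converged,
                    "r2": f.r2,
                    "chi2": f.chi2,
                    "sem": f.sem,
                    "m": f.m,
                    "p": f.p,
                }
                for name, v in f.estimates.items():
                    row[name] = v
                    row[f"se_{name}"] = f.standard_errors.get(name, float("nan"))
                rows.append(row)
        return pd.DataFrame(rows)

    def verdict_table(self) -> pd.DataFrame:
        rows = []
        for v in self.verdicts:
            row = {"model": v.model_id, "status": v.status, "reason": v.reason}
            for stat in ("r2", "chi2", "sem"):
                rng = v.criteria.get(stat)
                row[f"{stat}_min"], row[f"{stat}_max"] = rng if rng else (None, None)
            rows.append(row)
        return pd.DataFrame(rows)

    def kinetic_table(self) -> pd.DataFrame:
        if self.kinetics is None:
            return pd.DataFrame()
        rows = []
        for rec in self.kinetics.records:
            row = {"temperature_C": rec.temperature, "r2": rec.r2, **rec.params}
            for name in ("t_half", "d", "t_r", "alpha"):
                value = getattr(rec, name)
                if value is not None:
                    row[name + "_min"] = value
            rows.append(row)
        df = pd.DataFrame(rows)
        if self.kinetics.z is not None:
            df["z_C"] = self.kinetics.z
        if self.kinetics.z_prime is not None:
            df[f"z_prime_C_{self.kinetics.z_prime_base}"] = self.kinetics.z_prime
        return df

    def thermo_table(self) -> pd.DataFrame:
        if self.thermo is None:
            return pd.DataFrame()
        rows = [
            {
                "temperature_C": rec.temperature,
                "Ea_kJ_mol": self.thermo.ea_kj_mol,
                "dH_kJ_mol": rec.dH,
                "dG_kJ_mol": rec.dG,
                "dS_J_mol_K": rec.dS,
                "TdS_over_dH": rec.ratio,
                "apparent": self.thermo.apparent,
            }
            for rec in self.thermo.records
        ]
        return pd.DataFrame(rows)

    # -- report -------------------------------------------------------------

    def to_report(self) -> dict:
        """JSON-ready dict; stable ordering and float formatting."""
        dataset = {
            "label": self.model.label,
            "temperatures_C": list(self.model.temperatures),
            "n_observations": {
                f"{c.temperature:g}": int(c.n_obs) for c in self.model.curves
            },
        }
        fits = {
            mid: {
                f"{f.temperature:g}": {
                    "estimates": f.estimates,
                    "standard_errors": f.standard_errors,
                    "r2": f.r2,
                    "chi2": f.chi2,
                    "sem": f.sem,
                    "converged": f.converged,
                    "m": f.m,
                    "p": f.p,
                }
                for f in fr
            }
            for mid, fr in self.fits_by_model.items()
        }
        selection = [
            {
                "model": v.model_id,
                "status": v.status,
                "reason": v.reason,
                "criteria": {
                    stat: (list(rng) if rng else None)
                    for stat, rng in v.criteria.items()
                },
            }
            for v in self.verdicts
        ]
        kinetics = None
        if self.kinetics is not None:
            kinetics = {
                "model": self.kinetics.model_id,
                "records": [
                    {
                        "temperature_C": rec.temperature,
                        "params": rec.params,
                        "r2": rec.r2,
                        "t_half_min": rec.t_half,
                        "d_min": rec.d,
                        "t_r_min": rec.t_r,
                        "alpha_min": rec.alpha,
                    }
                    for rec in self.kinetics.records
                ],
                "z_C": self.kinetics.z,
                "z_prime_C": self.kinetics.z_prime,
                "z_prime_base": self.kinetics.z_prime_base,
                "log_logistic": (
                    {
                        "k_prime_per_C": self.kinetics.log_logistic.k_prime,
                        "T_c_C": self.kinetics.log_logistic.T_c,
                        "r2": self.kinetics.log_logistic.r2,
                        "converged": self.kinetics.log_logistic.converged,
                    }
                    if self.kinetics.log_logistic is not None
                    else None
                ),
            }
        thermo_ = None
        if self.thermo is not None:
            thermo_ = {
                "Ea_kJ_mol": self.thermo.ea_kj_mol,
                "arrhenius_intercept": self.thermo.arrhenius_intercept,
                "arrhenius_r2": self.thermo.arrhenius_r2,
                "arrhenius_rate_unit": self.thermo.arrhenius_rate_unit,
                "apparent": self.thermo.apparent,
                "unit_mode": self.thermo.unit_mode,
                "records": [
                    {
                        "temperature_C": rec.temperature,
                        "dH_kJ_mol": rec.dH,
                        "dG_kJ_mol": rec.dG,
                        "dS_J_mol_K": rec.dS,
                        "TdS_over_dH": rec.ratio,
                    }
                    for rec in self.thermo.records
                ],
            }
        report = {
            "package": {"name": "thermokin", "version": __version__},
            "dataset": dataset,
            "options": self.options.as_dict(),
            "fits": fits,
            "selection": selection,
            "accepted_model": self.accepted_model_id,
            "kinetics": kinetics,
            "thermodynamics": thermo_,
            "warnings": list(self.warnings),
        }
        return _sanitize(report)

    def to_json(self, path=None) -> str:
        """Serialised report; byte-identical across reruns on the same input."""
        text = json.dumps(self.to_report(), sort_keys=True, indent=2, allow_nan=False)
        text += "\n"
        if path is not None:
            with open(path, "w", encoding="utf-8", newline="\n") as fh:
                fh.write(text)
        return text

    # -- presentation -------------------------------------------------------

    def summary(self) -> str:
        """Human-readable account of selection, kinetics and thermodynamics."""
        lines = []
        title = "Thermal inactivation analysis"
        if self.model.label:
            title += f" — {self.model.label}"
        lines += [title, "=" * len(title)]
        temps = ", ".join(f"{t:g}" for t in self.model.temperatures)
        lines.append(f"Temperatures (degC): {temps}")
        lines.append(f"Accepted model: {self.accepted_model_id or 'none'}")
        lines.append("")
        lines.append("Model screening")
        lines.append("-" * 15)
        for v in self.verdicts:
            rng = v.criteria.get("r2")
            r2_txt = f"r2 [{rng[0]:.4f}; {rng[1]:.4f}]" if rng else "r2 —"
            lines.append(f"{v.model_id:<22} {v.status:<8} {v.reason:<24} {r2_txt}")
        if self.kinetics is not None:
            lines.append("")
            lines.append("Kinetic parameters")
            lines.append("-" * 18)
            lines.append(self.kinetic_table().to_string(index=False, float_format=lambda x: f"{x:.4g}"))
        if self.thermo is not None:
            lines.append("")
            header = "Activation thermodynamics"
            if self.thermo.apparent:
                header += " (apparent)"
            lines.append(header)
            lines.append("-" * len(header))
            lines.append(f"Ea = {self.thermo.ea_kj_mol:.2f} kJ/mol "
                         f"(Arrhenius r2 = {self.thermo.arrhenius_r2:.4f}, "
                         f"rates in {self.thermo.arrhenius_rate_unit})")
            lines.append(self.thermo_table().drop(columns=["apparent"]).to_string(
                index=False, float_format=lambda x: f"{x:.4g}"))
        for w in self.warnings:
            lines.append("")
            lines.append(f"warning: {w}")
        return "\n".join(lines)

    def plot_fits(self, ax=None):
        """Observed points and the accepted model's curves per temperature."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        for curve in self.model.curves:
            pts = ax.plot(
                curve.times, curve.activities, "o", ms=4, alpha=0.6,
                label=f"{curve.temperature:g} degC",
            )
            if self.accepted_model_id is not None:
                fit = next(
                    f for f in self.fits_by_model[self.accepted_model_id]
                    if f.temperature == curve.temperature
                )
                if fit.converged:
                    grid = np.linspace(0, curve.times.max(), 200)
                    ax.plot(grid, fit.predict(grid), "-", color=pts[0].get_color())
        ax.set_xlabel("time (min)")
        ax.set_ylabel("residual activity A/A0")
        ax.set_ylim(bottom=min(0.0, ax.get_ylim()[0]))
        ax.legend(title=self.accepted_model_id or "data")
        return ax


# ---------------------------------------------------------------------------
# report re-rendering (used by the CLI `report` command)
# ---------------------------------------------------------------------------

def report_tables(report: dict) -> dict[str, pd.DataFrame]:
    """Rebuild the delimited tables from a JSON report dict."""
    fit_rows = []
    for mid, per_temp in report.get("fits", {}).items():
        for temp, f in per_temp.items():
            row = {
                "model": mid,
                "temperature_C": float(temp),
                "converged": f["converged"],
                "r2": f["r2"],
                "chi2": f["chi2"],
                "sem": f["sem"],
                "m": f["m"],
                "p": f["p"],
            }
            for name, v in f["estimates"].items():
                row[name] = v
                row[f"se_{name}"] = f["standard_errors"].get(name)
            fit_rows.append(row)
    tables = {"fits": pd.DataFrame(fit_rows)}

    sel_rows = []
    for v in report.get("selection", []):
        row = {"model": v["model"], "status": v["status"], "reason": v["reason"]}
        for stat, rng in (v.get("criteria") or {}).items():
            row[f"{stat}_min"], row[f"{stat}_max"] = rng if rng else (None, None)
        sel_rows.append(row)
    tables["selection"] = pd.DataFrame(sel_rows)

    kin = report.get("kinetics")
    if kin:
        rows = []
        for rec in kin["records"]:
            row = {"temperature_C": rec["temperature_C"], "r2": rec["r2"], **rec["params"]}
            for key in ("t_half_min", "d_min", "t_r_min", "alpha_min"):
                if rec.get(key) is not None:
                    row[key] = rec[key]
            rows.append(row)
        df = pd.DataFrame(rows)
        if kin.get("z_C") is not None:
            df["z_C"] = kin["z_C"]
        if kin.get("z_prime_C") is not None:
            df[f"z_prime_C_{kin['z_prime_base']}"] = kin["z_prime_C"]
        tables["kinetics"] = df

    th = report.get("thermodynamics")
    if th:
        tables["thermodynamics"] = pd.DataFrame(
            [
                {
                    "temperature_C": rec["temperature_C"],
                    "Ea_kJ_mol": th["Ea_kJ_mol"],
                    "dH_kJ_mol": rec["dH_kJ_mol"],
                    "dG_kJ_mol": rec["dG_kJ_mol"],
                    "dS_J_mol_K": rec["dS_J_mol_K"],
                    "TdS_over_dH": rec["TdS_over_dH"],
                    "apparent": th["apparent"],
                }
                for rec in th["records"]
            ]
        )
    return tables
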