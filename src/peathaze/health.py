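"""Long-term health-impact assessment for PM2.5 exposure.

Implements the concentration-response chain used in burden-of-disease
assessments of landscape-fire smoke:

    RR(X)  = [(X + 1) / (X_o + 1)]^beta      (log-linear form)
    RR(X)  = exp[beta (X - X_o)]             (linear-exponential form)
    AF     = RR(X) - RR(X_o) = RR(X) - 1
    deaths = AF * CDR * percent_of_deaths * population

where X is a village's period-mean PM2.5 increment (ug/m3), X_o the lowest
observed village mean (the lowest-effect level), beta the excess risk per
unit PM2.5, CDR the crude death rate and percent_of_deaths the category's
share of all-cause mortality. RR is defined for X >= X_o and clamped to 1
below it, so attributable burden is never negative.

Coefficients originally expressed per unit PM10 are renormalized with the
Indonesian PM10/PM2.5 ratio 48/21.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "PM10_PM25_RATIO",
    "HealthCaseSpec",
    "default_specs",
    "renormalize_beta",
    "display_beta",
    "relative_risk",
    "attributable_fraction",
    "attributable_deaths",
    "rate_per_100k",
    "round_half_up",
    "ImpactResult",
    "run_hia",
    "sensitivity",
]

#: Indonesian PM10 / PM2.5 conversion ratio, kept as the exact rational
PM10_PM25_RATIO = 48.0 / 21.0

DEFAULT_CDR = 0.0058  # crude death rate, deaths per person-year (2015)


@dataclass(frozen=True)
class HealthCaseSpec:
    """One mortality category's exposure-response configuration."""

    name: str
    form: str  # 'log_linear' or 'linear'
    beta: float  # excess risk per ug/m3 PM2.5
    percent_of_deaths: float  # category share of all-cause deaths, 0..1
    age_group: str  # 'all', 'under5' or 'adults30plus'
    age_fraction: float  # age group share of total population, 0..1

    def __post_init__(self) -> None:
        if self.form not in ("log_linear", "linear"):
            raise ValueError(f"unknown RR form {self.form!r}")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if not 0.0 <= self.percent_of_deaths <= 1.0:
            raise ValueError(f"{self.name}: percent_of_deaths outside [0, 1]")
        if not 0.0 <= self.age_fraction <= 1.0:
            raise ValueError(f"{self.name}: age_fraction outside [0, 1]")


def default_specs() -> list[HealthCaseSpec]:
    """The four default mortality categories.

    All-cause and chronic-respiratory betas are PM10 coefficients (0.0008
    and 0.00166) renormalized by 48/21; cardiovascular and lung-cancer
    betas apply to PM2.5 directly with the log-linear form.
    """
    return [
        HealthCaseSpec("all_cause", "linear", renormalize_beta(0.0008),
                       1.00, "all", 1.0),
        HealthCaseSpec("chronic_respiratory", "linear", renormalize_beta(0.00166),
                       0.04, "under5", 0.10),
        HealthCaseSpec("cardiovascular", "log_linear", 0.15515,
                       0.33, "adults30plus", 0.445),
        HealthCaseSpec("lung_cancer", "log_linear", 0.23218,
                       0.02, "adults30plus", 0.445),
    ]


def renormalize_beta(beta_pm10: float, ratio: float = PM10_PM25_RATIO) -> float:
    """Convert a per-PM10 coefficient to per-PM2.5 by multiplying with the
    PM10/PM2.5 ratio. Full precision is retained; use display_beta for the
    6-decimal reporting form."""
    if beta_pm10 <= 0 or ratio <= 0:
        raise ValueError("beta and ratio must be positive")
    return beta_pm10 * ratio


def display_beta(beta: float) -> float:
    """Reporting precision for beta coefficients (6 decimal places)."""
    return round(beta, 6)


def _check_concentrations(x, x_o) -> None:
    if np.any(np.asarray(x) < 0) or np.any(np.asarray(x_o) < 0):
        raise ValueError("concentrations must be non-negative")


def relative_risk(x, x_o, spec: HealthCaseSpec):
    """RR at exposure x relative to reference x_o (scalar or array).

    Clamped to exactly 1 for x < x_o (the response is defined only above
    the lowest-effect level); RR(x_o) = 1 in both functional forms.
    """
    _check_concentrations(x, x_o)
    x = np.asarray(x, dtype=float)
    if spec.form == "log_linear":
        rr = ((x + 1.0) / (np.asarray(x_o) + 1.0)) ** spec.beta
    else:
        rr = np.exp(spec.beta * (x - x_o))
    rr = np.where(x < x_o, 1.0, rr)
    return float(rr) if rr.ndim == 0 else rr


def attributable_fraction(x, x_o, spec: HealthCaseSpec):
    """AF = RR(x) - RR(x_o) = RR(x) - 1; non-negative, uncapped.

    Values above 1 are possible for large exposures with large beta and
    are reported with a warning rather than truncated.
    """
    af = relative_risk(x, x_o, spec) - 1.0
    if np.any(np.asarray(af) > 1.0):
        warnings.warn(
            f"{spec.name}: attributable fraction exceeds 1 at some exposures",
            stacklevel=2,
        )
    return af


def attributable_deaths(
    af, cdr: float, population, percent_of_deaths: float, age_fraction: float = 1.0
):
    """Annual attributable deaths: AF * CDR * category share * population
    in the age group (population * age_fraction). Unrounded."""
    if not 0.0 <= percent_of_deaths <= 1.0:
        raise ValueError("percent_of_deaths outside [0, 1]")
    if not 0.0 <= age_fraction <= 1.0:
        raise ValueError("age_fraction outside [0, 1]")
    if cdr < 0 or np.any(np.asarray(af) < 0) or np.any(np.asarray(population) < 0):
        raise ValueError("af, cdr and population must be non-negative")
    return af * cdr * percent_of_deaths * (np.asarray(population, dtype=float) * age_fraction)


def rate_per_100k(deaths: float, population: float) -> float:
    """Deaths per 100,000 population per year (unrounded; round for print)."""
    if population <= 0:
        raise ValueError("population must be positive")
    return deaths / population * 1.0e5


def round_half_up(x: float) -> int:
    """Reporting rounding for death counts (0.5 rounds away from zero)."""
    return int(math.floor(x + 0.5))


@dataclass
class ImpactResult:
    """Per-village and regional attributable-mortality results."""

    villages: pd.DataFrame  # per-village AF and deaths per category
    table: pd.DataFrame  # region table: category x age-basis rows
    x_o: float
    cdr: float
    specs: list[HealthCaseSpec]

    def total_attributable(self, category: str) -> float:
        """Regional all-ages attributable deaths for one category (unrounded)."""
        row = self.table[
            (self.table["category"] == category) & (self.table["basis"] == "all_ages")
        ]
        return float(row["attributable_deaths"].iloc[0])


def run_hia(
    villages: pd.DataFrame,
    specs: list[HealthCaseSpec] | None = None,
    cdr: float = DEFAULT_CDR,
    x_o: float | None = None,
) -> ImpactResult:
    """Run the health-impact assessment over a village exposure table.

    ``villages`` needs columns village_id, population and mean_pm25 (the
    period-mean PM2.5 increment X). Every village's AF uses its own X
    against the single regional reference X_o (by default the lowest
    village mean). The region table carries, per category, an all-ages row
    (AF applied to the full population) and, where the category targets an
    age group, a second row scaled by the age fraction — both conventions
    are reported; the headline uses the all-ages basis.
    """
    specs = default_specs() if specs is None else specs
    required = {"village_id", "population", "mean_pm25"}
    missing_cols = required - set(villages.columns)
    if missing_cols:
        raise KeyError(f"village table missing columns: {sorted(missing_cols)}")
    bad = villages[villages["mean_pm25"].isna()]
    if len(bad):
        raise ValueError(f"villages missing exposure: {list(bad['village_id'])}")
    x = villages["mean_pm25"].to_numpy(dtype=float)
    pop = villages["population"].to_numpy(dtype=float)
    if x_o is None:
        x_o = float(x.min())

    per_village = villages[["village_id", "population", "mean_pm25"]].copy()
    table_rows = []
    total_pop = float(pop.sum())
    for spec in specs:
        af = attributable_fraction(x, x_o, spec)
        deaths_v = attributable_deaths(af, cdr, pop, spec.percent_of_deaths)
        per_village[f"af_{spec.name}"] = af
        per_village[f"deaths_{spec.name}"] = deaths_v
        total = float(deaths_v.sum())
        baseline_all = cdr * total_pop * spec.percent_of_deaths
        table_rows.append({
            "category": spec.name,
            "basis": "all_ages",
            "age_group": "all",
            "population": total_pop,
            "baseline_deaths": baseline_all,
            "attributable_deaths": total,
            "per_100k": rate_per_100k(total, total_pop),
        })
        if spec.age_group != "all":
            pop_age = total_pop * spec.age_fraction
            table_rows.append({
                "category": spec.name,
                "basis": "age_group",
                "age_group": spec.age_group,
                "population": pop_age,
                "baseline_deaths": baseline_all * spec.age_fraction,
                "attributable_deaths": total * spec.age_fraction,
                "per_100k": rate_per_100k(total * spec.age_fraction, pop_age),
            })
    table = pd.DataFrame(table_rows)
    return ImpactResult(per_village, table, x_o=x_o, cdr=cdr, specs=specs)


def _flip_form(spec: HealthCaseSpec) -> HealthCaseSpec:
    return replace(spec, form="linear" if spec.form == "log_linear" else "log_linear")


def sensitivity(
    villages: pd.DataFrame,
    specs: list[HealthCaseSpec] | None = None,
    cdr: float = DEFAULT_CDR,
    deltas: tuple[float, ...] = (10.0, -10.0),
    x_o_alt: float = 10.0,
    swap_forms: bool = True,
) -> pd.DataFrame:
    """Sensitivity of attributable deaths to the exposure-response choices.

    Variants: shift every village exposure by +/-10 ug/m3 (floored at 0,
    reference X_o unchanged), fix the reference at the WHO annual guideline
    (X_o = 10), and swap each category's functional form. Percent changes
    are computed on unrounded totals.
    """
    specs = default_specs() if specs is None else specs
    base = run_hia(villages, specs, cdr)
    rows = []

    def pct_changes(variant: ImpactResult, name: str) -> None:
        for spec in specs:
            b = base.total_attributable(spec.name)
            v = variant.total_attributable(spec.name)
            change = float("nan") if b == 0 else (v - b) / b * 100.0
            rows.append({
                "variant": name,
                "category": spec.name,
                "baseline_deaths": b,
                "variant_deaths": v,
                "pct_change": change,
            })

    for d in deltas:
        shifted = villages.copy()
        shifted["mean_pm25"] = np.maximum(0.0, shifted["mean_pm25"] + d)
        pct_changes(run_hia(shifted, specs, cdr, x_o=base.x_o), f"X{d:+g}")
    if x_o_alt is not None:
        pct_changes(run_hia(villages, specs, cdr, x_o=x_o_alt), f"Xo={x_o_alt:g}")
    if swap_forms:
        pct_changes(run_hia(villages, [_flip_form(s) for s in specs], cdr),
                    "alternate_form")
    return pd.DataFrame(rows)
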