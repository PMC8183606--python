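"""Clinical-pathway costing: SW hospitalization blocks and SV long-term therapies.

The public payer reimburses ward admissions with a flat fee regardless of
length of stay, while ICU care is paid per day. Long-term costs of a missed
simple-virilizing diagnosis are growth-hormone and GnRH-analog therapy for
precocious pseudo-puberty, the masculinization process for 46,XX patients
reared as males, and a diagnostic laboratory panel per patient.

Per-patient therapy costs are kept unrounded until the cohort total, which is
then rounded to the cent; fractional ampoules are allowed (treatment spans
years, so part-used ampoules average out). Years are 365 days.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal

from ._rounding import round_half_up, to_cents
from .parameters import SVPathwayParams, UnitCosts

DAYS_PER_YEAR = 365
#: one 11.25 mg GnRHa depot ampoule every 3 months
GNRHA_AMPOULES_PER_YEAR = 4


@dataclass(frozen=True)
class HospitalizationBlock:
    """Dehydration hospitalizations for one arm's unrecognized SW cases."""

    n_at_risk: int
    n_hospitalized: int
    n_icu: int
    icu_days: float
    cost: Decimal

    def __post_init__(self) -> None:
        if not (0 <= self.n_icu <= self.n_hospitalized <= self.n_at_risk):
            raise ValueError("need n_icu <= n_hospitalized <= n_at_risk, all >= 0")
        if self.cost < 0:
            raise ValueError("cost must be >= 0")

    @property
    def n_not_hospitalized(self) -> int:
        return self.n_at_risk - self.n_hospitalized


@dataclass(frozen=True)
class TherapyCost:
    """Cohort cost of one long-term therapy for unrecognized SV patients."""

    therapy: str  # GH | GnRHa | masculinization | diagnostic_lab
    n_treated: int
    cost: Decimal

    def __post_init__(self) -> None:
        if self.n_treated < 0 or self.cost < 0:
            raise ValueError("n_treated and cost must be >= 0")


def hospitalization_block(
    n_at_risk: int,
    hosp_rate: float,
    icu_rate: float,
    icu_days: float,
    costs: UnitCosts,
) -> HospitalizationBlock:
    """Hospitalize ``hosp_rate`` of those at risk; send ``icu_rate`` of the
    hospitalized to ICU for ``icu_days`` days each."""
    n_hosp = round_half_up(n_at_risk * hosp_rate)
    n_icu = round_half_up(n_hosp * icu_rate)
    cost = n_hosp * costs.ward_hospitalization + n_icu * icu_days * costs.icu_day
    return HospitalizationBlock(n_at_risk, n_hosp, n_icu, icu_days, to_cents(cost))


def gh_per_patient_cost(
    dose_ui_day: float, years: float, ampoule_ui: float, ampoule_price: float
) -> float:
    """Unrounded GH cost for one patient: dose x 365 x years, priced per ampoule."""
    return dose_ui_day * DAYS_PER_YEAR * years / ampoule_ui * ampoule_price


def gh_cohort_cost(
    n_treated: int, dose_ui_day: float, years: float, ampoule_ui: float, ampoule_price: float
) -> Decimal:
    return to_cents(n_treated * gh_per_patient_cost(dose_ui_day, years, ampoule_ui, ampoule_price))


def gnrha_cohort_cost(n_treated: int, years: float, ampoule_price: float) -> Decimal:
    return to_cents(n_treated * GNRHA_AMPOULES_PER_YEAR * years * ampoule_price)


def sv_long_term_costs(
    n_unrecognized_sv: int, sv: SVPathwayParams, costs: UnitCosts
) -> list[TherapyCost]:
    """Long-term therapy ledger for unrecognized SV patients.

    Treated counts are rounded per therapy from the full unrecognized pool;
    every patient in the pool pays the diagnostic laboratory panel.
    """
    n = n_unrecognized_sv
    n_masc = round_half_up(n * sv.female_fraction * sv.masculinization_rate)
    n_gh = round_half_up(n * sv.gh_use_rate)
    n_gnrha = round_half_up(n * sv.gnrha_use_rate)
    return [
        TherapyCost("masculinization", n_masc, to_cents(n_masc * costs.masculinization)),
        TherapyCost(
            "GH",
            n_gh,
            gh_cohort_cost(n_gh, sv.gh_dose_ui_per_day, sv.gh_years,
                           costs.gh_ampoule_ui, costs.gh_ampoule_price),
        ),
        TherapyCost("GnRHa", n_gnrha, gnrha_cohort_cost(n_gnrha, sv.gnrha_years,
                                                        costs.gnrha_ampoule_price)),
        TherapyCost("diagnostic_lab", n, to_cents(n * costs.diagnostic_lab)),
    ]
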