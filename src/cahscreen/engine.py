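"""Two-arm evaluation of the decision tree and the ICER.

The screening arm bills every newborn the filter-paper 17-OHP test and pushes
the non-affected through the false-positive recall cascade; affected newborns
are all detected, so the arm has zero deaths and no long-term morbidity costs
(screened SW cases can still be hospitalized before the screening result
arrives). The clinical-diagnosis arm has no screening costs: recognized cases
pay a diagnostic laboratory panel, unrecognized SW cases die at the assumed
mortality rate or survive into the hospitalization pathway, and unrecognized
SV cases accrue the long-term therapy costs.

Effectiveness is deaths averted converted to discounted life-years; the ICER
is the incremental cost per discounted life-year saved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal

from ._rounding import round_half_up, to_cents
from .cascade import (
    LineItem,
    cascade_costs,
    category_unit_cost,
    ledger_to_frame,
    partition_birth_cohort,
    run_cascade,
)
from .outcomes import gh_cohort_cost, gnrha_cohort_cost, hospitalization_block, sv_long_term_costs
from .parameters import ModelParams

DLY_CONVENTIONS = ("constant", "annuity_ordinary", "annuity_due")


@dataclass(frozen=True)
class RoundedNode:
    """Audit record of one integer-rounding step: expectation vs rounded count."""

    label: str
    expectation: float
    rounded: int


@dataclass
class ArmLedger:
    """Itemized costs and deaths for one strategy arm."""

    strategy: str  # "screened" | "unscreened"
    line_items: list[LineItem]
    deaths: int
    rounded_nodes: list[RoundedNode] = field(default_factory=list)

    @property
    def total_cost(self) -> Decimal:
        return sum((item.cost for item in self.line_items), Decimal("0.00"))

    def line(self, label: str) -> LineItem:
        for item in self.line_items:
            if item.label == label:
                return item
        raise KeyError(f"no ledger line labelled {label!r}")

    def to_frame(self):
        return ledger_to_frame(self.line_items)


@dataclass(frozen=True)
class CEAResult:
    """Incremental cost-effectiveness of screening vs clinical diagnosis.

    ``cost_per_death_averted`` and ``icer`` are ``None`` when no deaths are
    averted (the ratio is undefined on this effect measure).
    """

    label: str
    incremental_cost: Decimal
    deaths_averted: int
    discounted_ly: float
    cost_per_death_averted: Decimal | None
    icer: Decimal | None

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "incremental_cost_usd": float(self.incremental_cost),
            "deaths_averted": self.deaths_averted,
            "discounted_ly_per_death": self.discounted_ly,
            "cost_per_death_averted_usd": (
                None if self.cost_per_death_averted is None else float(self.cost_per_death_averted)
            ),
            "icer_usd_per_ly": None if self.icer is None else float(self.icer),
        }


def _round_node(log: list[RoundedNode], label: str, expectation: float) -> int:
    n = round_half_up(expectation)
    log.append(RoundedNode(label, float(expectation), n))
    return n


def evaluate_screened_arm(params: ModelParams) -> ArmLedger:
    """Cost the newborn-screening strategy arm. Deaths are zero by assumption."""
    epi, sw, costs = params.epidemiology, params.sw, params.costs
    log: list[RoundedNode] = []
    part = partition_birth_cohort(epi.live_births, epi.cah_incidence, epi.sw_fraction)
    log.append(RoundedNode("affected", float(epi.live_births * epi.cah_incidence), part.affected))
    log.append(RoundedNode("sw", part.affected * epi.sw_fraction, part.sw))

    sw_rec = _round_node(log, "sw_recognized", part.sw * epi.clinical_recognition_sw)
    sw_unrec = part.sw - sw_rec
    hosp = hospitalization_block(
        sw_unrec, sw.hosp_rate_screened, sw.icu_rate_screened, sw.icu_days_screened, costs
    )
    log.append(RoundedNode("sw_hospitalized", sw_unrec * sw.hosp_rate_screened, hosp.n_hospitalized))
    log.append(RoundedNode("sw_icu", hosp.n_hospitalized * sw.icu_rate_screened, hosp.n_icu))

    ab = category_unit_cost("A+B", costs)
    aab = category_unit_cost("2A+B", costs)
    items = [
        LineItem("sw_recognized_screen", sw_rec, "A+B", to_cents(sw_rec * ab)),
        LineItem("sw_unrecognized_screen", sw_unrec, "A+B", to_cents(sw_unrec * ab)),
        LineItem("sw_unrecognized_hospitalization", hosp.n_hospitalized, "ward+ICU", hosp.cost),
        LineItem("sv_screen", part.sv, "2A+B", to_cents(part.sv * aab)),
    ]
    cascade = run_cascade(part.non_affected, params.screening)
    log.append(RoundedNode("fp_total", part.non_affected * params.screening.fp_rate,
                           cascade.fp_total))
    log.append(RoundedNode("fp_high", cascade.fp_total * params.screening.high_risk_fraction,
                           cascade.fp_high))
    log.append(RoundedNode(
        "confirm_tn", cascade.fp_high * (1 - params.screening.confirmatory_fp_fraction),
        cascade.confirm_tn))
    log.append(RoundedNode(
        "retest_tn", cascade.fp_low * (1 - params.screening.retest_fp_fraction),
        cascade.retest_tn))
    items.extend(cascade_costs(cascade, costs))
    return ArmLedger("screened", items, deaths=0, rounded_nodes=log)


def evaluate_unscreened_arm(params: ModelParams) -> ArmLedger:
    """Cost the clinical-diagnosis strategy arm and count its deaths.

    Deaths occur among unrecognized SW cases and are removed before the
    hospitalization rate applies (survivor denominator); deceased patients
    incur no cost.
    """
    epi, sw, sv, costs = params.epidemiology, params.sw, params.sv, params.costs
    log: list[RoundedNode] = []
    part = partition_birth_cohort(epi.live_births, epi.cah_incidence, epi.sw_fraction)
    log.append(RoundedNode("affected", float(epi.live_births * epi.cah_incidence), part.affected))
    log.append(RoundedNode("sw", part.affected * epi.sw_fraction, part.sw))

    sw_rec = _round_node(log, "sw_recognized", part.sw * epi.clinical_recognition_sw)
    sw_unrec = part.sw - sw_rec
    deaths = _round_node(log, "sw_deaths", sw_unrec * epi.sw_mortality_unscreened)
    survivors = sw_unrec - deaths
    hosp = hospitalization_block(
        survivors, sw.hosp_rate_unscreened, sw.icu_rate_unscreened, sw.icu_days_unscreened, costs
    )
    log.append(RoundedNode("sw_hospitalized", survivors * sw.hosp_rate_unscreened,
                           hosp.n_hospitalized))
    log.append(RoundedNode("sw_icu", hosp.n_hospitalized * sw.icu_rate_unscreened, hosp.n_icu))

    sv_rec = _round_node(log, "sv_recognized", part.sv * epi.clinical_recognition_sv)
    sv_unrec = part.sv - sv_rec
    therapy = sv_long_term_costs(sv_unrec, sv, costs)
    by_name = {t.therapy: t for t in therapy}
    log.append(RoundedNode("sv_reared_male_46xx",
                           sv_unrec * sv.female_fraction * sv.masculinization_rate,
                           by_name["masculinization"].n_treated))
    log.append(RoundedNode("sv_gh_treated", sv_unrec * sv.gh_use_rate, by_name["GH"].n_treated))
    log.append(RoundedNode("sv_gnrha_treated", sv_unrec * sv.gnrha_use_rate,
                           by_name["GnRHa"].n_treated))

    lab = costs.diagnostic_lab
    items = [
        LineItem("sw_recognized_lab", sw_rec, "lab", to_cents(sw_rec * lab)),
        LineItem("sw_unrecognized_hospitalization", hosp.n_hospitalized, "ward+ICU", hosp.cost),
        LineItem("sw_dehydrated_not_hospitalized_lab", hosp.n_not_hospitalized, "lab",
                 to_cents(hosp.n_not_hospitalized * lab)),
        LineItem("sv_recognized_lab", sv_rec, "lab", to_cents(sv_rec * lab)),
        LineItem("sv_masculinization", by_name["masculinization"].n_treated, "masculinization",
                 by_name["masculinization"].cost),
        LineItem("sv_gh_therapy", by_name["GH"].n_treated, "GH", by_name["GH"].cost),
        LineItem("sv_gnrha_therapy", by_name["GnRHa"].n_treated, "GnRHa", by_name["GnRHa"].cost),
        LineItem("sv_unrecognized_lab", sv_unrec, "lab", by_name["diagnostic_lab"].cost),
    ]
    return ArmLedger("unscreened", items, deaths=deaths, rounded_nodes=log)


def discounted_life_years(
    life_expectancy: float,
    rate: float,
    convention: str = "constant",
    constant_value: float = 30.2,
) -> float:
    """Discounted life-years gained per death averted.

    ``constant`` returns the fixed published value (default 30.2 years for a
    3% rate over 76 years of life expectancy); the annuity conventions compute
    the present value of one life-year per year over the full life expectancy.
    """
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    if life_expectancy <= 0:
        raise ValueError("life_expectancy must be positive")
    if convention == "constant":
        return constant_value
    if convention not in DLY_CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}; valid: {', '.join(DLY_CONVENTIONS)}")
    if rate == 0:
        return float(life_expectancy)
    ordinary = (1.0 - (1.0 + rate) ** -life_expectancy) / rate
    return ordinary * (1.0 + rate) if convention == "annuity_due" else ordinary


def incremental_analysis(
    screened: ArmLedger, unscreened: ArmLedger, discounted_ly: float, label: str = ""
) -> CEAResult:
    """Incremental cost, deaths averted, cost per death averted and ICER."""
    deaths_averted = unscreened.deaths - screened.deaths
    if deaths_averted < 0:
        raise ValueError("deaths averted is negative; arms passed in the wrong order?")
    incremental = screened.total_cost - unscreened.total_cost
    if deaths_averted == 0:
        return CEAResult(label, incremental, 0, discounted_ly, None, None)
    per_death = to_cents(incremental / deaths_averted)
    icer = to_cents(per_death / to_cents(discounted_ly))
    return CEAResult(label, incremental, deaths_averted, discounted_ly, per_death, icer)


def evaluate_scenario(params: ModelParams) -> tuple[ArmLedger, ArmLedger, CEAResult]:
    """Run both arms and the incremental analysis for one parameter set."""
    screened = evaluate_screened_arm(params)
    unscreened = evaluate_unscreened_arm(params)
    result = incremental_analysis(
        screened, unscreened, params.epidemiology.discounted_ly_per_death,
        label=params.scenario_name,
    )
    return screened, unscreened, result


def cost_per_case_detected(arm: ArmLedger, params: ModelParams) -> float:
    """Screening cost per CAH case detected, dividing by the *unrounded*
    expected yearly case count (secondary descriptive statistic)."""
    expected_cases = float(params.epidemiology.live_births * params.epidemiology.cah_incidence)
    return float(arm.total_cost) / expected_cases
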