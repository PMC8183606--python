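"""Birth-cohort partition and the screening false-positive cascade.

Every screened newborn pays at least one filter-paper 17-OHP test (cost
category ``A``). Screen-positive but unaffected newborns enter a recall
cascade: low-risk positives get a filter-paper retest (``2A``, escalating to
``2A+B`` if the retest is again positive), high-risk positives go straight to
serum confirmation plus a specialist consultation (``A+B``, escalating to
``A+2B`` when the first confirmatory work-up stays inconclusive).

Counts are integers: each ``rate x count`` node is rounded half-away-from-zero
and its complement obtained by subtraction, so the split identities hold
exactly (see :mod:`cahscreen._rounding`).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal
from fractions import Fraction

import pandas as pd

from ._rounding import round_half_up, to_cents
from .parameters import ScreeningPerformance, UnitCosts

#: cost-category labels: A = filter-paper screen, B = confirmatory labs + consultation
COST_CATEGORY_LABELS = ("A", "2A", "A+B", "2A+B", "A+2B")


@dataclass(frozen=True)
class CohortPartition:
    """Yearly birth cohort split into affected (SW/SV) and non-affected."""

    live_births: int
    affected: int
    sw: int
    sv: int
    non_affected: int

    def __post_init__(self) -> None:
        if self.sw + self.sv != self.affected:
            raise ValueError("sw + sv must equal affected")
        if self.affected + self.non_affected != self.live_births:
            raise ValueError("affected + non_affected must equal live_births")
        if min(self.affected, self.sw, self.sv, self.non_affected) < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class CascadeCounts:
    """Integer counts at every node of the false-positive recall cascade."""

    non_affected: int
    true_negative: int
    fp_total: int
    fp_high: int
    fp_low: int
    confirm_tn: int
    confirm_fp: int
    retest_tn: int
    retest_fp: int

    def __post_init__(self) -> None:
        checks = (
            self.true_negative + self.fp_total == self.non_affected,
            self.fp_high + self.fp_low == self.fp_total,
            self.confirm_tn + self.confirm_fp == self.fp_high,
            self.retest_tn + self.retest_fp == self.fp_low,
        )
        if not all(checks):
            raise ValueError("cascade conservation identities violated")
        if min(self.true_negative, self.fp_total, self.fp_high, self.fp_low,
               self.confirm_tn, self.confirm_fp, self.retest_tn, self.retest_fp) < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class LineItem:
    """One row of a cost ledger: a labelled count billed at a unit-cost category."""

    label: str
    count: int
    unit_label: str
    cost: Decimal


def partition_birth_cohort(
    live_births: int, incidence: Fraction | float, sw_fraction: float
) -> CohortPartition:
    """Split the yearly birth cohort into SW / SV / non-affected newborns."""
    if live_births < 0:
        raise ValueError("live_births must be >= 0")
    affected = round_half_up(live_births * incidence)
    sw = round_half_up(affected * sw_fraction)
    return CohortPartition(
        live_births=live_births,
        affected=affected,
        sw=sw,
        sv=affected - sw,
        non_affected=live_births - affected,
    )


def run_cascade(non_affected: int, perf: ScreeningPerformance) -> CascadeCounts:
    """Push the non-affected newborns through the false-positive recall cascade.

    Affected newborns are all screen-positive by construction; the model has
    no false negatives, so the first-tier FP rate applies to non-affected
    newborns only.
    """
    if non_affected < 0:
        raise ValueError("non_affected must be >= 0")
    fp_total = round_half_up(non_affected * perf.fp_rate)
    fp_high = round_half_up(fp_total * perf.high_risk_fraction)
    fp_low = fp_total - fp_high
    confirm_tn = round_half_up(fp_high * (1.0 - perf.confirmatory_fp_fraction))
    retest_tn = round_half_up(fp_low * (1.0 - perf.retest_fp_fraction))
    return CascadeCounts(
        non_affected=non_affected,
        true_negative=non_affected - fp_total,
        fp_total=fp_total,
        fp_high=fp_high,
        fp_low=fp_low,
        confirm_tn=confirm_tn,
        confirm_fp=fp_high - confirm_tn,
        retest_tn=retest_tn,
        retest_fp=fp_low - retest_tn,
    )


def category_unit_cost(label: str, costs: UnitCosts) -> Decimal:
    """Per-child cost of a screening cost category, rounded to the cent."""
    a, b = costs.screen_test_A, costs.confirm_consult_B
    try:
        value = {
            "A": a,
            "2A": 2 * a,
            "A+B": a + b,
            "2A+B": 2 * a + b,
            "A+2B": a + 2 * b,
        }[label]
    except KeyError:
        raise ValueError(
            f"unknown cost category {label!r}; valid: {', '.join(COST_CATEGORY_LABELS)}"
        ) from None
    return to_cents(value)


def cascade_costs(counts: CascadeCounts, costs: UnitCosts) -> list[LineItem]:
    """Itemized screening costs of the non-affected cohort, one line per node."""
    spec = (
        ("true_negative", counts.true_negative, "A"),
        ("confirmatory_true_negative", counts.confirm_tn, "A+B"),
        ("confirmatory_false_positive", counts.confirm_fp, "A+2B"),
        ("retest_true_negative", counts.retest_tn, "2A"),
        ("retest_false_positive", counts.retest_fp, "2A+B"),
    )
    return [
        LineItem(label, n, cat, to_cents(n * category_unit_cost(cat, costs)))
        for label, n, cat in spec
    ]


def ledger_to_frame(items: list[LineItem]) -> pd.DataFrame:
    """Cost-ledger lines as a DataFrame (CSV schema: node_label, count,
    unit_cost_label, cost_usd)."""
    return pd.DataFrame(
        [(i.label, i.count, i.unit_label, float(i.cost)) for i in items],
        columns=["node_label", "count", "unit_cost_label", "cost_usd"],
    )
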