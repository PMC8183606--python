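"""Deterministic sensitivity machinery: one-way sweeps, scenario tables, tornado.

Sweeps re-run the full integer-rounded two-arm engine at each tested value
(no linearization), so a parameter swept to its base value returns the
base-case ICER exactly. The published one-way analysis moves four quantities:
CAH incidence, the SW/SV clinical-recognition pair (jointly), SW mortality
without screening, and the first-tier false-positive rate;
:func:`reference_ranges` returns those four ranges.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal
from fractions import Fraction

import numpy as np
import pandas as pd

from .engine import evaluate_scenario
from .parameters import ModelParams, ParamRange

REFERENCE_RANGES = {
    "incidence": ParamRange("epidemiology.cah_incidence",
                            Fraction(1, 15_000), Fraction(1, 10_000)),
    "clinical_recognition": ParamRange(
        ("epidemiology.clinical_recognition_sw", "epidemiology.clinical_recognition_sv"),
        (0.16, 0.11), (0.55, 0.45)),
    "sw_mortality": ParamRange("epidemiology.sw_mortality_unscreened", 0.042, 0.11),
    "fp_rate": ParamRange("screening.fp_rate", 0.001, 0.005),
}


def reference_ranges() -> list[ParamRange]:
    """The four one-way ranges of the published sensitivity analysis."""
    return list(REFERENCE_RANGES.values())


@dataclass(frozen=True)
class OneWayResult:
    """One evaluation point of a one-way sweep."""

    parameter_path: str
    tested_value: tuple
    icer: Decimal | None
    deaths_averted: int
    incremental_cost: Decimal


@dataclass(frozen=True)
class TornadoRow:
    parameter_path: str
    icer_at_low: Decimal | None
    icer_at_high: Decimal | None
    span: Decimal


def _interpolated_values(rng: ParamRange, n_points: int) -> list[tuple]:
    """Evaluation points between low and high inclusive, element-wise for
    paired ranges; exact rationals are preserved at the endpoints."""
    lows, highs = rng.values("low"), rng.values("high")
    ts = np.linspace(0.0, 1.0, n_points)
    points = []
    for t in ts:
        vals = []
        for lo, hi in zip(lows, highs):
            if t == 0.0:
                vals.append(lo)
            elif t == 1.0:
                vals.append(hi)
            else:
                vals.append(float(lo) + t * (float(hi) - float(lo)))
        points.append(tuple(vals))
    return points


def _evaluate_at(base: ModelParams, rng: ParamRange, values: tuple) -> OneWayResult:
    params = base.replace(**dict(zip(rng.paths, values)))
    _, _, res = evaluate_scenario(params)
    return OneWayResult(rng.key, values, res.icer, res.deaths_averted, res.incremental_cost)


def one_way_sweep(
    base: ModelParams, ranges: list[ParamRange], n_points: int = 2
) -> list[OneWayResult]:
    """Evaluate the full CEA at ``n_points`` values across each range, all
    other parameters held at base."""
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    out: list[OneWayResult] = []
    for rng in ranges:
        for values in _interpolated_values(rng, n_points):
            out.append(_evaluate_at(base, rng, values))
    return out


def sweep_to_frame(results: list[OneWayResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter_path": r.parameter_path,
                "tested_value": "|".join(str(float(v)) for v in r.tested_value),
                "icer_usd_per_ly": None if r.icer is None else float(r.icer),
                "deaths_averted": r.deaths_averted,
                "incremental_cost_usd": float(r.incremental_cost),
            }
            for r in results
        ]
    )


def scenario_comparison(scenarios: list[ModelParams]) -> pd.DataFrame:
    """One CEAResult row per named scenario."""
    if not scenarios:
        raise ValueError("need at least one scenario")
    rows = []
    for params in scenarios:
        _, _, res = evaluate_scenario(params)
        rows.append(res.to_dict())
    return pd.DataFrame(rows)


def tornado(base: ModelParams, ranges: list[ParamRange]) -> list[TornadoRow]:
    """Endpoint ICERs per parameter, ordered by descending ICER span
    (ties broken lexically by parameter path)."""
    rows = []
    for rng in ranges:
        lo = _evaluate_at(base, rng, rng.values("low")).icer
        hi = _evaluate_at(base, rng, rng.values("high")).icer
        span = abs(hi - lo) if lo is not None and hi is not None else Decimal("0.00")
        rows.append(TornadoRow(rng.key, lo, hi, span))
    rows.sort(key=lambda r: (-r.span, r.parameter_path))
    return rows


def tornado_to_frame(rows: list[TornadoRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter_path": r.parameter_path,
                "icer_at_low": None if r.icer_at_low is None else float(r.icer_at_low),
                "icer_at_high": None if r.icer_at_high is None else float(r.icer_at_high),
                "span": float(r.span),
            }
            for r in rows
        ]
    )
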