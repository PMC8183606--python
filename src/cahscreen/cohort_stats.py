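"""Patient-level cohort statistics and model-parameter estimators.

The decision model's clinical inputs are derived from two cohorts: an
unscreened (clinically diagnosed) CAH cohort and a newborn-screened one.
This module summarizes patient tables (means with t-based 95% CIs,
proportions with Wilson CIs), compares the two cohorts variable by variable
(Welch t-test for means; chi-square, or Fisher's exact test when any
expected cell is below 5, for proportions), and maps the cohort statistics
onto decision-model parameter fields — optionally averaging with externally
published estimates, as the base-case column does.

"Recognized early" means diagnosed before the salt-wasting crisis for SW
patients, and diagnosed within the first 30 days of life for SV patients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

SV_NEONATAL_WINDOW_DAYS = 30


@dataclass
class PatientRecord:
    """One (real or synthetic) classical-CAH patient."""

    cohort: str  # screened | unscreened
    form: str  # SW | SV
    sex_karyotype: str  # 46XX | 46XY
    birth_group: str  # pre1990 | 1990s | post1999
    recognized_early: bool
    dehydrated: bool
    hospitalized: bool
    icu: bool
    icu_days: float
    sodium: float
    age_at_diagnosis: float
    gh_treated: bool
    gh_years: float
    gnrha_treated: bool
    gnrha_years: float
    reared_male_46xx: bool

    def __post_init__(self) -> None:
        if self.icu and not self.hospitalized:
            raise ValueError("icu implies hospitalized")
        if self.hospitalized and not self.dehydrated:
            raise ValueError("hospitalized implies dehydrated")
        if self.icu_days > 0 and not self.icu:
            raise ValueError("icu_days > 0 requires icu")
        if self.gh_years > 0 and not self.gh_treated:
            raise ValueError("gh_years > 0 requires gh_treated")
        if self.gnrha_years > 0 and not self.gnrha_treated:
            raise ValueError("gnrha_years > 0 requires gnrha_treated")


_FIELDS = [f.name for f in fields(PatientRecord)]
_BOOL_FIELDS = [f.name for f in fields(PatientRecord) if f.type == "bool"]


def records_to_frame(records: Iterable[PatientRecord]) -> pd.DataFrame:
    return pd.DataFrame([[getattr(r, name) for name in _FIELDS] for r in records],
                        columns=_FIELDS)


def frame_to_records(frame: pd.DataFrame) -> list[PatientRecord]:
    return [PatientRecord(**{name: row[name] for name in _FIELDS})
            for _, row in frame.iterrows()]


def read_cohort_csv(path) -> list[PatientRecord]:
    """Read a patient table (one header row of PatientRecord field names;
    missing values as empty cells, coerced to 0 for durations)."""
    frame = pd.read_csv(path)
    missing = set(_FIELDS) - set(frame.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    for name in ("icu_days", "gh_years", "gnrha_years"):
        frame[name] = frame[name].fillna(0.0)
    for name in _BOOL_FIELDS:
        frame[name] = frame[name].astype(bool)
    return frame_to_records(frame)


def write_cohort_csv(records: Iterable[PatientRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


# -- summaries --------------------------------------------------------------


@dataclass(frozen=True)
class MeanCI:
    """Sample mean with a t-based 95% confidence interval (CI requires n >= 2)."""

    n: int
    mean: float
    ci_low: float | None
    ci_high: float | None


@dataclass(frozen=True)
class CohortSummary:
    n: int
    mean_sodium: MeanCI | None
    mean_age_at_diagnosis: MeanCI | None
    prop_hospitalized: float | None
    prop_icu_among_hospitalized: float | None
    mean_icu_days: MeanCI | None
    prop_recognized: float | None
    prop_gh: float | None
    prop_gnrha: float | None


def mean_ci(values: Sequence[float], level: float = 0.95) -> MeanCI | None:
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        return None
    m = float(np.mean(x))
    if x.size < 2:
        return MeanCI(int(x.size), m, None, None)
    half = float(stats.t.ppf(0.5 + level / 2, x.size - 1) * np.std(x, ddof=1) / math.sqrt(x.size))
    return MeanCI(int(x.size), m, m - half, m + half)


def proportion_ci(successes: int, n: int, level: float = 0.95) -> tuple[float, float, float]:
    """Exact fraction with a Wilson score interval."""
    lo, hi = proportion_confint(successes, n, alpha=1 - level, method="wilson")
    return successes / n, float(lo), float(hi)


def _prop(frame: pd.DataFrame, col: str) -> float | None:
    return None if frame.empty else float(frame[col].mean())


def summarize_cohort(
    records: Sequence[PatientRecord], subset: str | None = None
) -> CohortSummary:
    """Summary statistics over ``records``, optionally restricted by a pandas
    query expression (e.g. ``"form == 'SW'"``). Statistics whose subset is
    empty are reported as ``None``, never as zero."""
    frame = records_to_frame(records)
    if subset is not None:
        frame = frame.query(subset)
    hosp = frame[frame["hospitalized"]]
    icu = frame[frame["icu"]]
    return CohortSummary(
        n=len(frame),
        mean_sodium=mean_ci(frame["sodium"]) if len(frame) else None,
        mean_age_at_diagnosis=mean_ci(frame["age_at_diagnosis"]) if len(frame) else None,
        prop_hospitalized=_prop(frame, "hospitalized"),
        prop_icu_among_hospitalized=_prop(hosp, "icu"),
        mean_icu_days=mean_ci(icu["icu_days"]) if len(icu) else None,
        prop_recognized=_prop(frame, "recognized_early"),
        prop_gh=_prop(frame, "gh_treated"),
        prop_gnrha=_prop(frame, "gnrha_treated"),
    )


# -- estimators feeding the decision model ----------------------------------


def estimate_sw_mortality_from_deficit(
    sw_fraction_screened: float, sw_fraction_unscreened: float
) -> float:
    """Unscreened SW mortality estimated as the SW-frequency deficit: the
    screened cohort's SW fraction minus the unscreened cohort's, floored at 0
    (missing SW cases are presumed to have died undiagnosed)."""
    for name, v in (("sw_fraction_screened", sw_fraction_screened),
                    ("sw_fraction_unscreened", sw_fraction_unscreened)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    return max(sw_fraction_screened - sw_fraction_unscreened, 0.0)


def clinical_recognition_rate(records: Sequence[PatientRecord], form: str) -> float:
    """Probability of clinical recognition before symptoms, by form.

    SW: fraction diagnosed before the salt-wasting crisis (1 - crisis rate).
    SV: fraction diagnosed within the first 30 days of life.
    """
    if form not in ("SW", "SV"):
        raise ValueError("form must be 'SW' or 'SV'")
    frame = records_to_frame(records)
    frame = frame[frame["form"] == form]
    if frame.empty:
        raise ValueError(f"no records of form {form}")
    if form == "SW":
        return float(1.0 - frame["dehydrated"].mean())
    return float((frame["age_at_diagnosis"] <= SV_NEONATAL_WINDOW_DAYS).mean())


# -- two-cohort comparison --------------------------------------------------

_MEAN_VARS = {
    "sodium": ("sodium", None),
    "age_at_diagnosis": ("age_at_diagnosis", None),
    "icu_days": ("icu_days", "icu"),  # among ICU-admitted patients only
}
_PROP_VARS = ["dehydrated", "hospitalized", "icu", "recognized_early",
              "gh_treated", "gnrha_treated"]


def _welch_row(a: np.ndarray, b: np.ndarray) -> tuple[float, float, str]:
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p), "welch_t"


def _prop_row(k_a: int, n_a: int, k_b: int, n_b: int) -> tuple[float, float, str]:
    table = np.array([[k_a, n_a - k_a], [k_b, n_b - k_b]])
    if table.min() >= 0 and table.sum(axis=1).min() > 0:
        expected = stats.contingency.expected_freq(table)
        if (expected < 5).any():
            odds, p = stats.fisher_exact(table)
            return float(odds), float(p), "fisher_exact"
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p), "chi_square"


def compare_cohorts(
    a: Sequence[PatientRecord], b: Sequence[PatientRecord], alpha: float = 0.05
) -> pd.DataFrame:
    """Variable-by-variable comparison of two cohorts.

    Means are compared with Welch's unequal-variance t-test, proportions with
    the chi-square test (Fisher's exact test when any expected cell count is
    below 5). Two-sided p-values; ``significant`` flags p < alpha.
    """
    if not a or not b:
        raise ValueError("both cohorts must be non-empty")
    fa, fb = records_to_frame(a), records_to_frame(b)
    rows: list[dict[str, Any]] = []
    for name, (col, gate) in _MEAN_VARS.items():
        xa = fa[fa[gate]][col] if gate else fa[col]
        xb = fb[fb[gate]][col] if gate else fb[col]
        xa, xb = xa.to_numpy(float), xb.to_numpy(float)
        row = {"variable": name, "type": "mean",
               "value_a": float(np.mean(xa)) if xa.size else None,
               "value_b": float(np.mean(xb)) if xb.size else None}
        if xa.size >= 2 and xb.size >= 2:
            stat, p, test = _welch_row(xa, xb)
            row.update(difference=row["value_a"] - row["value_b"],
                       test=test, statistic=stat, p_value=p, significant=p < alpha)
        else:
            row.update(difference=None, test=None, statistic=None,
                       p_value=None, significant=None)
        rows.append(row)
    for name in _PROP_VARS:
        k_a, n_a = int(fa[name].sum()), len(fa)
        k_b, n_b = int(fb[name].sum()), len(fb)
        stat, p, test = _prop_row(k_a, n_a, k_b, n_b)
        rows.append({
            "variable": name, "type": "proportion",
            "value_a": k_a / n_a, "value_b": k_b / n_b,
            "difference": k_a / n_a - k_b / n_b,
            "test": test, "statistic": stat, "p_value": p, "significant": p < alpha,
        })
    return pd.DataFrame(rows)


# -- screened-program descriptive statistics --------------------------------


def screened_incidence_denominator(n_cases: int, n_screened: int) -> int:
    """Incidence expressed as ``1:denominator`` from confirmed cases among
    screened newborns (denominator rounded to the nearest integer)."""
    if n_cases <= 0 or n_screened <= 0:
        raise ValueError("counts must be positive")
    return int(round(n_screened / n_cases))


def first_tier_fp_rate(n_false_positive: int, n_screened: int) -> float:
    """First-tier screen false-positive rate as a proportion."""
    if n_screened <= 0 or n_false_positive < 0:
        raise ValueError("invalid counts")
    return n_false_positive / n_screened


# -- parameter derivation ---------------------------------------------------

_RECENT_GROUPS = ("1990s", "post1999")


def _recent_sw_fraction(frame: pd.DataFrame) -> float:
    """Mean SW fraction over the recent birth groups (per-group average),
    falling back to the whole cohort when no group labels match."""
    recent = frame[frame["birth_group"].isin(_RECENT_GROUPS)]
    if recent.empty:
        recent = frame
        groups = [frame]
    else:
        groups = [g for _, g in recent.groupby("birth_group")]
    return float(np.mean([(g["form"] == "SW").mean() for g in groups]))


def params_from_cohorts(
    unscreened: Sequence[PatientRecord],
    screened: Sequence[PatientRecord],
    averaging_partner: dict[str, float] | None = None,
    assumed_sw_fraction_screened: float = 0.75,
) -> dict[str, float]:
    """Derive decision-model parameter values from the two cohorts.

    Returns a mapping of dotted parameter paths (as accepted by
    ``ModelParams.replace``) to estimates. Where ``averaging_partner``
    supplies an external estimate for a path, the result is the average of
    the cohort value and the partner value; other paths keep the raw cohort
    value. Note the published denominators: the screened hospitalization rate
    is a fraction of all SW patients, the unscreened one a fraction of
    dehydrated patients.
    """
    fu = records_to_frame(unscreened)
    fs = records_to_frame(screened)
    if fu.empty or fs.empty:
        raise ValueError("both cohorts must be non-empty")
    u_sw = fu[fu["form"] == "SW"]
    s_sw = fs[fs["form"] == "SW"]
    u_sw_dehyd = u_sw[u_sw["dehydrated"]]
    u_sw_hosp = u_sw[u_sw["hospitalized"]]
    s_sw_hosp = s_sw[s_sw["hospitalized"]]
    u_sv = fu[fu["form"] == "SV"]

    raw: dict[str, float] = {
        "epidemiology.clinical_recognition_sw": clinical_recognition_rate(unscreened, "SW"),
        "epidemiology.clinical_recognition_sv": clinical_recognition_rate(unscreened, "SV"),
        "epidemiology.sw_mortality_unscreened": estimate_sw_mortality_from_deficit(
            assumed_sw_fraction_screened, _recent_sw_fraction(fu)),
        "sw.hosp_rate_unscreened": float(u_sw_dehyd["hospitalized"].mean())
        if len(u_sw_dehyd) else float("nan"),
        "sw.icu_rate_unscreened": float(u_sw_hosp["icu"].mean())
        if len(u_sw_hosp) else float("nan"),
        "sw.icu_days_unscreened": float(u_sw[u_sw["icu"]]["icu_days"].mean())
        if u_sw["icu"].any() else float("nan"),
        "sw.hosp_rate_screened": float(s_sw["hospitalized"].mean()) if len(s_sw) else float("nan"),
        "sw.icu_rate_screened": float(s_sw_hosp["icu"].mean())
        if len(s_sw_hosp) else float("nan"),
        "sw.icu_days_screened": float(s_sw[s_sw["icu"]]["icu_days"].mean())
        if s_sw["icu"].any() else float("nan"),
        "sv.gh_use_rate": float(u_sv["gh_treated"].mean()) if len(u_sv) else float("nan"),
        "sv.gh_years": float(u_sv[u_sv["gh_treated"]]["gh_years"].mean())
        if u_sv["gh_treated"].any() else float("nan"),
        "sv.gnrha_use_rate": float(u_sv["gnrha_treated"].mean()) if len(u_sv) else float("nan"),
        "sv.gnrha_years": float(u_sv[u_sv["gnrha_treated"]]["gnrha_years"].mean())
        if u_sv["gnrha_treated"].any() else float("nan"),
        "sv.masculinization_rate": float(
            u_sv[u_sv["sex_karyotype"] == "46XX"]["reared_male_46xx"].mean())
        if (u_sv["sex_karyotype"] == "46XX").any() else float("nan"),
    }
    partner = averaging_partner or {}
    return {
        path: (value + partner[path]) / 2.0 if path in partner else value
        for path, value in raw.items()
    }
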