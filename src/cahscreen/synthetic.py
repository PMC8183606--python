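"""Synthetic patient-cohort generator.

Emulates the patient-level structure behind the published cohort summaries so
the estimation and comparison pipeline is testable without hospital records.
Flags follow the conditional chain crisis -> dehydrated -> hospitalized ->
ICU; continuous variables are truncated normals (serum sodium within
100-150 mEq/L, durations positive), with standard deviations back-derived
from printed 95% confidence intervals as half-width x sqrt(n) / t(n-1).

One integer seed drives named independent sub-streams (one per variable), so
adding a variable does not perturb the draws of existing ones. Variables are
generated independently; any real-world correlation between, e.g., sodium and
ICU stay is not reproduced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace

import numpy as np
from scipy import stats

from .cohort_stats import PatientRecord

SODIUM_BOUNDS = (100.0, 150.0)  # mEq/L, physiologic plausibility window
MIN_ICU_DAYS = 1.0
#: SV patients without salt loss: near-normal sodium at diagnosis
SV_SODIUM_MEAN, SV_SODIUM_SD = 138.0, 2.5
#: unrecognized SV cases present years later (precocious pseudo-puberty)
SV_LATE_AGE_MEAN_DAYS, SV_LATE_AGE_SD_DAYS = 5.7 * 365, 730.0

PRESET_NAMES = ("unscreened", "screened", "group3")

# fixed stream indices; append only, never renumber
_STREAMS = {
    "sex": 0,
    "crisis": 1,
    "hospitalized": 2,
    "icu": 3,
    "icu_days": 4,
    "sodium": 5,
    "age_dx": 6,
    "gh_flag": 7,
    "gh_years": 8,
    "gnrha_flag": 9,
    "gnrha_years": 10,
    "reared_male": 11,
    "sv_recognition": 12,
    "sv_sodium": 13,
    "sv_age": 14,
}


def sd_from_ci(half_width: float, n: int, level: float = 0.95) -> float:
    """Back-derive a sample SD from a printed t-based CI half-width."""
    if n < 2:
        raise ValueError("need n >= 2")
    return half_width * math.sqrt(n) / stats.t.ppf(0.5 + level / 2, n - 1)


@dataclass(frozen=True)
class GeneratorTruth:
    """Ground-truth parameters of one synthetic cohort."""

    n_sw: int
    n_sv: int
    cohort: str = "unscreened"
    birth_group: str = "post1999"
    female_fraction_sv: float = 0.74
    crisis_rate_sw: float = 0.84
    hosp_rate_dehydrated: float = 0.91
    icu_rate_hospitalized: float = 0.36
    icu_days_mean: float = 23.0
    icu_days_sd: float = 24.0
    sodium_mean: float = 121.2
    sodium_sd: float = 15.0
    age_dx_mean: float = 38.8
    age_dx_sd: float = 39.0
    sv_recognition_rate: float = 0.11
    gh_rate: float = 0.14
    gh_years_mean: float = 3.2
    gh_years_sd: float = 1.3
    gnrha_rate: float = 0.28
    gnrha_years_mean: float = 3.8
    gnrha_years_sd: float = 1.7
    reared_male_rate_46xx: float = 0.15
    seed: int = 0

    _PROPORTIONS = ("female_fraction_sv", "crisis_rate_sw", "hosp_rate_dehydrated",
                    "icu_rate_hospitalized", "sv_recognition_rate", "gh_rate",
                    "gnrha_rate", "reared_male_rate_46xx")

    def __post_init__(self) -> None:
        for name in ("n_sw", "n_sv"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer")
        for name in self._PROPORTIONS:
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for f in fields(self):
            if f.name.endswith("_sd") and getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be >= 0")


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                        spawn_key=(_STREAMS[stream],)))


def _truncnorm(
    rng: np.random.Generator, n: int, mean: float, sd: float,
    lower: float = -np.inf, upper: float = np.inf,
) -> np.ndarray:
    if n == 0:
        return np.empty(0)
    if sd == 0:
        return np.full(n, float(np.clip(mean, lower, upper)))
    a, b = (lower - mean) / sd, (upper - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def generate_cohort(truth: GeneratorTruth) -> list[PatientRecord]:
    """Draw a reproducible synthetic cohort of SW and SV patients."""
    t = truth
    records: list[PatientRecord] = []

    # SW pathway: crisis -> hospitalized -> ICU
    n = t.n_sw
    dehydrated = _rng(t.seed, "crisis").random(n) < t.crisis_rate_sw
    hospitalized = dehydrated & (_rng(t.seed, "hospitalized").random(n) < t.hosp_rate_dehydrated)
    icu = hospitalized & (_rng(t.seed, "icu").random(n) < t.icu_rate_hospitalized)
    icu_days = np.zeros(n)
    icu_days[icu] = _truncnorm(_rng(t.seed, "icu_days"), int(icu.sum()),
                               t.icu_days_mean, t.icu_days_sd, lower=MIN_ICU_DAYS)
    sodium = _truncnorm(_rng(t.seed, "sodium"), n, t.sodium_mean, t.sodium_sd, *SODIUM_BOUNDS)
    age = _truncnorm(_rng(t.seed, "age_dx"), n, t.age_dx_mean, t.age_dx_sd, lower=0.0)
    female = _rng(t.seed, "sex").random(n + t.n_sv) < t.female_fraction_sv
    for i in range(n):
        records.append(PatientRecord(
            cohort=t.cohort, form="SW",
            sex_karyotype="46XX" if female[i] else "46XY",
            birth_group=t.birth_group,
            recognized_early=not dehydrated[i],
            dehydrated=bool(dehydrated[i]),
            hospitalized=bool(hospitalized[i]),
            icu=bool(icu[i]),
            icu_days=float(icu_days[i]),
            sodium=float(sodium[i]),
            age_at_diagnosis=float(age[i]),
            gh_treated=False, gh_years=0.0,
            gnrha_treated=False, gnrha_years=0.0,
            reared_male_46xx=False,
        ))

    # SV pathway: recognition window, long-term therapies, sex misassignment
    m = t.n_sv
    recognized = _rng(t.seed, "sv_recognition").random(m) < t.sv_recognition_rate
    gh = _rng(t.seed, "gh_flag").random(m) < t.gh_rate
    gnrha = _rng(t.seed, "gnrha_flag").random(m) < t.gnrha_rate
    gh_years = np.zeros(m)
    gh_years[gh] = _truncnorm(_rng(t.seed, "gh_years"), int(gh.sum()),
                              t.gh_years_mean, t.gh_years_sd, lower=0.1)
    gnrha_years = np.zeros(m)
    gnrha_years[gnrha] = _truncnorm(_rng(t.seed, "gnrha_years"), int(gnrha.sum()),
                                    t.gnrha_years_mean, t.gnrha_years_sd, lower=0.1)
    sv_sodium = _truncnorm(_rng(t.seed, "sv_sodium"), m, SV_SODIUM_MEAN, SV_SODIUM_SD,
                           *SODIUM_BOUNDS)
    # age consistent with the 30-day recognition window
    age_early = _rng(t.seed, "sv_age").uniform(1.0, 30.0, size=m)
    age_late = _truncnorm(_rng(t.seed, "sv_age"), m, SV_LATE_AGE_MEAN_DAYS,
                          SV_LATE_AGE_SD_DAYS, lower=31.0)
    reared = _rng(t.seed, "reared_male").random(m) < t.reared_male_rate_46xx
    sv_female = female[n:]
    for j in range(m):
        is_female = bool(sv_female[j])
        records.append(PatientRecord(
            cohort=t.cohort, form="SV",
            sex_karyotype="46XX" if is_female else "46XY",
            birth_group=t.birth_group,
            recognized_early=bool(recognized[j]),
            dehydrated=False, hospitalized=False, icu=False, icu_days=0.0,
            sodium=float(sv_sodium[j]),
            age_at_diagnosis=float(age_early[j] if recognized[j] else age_late[j]),
            gh_treated=bool(gh[j]), gh_years=float(gh_years[j]),
            gnrha_treated=bool(gnrha[j]), gnrha_years=float(gnrha_years[j]),
            reared_male_46xx=bool(reared[j] and is_female and not recognized[j]),
        ))
    return records


def paper_truth_presets(which: str, seed: int = 0) -> GeneratorTruth:
    """Generator truths mirroring the published cohort summaries.

    ``unscreened``: the full clinically diagnosed cohort (105 SW / 90 SV);
    ``screened``: the one-year screened cohort (19 SW / 6 SV under a 75% SW
    split of 25 cases); ``group3``: the post-1999 unscreened subcohort
    (23 SW / 10 SV). SDs are back-derived from the printed CIs with
    :func:`sd_from_ci` at the relevant subgroup sizes.
    """
    if which == "unscreened":
        return GeneratorTruth(
            n_sw=105, n_sv=90, cohort="unscreened", birth_group="post1999",
            female_fraction_sv=0.74,
            crisis_rate_sw=0.84, hosp_rate_dehydrated=0.91, icu_rate_hospitalized=0.36,
            icu_days_mean=23.0, icu_days_sd=sd_from_ci(9.45, 29),
            sodium_mean=121.2, sodium_sd=sd_from_ci(2.9, 105),
            age_dx_mean=38.8, age_dx_sd=sd_from_ci(7.65, 105),
            sv_recognition_rate=0.11,
            gh_rate=0.14, gh_years_mean=3.2, gh_years_sd=sd_from_ci(0.8, 13),
            gnrha_rate=0.28, gnrha_years_mean=3.8, gnrha_years_sd=sd_from_ci(0.71, 25),
            reared_male_rate_46xx=0.15, seed=seed,
        )
    if which == "screened":
        return GeneratorTruth(
            n_sw=19, n_sv=6, cohort="screened", birth_group="post1999",
            female_fraction_sv=0.60,
            crisis_rate_sw=12 / 19, hosp_rate_dehydrated=11 / 12, icu_rate_hospitalized=0.30,
            icu_days_mean=9.0, icu_days_sd=sd_from_ci(7.2, 3),
            sodium_mean=131.8, sodium_sd=sd_from_ci(2.6, 12),
            age_dx_mean=17.2, age_dx_sd=sd_from_ci(6.0, 25),
            sv_recognition_rate=1.0,
            gh_rate=0.0, gh_years_mean=0.0, gh_years_sd=0.0,
            gnrha_rate=0.0, gnrha_years_mean=0.0, gnrha_years_sd=0.0,
            reared_male_rate_46xx=0.0, seed=seed,
        )
    if which == "group3":
        return GeneratorTruth(
            n_sw=23, n_sv=10, cohort="unscreened", birth_group="post1999",
            female_fraction_sv=0.90,
            crisis_rate_sw=20 / 23, hosp_rate_dehydrated=18 / 20, icu_rate_hospitalized=0.61,
            icu_days_mean=20.0, icu_days_sd=sd_from_ci(13.8, 11),
            sodium_mean=121.2, sodium_sd=sd_from_ci(2.9, 105),
            age_dx_mean=38.8, age_dx_sd=sd_from_ci(7.65, 105),
            sv_recognition_rate=0.11,
            gh_rate=0.40, gh_years_mean=3.9, gh_years_sd=sd_from_ci(1.645, 13),
            gnrha_rate=0.30, gnrha_years_mean=5.1, gnrha_years_sd=sd_from_ci(2.1, 10),
            reared_male_rate_46xx=0.11, seed=seed,
        )
    raise ValueError(f"unknown preset {which!r}; valid names: {', '.join(PRESET_NAMES)}")


def with_size(truth: GeneratorTruth, n_sw: int | None = None, n_sv: int | None = None,
              seed: int | None = None) -> GeneratorTruth:
    """Copy of a truth with a different cohort size and/or seed."""
    updates = {}
    if n_sw is not None:
        updates["n_sw"] = n_sw
    if n_sv is not None:
        updates["n_sv"] = n_sv
    if seed is not None:
        updates["seed"] = seed
    return replace(truth, **updates)
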