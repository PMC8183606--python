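"""Model parameters for the CAH newborn-screening cost-effectiveness model.

The decision model compares two strategies on a yearly birth cohort: neonatal
17-OHP screening (NBS) versus clinical diagnosis alone. All inputs live in one
validated :class:`ModelParams` composite — epidemiology, screening test
performance, the salt-wasting (SW) hospitalization pathway, the simple
virilizing (SV) long-term therapy pathway, and public-health-system unit
costs in US$. Three named presets (``base``, ``best``, ``worst``) ship as
package data, plus an alternative set (``group3_2000``) derived from the most
recent unscreened birth cohort.

Incidence is stored as an exact rational (e.g. 1/12,250) so that, for
instance, ``2,923,535 x 1/12,250`` rounds without decimal drift.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field, fields
from fractions import Fraction
from importlib import resources
from typing import Any

import yaml

PRESET_NAMES = ("base", "best", "worst", "group3_2000")
#: presets that correspond to the three scenario columns of the published model
SCENARIO_NAMES = ("base", "best", "worst")


def parse_incidence(value: Any) -> Fraction:
    """Coerce an incidence given as ``'1/12250'``, ``'1:12250'``, a number,
    or a Fraction into an exact :class:`~fractions.Fraction`."""
    if isinstance(value, Fraction):
        return value
    if isinstance(value, str):
        for sep in ("/", ":"):
            if sep in value:
                num, den = value.split(sep)
                return Fraction(int(num.strip()), int(den.strip()))
        return Fraction(value)
    if isinstance(value, int):
        return Fraction(value)
    # float: recover the intended simple rational (1/12250 survives round-trip)
    return Fraction(value).limit_denominator(10_000_000)


def _check_unit(name: str, value: float) -> None:
    if not 0.0 <= float(value) <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


def _check_nonneg(name: str, value: float) -> None:
    if float(value) < 0:
        raise ValueError(f"{name} must be >= 0, got {value!r}")


@dataclass
class EpidemiologyParams:
    """Cohort size, disease frequency, recognition and mortality assumptions."""

    live_births: int
    cah_incidence: Fraction
    sw_fraction: float
    clinical_recognition_sw: float
    clinical_recognition_sv: float
    sw_mortality_unscreened: float
    life_expectancy_years: float = 76.0
    discount_rate: float = 0.03
    discounted_ly_per_death: float = 30.2

    def __post_init__(self) -> None:
        self.cah_incidence = parse_incidence(self.cah_incidence)
        if self.live_births < 0 or self.live_births != int(self.live_births):
            raise ValueError(f"live_births must be a non-negative integer, got {self.live_births!r}")
        self.live_births = int(self.live_births)
        if self.cah_incidence <= 0:
            raise ValueError("cah_incidence must be positive")
        for name in ("sw_fraction", "clinical_recognition_sw", "clinical_recognition_sv",
                     "sw_mortality_unscreened", "discount_rate"):
            _check_unit(name, getattr(self, name))
        if self.life_expectancy_years <= 0:
            raise ValueError("life_expectancy_years must be positive")
        if self.discounted_ly_per_death <= 0:
            raise ValueError("discounted_ly_per_death must be positive")


@dataclass
class ScreeningPerformance:
    """First-tier false-positive rate and the recall-cascade split fractions."""

    fp_rate: float
    high_risk_fraction: float
    low_risk_fraction: float
    confirmatory_fp_fraction: float
    retest_fp_fraction: float

    def __post_init__(self) -> None:
        for f in fields(self):
            _check_unit(f.name, getattr(self, f.name))
        if abs(self.high_risk_fraction + self.low_risk_fraction - 1.0) > 1e-9:
            raise ValueError("high_risk_fraction + low_risk_fraction must equal 1")


@dataclass
class SWPathwayParams:
    """Salt-wasting crisis pathway: hospitalization/ICU rates and ICU stay, by arm."""

    hosp_rate_screened: float
    icu_rate_screened: float
    icu_days_screened: float
    hosp_rate_unscreened: float
    icu_rate_unscreened: float
    icu_days_unscreened: float

    def __post_init__(self) -> None:
        for name in ("hosp_rate_screened", "icu_rate_screened",
                     "hosp_rate_unscreened", "icu_rate_unscreened"):
            _check_unit(name, getattr(self, name))
        for name in ("icu_days_screened", "icu_days_unscreened"):
            _check_nonneg(name, getattr(self, name))


@dataclass
class SVPathwayParams:
    """Simple-virilizing late-diagnosis pathway: GH/GnRHa therapy and sex misassignment."""

    gh_use_rate: float
    gh_years: float
    gh_dose_ui_per_day: float
    female_fraction: float
    masculinization_rate: float
    gnrha_use_rate: float
    gnrha_years: float

    def __post_init__(self) -> None:
        for name in ("gh_use_rate", "female_fraction", "masculinization_rate", "gnrha_use_rate"):
            _check_unit(name, getattr(self, name))
        for name in ("gh_years", "gh_dose_ui_per_day", "gnrha_years"):
            _check_nonneg(name, getattr(self, name))


@dataclass
class UnitCosts:
    """Public-health-system (SUS) reimbursement values, US$."""

    ward_hospitalization: float
    icu_day: float
    screen_test_A: float
    confirm_consult_B: float
    gh_ampoule_price: float
    gh_ampoule_ui: float
    gnrha_ampoule_price: float
    masculinization: float
    diagnostic_lab: float

    def __post_init__(self) -> None:
        for f in fields(self):
            _check_nonneg(f.name, getattr(self, f.name))


@dataclass
class ModelParams:
    """One complete scenario column of the decision model."""

    epidemiology: EpidemiologyParams
    screening: ScreeningPerformance
    sw: SWPathwayParams
    sv: SVPathwayParams
    costs: UnitCosts
    scenario_name: str = "custom"

    _BLOCKS = {
        "epidemiology": EpidemiologyParams,
        "screening": ScreeningPerformance,
        "sw": SWPathwayParams,
        "sv": SVPathwayParams,
        "costs": UnitCosts,
    }

    def __post_init__(self) -> None:
        for name, cls in self._BLOCKS.items():
            value = getattr(self, name)
            if isinstance(value, dict):
                setattr(self, name, cls(**value))
            elif not isinstance(value, cls):
                raise ValueError(f"{name} must be a {cls.__name__} or mapping")

    # -- field-path plumbing ------------------------------------------------

    def get(self, path: str) -> Any:
        """Return the scalar at a dotted field path, e.g. ``'sw.icu_days_unscreened'``."""
        obj: Any = self
        for part in path.split("."):
            if not hasattr(obj, part):
                raise KeyError(f"unresolvable parameter path: {path!r}")
            obj = getattr(obj, part)
        return obj

    def replace(self, **updates: Any) -> "ModelParams":
        """Copy with dotted-path scalar updates; re-validates every block."""
        new = copy.deepcopy(self)
        for path, value in updates.items():
            parts = path.split(".")
            obj: Any = new
            for part in parts[:-1]:
                if not hasattr(obj, part):
                    raise KeyError(f"unresolvable parameter path: {path!r}")
                obj = getattr(obj, part)
            if not hasattr(obj, parts[-1]):
                raise KeyError(f"unresolvable parameter path: {path!r}")
            setattr(obj, parts[-1], value)
        # re-run validation on each block
        for name, cls in self._BLOCKS.items():
            block = getattr(new, name)
            setattr(new, name, cls(**{f.name: getattr(block, f.name) for f in fields(cls)}))
        return new

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {"scenario_name": self.scenario_name}
        for name, cls in self._BLOCKS.items():
            block = getattr(self, name)
            d = {f.name: getattr(block, f.name) for f in fields(cls)}
            if name == "epidemiology":
                inc = d["cah_incidence"]
                d["cah_incidence"] = f"{inc.numerator}/{inc.denominator}"
            out[name] = d
        return out

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)


@dataclass(frozen=True)
class ParamRange:
    """A one-way sensitivity range for one scalar (or a jointly-moved tuple of
    scalars, e.g. the SW/SV clinical-recognition pair)."""

    parameter_path: str | tuple[str, ...]
    low: Any
    high: Any

    def __post_init__(self) -> None:
        if isinstance(self.parameter_path, (list, tuple)):
            object.__setattr__(self, "parameter_path", tuple(self.parameter_path))
            object.__setattr__(self, "low", tuple(self.low))
            object.__setattr__(self, "high", tuple(self.high))
            if len({len(self.parameter_path), len(self.low), len(self.high)}) != 1:
                raise ValueError("paired range: paths, lows and highs must have equal length")
            ok = all(lo <= hi for lo, hi in zip(self.low, self.high))
        else:
            ok = self.low <= self.high
        if not ok:
            raise ValueError("ParamRange requires low <= high (element-wise for paired ranges)")

    @property
    def paths(self) -> tuple[str, ...]:
        p = self.parameter_path
        return p if isinstance(p, tuple) else (p,)

    def values(self, which: str) -> tuple[Any, ...]:
        if which not in ("low", "high"):
            raise ValueError("which must be 'low' or 'high'")
        v = self.low if which == "low" else self.high
        return v if isinstance(v, tuple) else (v,)

    @property
    def key(self) -> str:
        return "+".join(self.paths)


def apply_range(params: ModelParams, rng: ParamRange, which: str) -> ModelParams:
    """Copy of *params* with the range's parameter(s) set to its low or high end."""
    updates = dict(zip(rng.paths, rng.values(which)))
    for path in updates:
        params.get(path)  # raise KeyError early on a bad path
    return params.replace(**updates)


# -- presets ----------------------------------------------------------------


def _read_preset_text(name: str) -> str:
    return (resources.files("cahscreen") / "presets" / f"{name}.yaml").read_text()


def preset(scenario: str) -> ModelParams:
    """The full parameter column for a named scenario.

    ``base``, ``best`` and ``worst`` are the three published scenario columns;
    ``group3_2000`` carries the inputs re-derived from the post-1999 unscreened
    birth cohort.
    """
    if scenario not in PRESET_NAMES:
        raise ValueError(
            f"unknown scenario {scenario!r}; valid names: {', '.join(PRESET_NAMES)}"
        )
    doc = yaml.safe_load(_read_preset_text(scenario))
    doc.pop("scenario", None)
    return ModelParams(**doc)


def _deep_update(base: dict, overrides: dict, prefix: str = "") -> None:
    for key, value in overrides.items():
        where = f"{prefix}{key}"
        if key not in base:
            raise ValueError(f"unknown parameter key: {where!r}")
        if isinstance(value, dict):
            if not isinstance(base[key], dict):
                raise ValueError(f"{where!r} is a scalar, got a mapping")
            _deep_update(base[key], value, prefix=where + ".")
        else:
            base[key] = value


def load_params(config_text: str) -> ModelParams:
    """Load a parameter configuration document (YAML).

    A ``scenario:`` key selects a preset; any other keys are (possibly nested)
    overrides applied on top of it. Without a ``scenario`` key the document
    must specify all five parameter blocks. Unknown keys are rejected by name;
    invariant violations name the offending field.
    """
    doc = yaml.safe_load(config_text)
    if not isinstance(doc, dict):
        raise ValueError("parameter config must be a mapping")
    doc = dict(doc)
    scenario = doc.pop("scenario", None)
    if scenario is not None:
        base = preset(scenario).to_dict()
        name = doc.pop("scenario_name", base["scenario_name"])
        _deep_update(base, doc)
        base["scenario_name"] = name
        return ModelParams(**base)
    known = set(ModelParams._BLOCKS) | {"scenario_name"}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    missing = set(ModelParams._BLOCKS) - set(doc)
    if missing:
        raise ValueError(
            f"missing parameter blocks {sorted(missing)}; add a 'scenario:' key to default them"
        )
    return ModelParams(**doc)
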