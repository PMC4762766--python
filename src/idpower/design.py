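"""Scenario definition, disease presets, and baseline-hazard calibration.

A :class:`Scenario` fully specifies one simulation cell: the cohort design
(size, entry ages, follow-up, visit schedule, loss to follow-up), the two
binary risk exposures and their misclassification rates, the log hazard
ratios acting on the healthy->diseased transition, the log-normal frailty,
the Weibull transition parameters, and the significance level.

Disease presets encode published Weibull fits to Canadian incidence and
mortality for three diseases spanning fast, slow and very slow progression:

================  =====  =====  ===================
disease           scale  shape  baseline prevalence
================  =====  =====  ===================
diabetes             65    2.0  0.14
dementia             48    5.6  0.02
parkinsons          130    3.3  0.02
================  =====  =====  ===================

with healthy->dead fixed at scale 42, shape 4.3 for all three.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .truncweibull import TransitionSet, WeibullParams

__all__ = [
    "CohortDesign",
    "ExposureSpec",
    "EffectSpec",
    "FrailtySpec",
    "DiseasePreset",
    "Scenario",
    "DEATH_PARAMS",
    "DISEASE_PRESETS",
    "make_preset",
    "calibrate_baseline_multiplier",
    "expected_prevalent_cases",
    "load_scenario",
    "save_scenario",
    "scenario_from_dict",
    "scenario_to_dict",
]

CONTINUOUS = "continuous"

#: healthy -> dead transition, shared by every disease preset
DEATH_PARAMS = WeibullParams(scale=42.0, shape=4.3)


class ConfigError(ValueError):
    """Raised for invalid or unknown scenario configuration."""


@dataclass(frozen=True)
class CohortDesign:
    """Cohort size, entry-age distribution, follow-up and observation schedule.

    ``visit_interval_years`` may be the string ``"continuous"`` for exact
    event-time ascertainment, or a positive number of years between panel
    visits (disease status checked at entry and every interval thereafter).
    ``ltfu_rate`` is the instantaneous loss-to-follow-up rate per year.
    """

    n_subjects: int
    entry_age_min: float = 45.0
    entry_age_max: float = 85.0
    entry_age_distribution: str = "uniform"
    followup_years: float = 21.0
    visit_interval_years: float | str = 3.0
    ltfu_rate: float = 0.005

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise ConfigError("n_subjects must be >= 0")
        if not self.entry_age_min < self.entry_age_max:
            raise ConfigError("entry_age_min must be < entry_age_max")
        if self.entry_age_distribution != "uniform":
            raise ConfigError(
                f"unsupported entry_age_distribution {self.entry_age_distribution!r}"
            )
        if not self.followup_years > 0:
            raise ConfigError("followup_years must be > 0")
        if isinstance(self.visit_interval_years, str):
            if self.visit_interval_years != CONTINUOUS:
                raise ConfigError(
                    "visit_interval_years must be a positive number or 'continuous'"
                )
        elif not self.visit_interval_years > 0:
            raise ConfigError("visit_interval_years must be > 0")

    @property
    def is_continuous(self) -> bool:
        return self.visit_interval_years == CONTINUOUS


@dataclass(frozen=True)
class ExposureSpec:
    """Prevalences and non-differential misclassification rates of the two exposures."""

    prevalence_env: float
    prevalence_gen: float
    misclass_env: float = 0.0
    misclass_gen: float = 0.0

    def __post_init__(self) -> None:
        for name in ("prevalence_env", "prevalence_gen"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for name in ("misclass_env", "misclass_gen"):
            v = getattr(self, name)
            if not 0 <= v < 0.5:
                raise ConfigError(f"{name} must be in [0, 0.5), got {v}")


@dataclass(frozen=True)
class EffectSpec:
    """Log hazard ratios for the environmental, genetic and interaction effects."""

    beta_env: float = 0.0
    beta_gen: float = 0.0
    beta_gxe: float = 0.0

    def __post_init__(self) -> None:
        for name in ("beta_env", "beta_gen", "beta_gxe"):
            if not math.isfinite(getattr(self, name)):
                raise ConfigError(f"{name} must be finite")


@dataclass(frozen=True)
class FrailtySpec:
    """Log-normal frailty: a Normal(0, sd^2) term added to the log hazard.

    The default sd of 0.585 encodes a 10-fold ratio in baseline risk between
    individuals at the 97.5th and 2.5th population percentiles,
    exp(2 * 1.96 * 0.585) ~ 9.9.
    """

    sd: float = 0.585

    def __post_init__(self) -> None:
        if not self.sd >= 0:
            raise ConfigError("frailty sd must be >= 0")


@dataclass(frozen=True)
class DiseasePreset:
    """Published transition parameters and baseline prevalence for one disease."""

    label: str
    transitions: TransitionSet
    baseline_prevalence: float


DISEASE_PRESETS: dict[str, DiseasePreset] = {
    "diabetes": DiseasePreset(
        "diabetes",
        TransitionSet(WeibullParams(65.0, 2.0), DEATH_PARAMS),
        baseline_prevalence=0.14,
    ),
    "dementia": DiseasePreset(
        "dementia",
        TransitionSet(WeibullParams(48.0, 5.6), DEATH_PARAMS),
        baseline_prevalence=0.02,
    ),
    "parkinsons": DiseasePreset(
        "parkinsons",
        TransitionSet(WeibullParams(130.0, 3.3), DEATH_PARAMS),
        baseline_prevalence=0.02,
    ),
}


def make_preset(disease_label: str) -> DiseasePreset:
    """Return the published parameter preset for ``disease_label``."""
    try:
        return DISEASE_PRESETS[disease_label]
    except KeyError:
        raise KeyError(
            f"unknown disease {disease_label!r}; known: {sorted(DISEASE_PRESETS)}"
        ) from None


@dataclass(frozen=True)
class Scenario:
    """Complete specification of one simulation cell."""

    design: CohortDesign
    exposures: ExposureSpec
    effects: EffectSpec
    transitions: TransitionSet
    disease_label: str = ""
    frailty: FrailtySpec = field(default_factory=FrailtySpec)
    alpha: float = 0.05
    #: target marginal Weibull scale for the 1->2 transition; the baseline
    #: hazard is calibrated so the population-average hazard matches this
    #: scale.  Defaults to the transition-set scale.
    population_scale_12: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if self.population_scale_12 is None:
            object.__setattr__(
                self, "population_scale_12", self.transitions.healthy_to_diseased.scale
            )
        elif not self.population_scale_12 > 0:
            raise ConfigError("population_scale_12 must be > 0")

    def replace(self, **kwargs: Any) -> "Scenario":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_preset(cls, disease_label: str, **kwargs: Any) -> "Scenario":
        """Build a scenario from a disease preset plus overrides.

        ``design`` defaults to the 30,000-subject, 21-year, 3-yearly-visit
        cohort; exposures and effects must be supplied or default to
        prevalence 0.1 with no misclassification and null effects.
        """
        preset = make_preset(disease_label)
        kwargs.setdefault("design", CohortDesign(n_subjects=30_000))
        kwargs.setdefault("exposures", ExposureSpec(0.1, 0.1))
        kwargs.setdefault("effects", EffectSpec())
        return cls(
            transitions=preset.transitions, disease_label=disease_label, **kwargs
        )


def calibrate_baseline_multiplier(scenario: Scenario) -> float:
    """Population-average hazard multiplier E[exp(bE*xE + bG*xG + bGxE*xE*xG + f)].

    The simulator divides each subject's hazard multiplier by this constant so
    that the population-average 1->2 hazard equals the preset (marginal)
    Weibull hazard.  With independent Bernoulli exposures and Normal(0, sd^2)
    frailty the expectation has a closed form: a sum over the four exposure
    cells times the log-normal mean exp(sd^2/2).
    """
    ex, ef = scenario.exposures, scenario.effects
    pe, pg = ex.prevalence_env, ex.prevalence_gen
    cells = (
        (1 - pe) * (1 - pg)
        + pe * (1 - pg) * math.exp(ef.beta_env)
        + (1 - pe) * pg * math.exp(ef.beta_gen)
        + pe * pg * math.exp(ef.beta_env + ef.beta_gen + ef.beta_gxe)
    )
    return cells * math.exp(scenario.frailty.sd**2 / 2)


def expected_prevalent_cases(design: CohortDesign, preset: DiseasePreset) -> float:
    """Expected number of prevalent cases at baseline: n * baseline prevalence."""
    return design.n_subjects * preset.baseline_prevalence


# ---------------------------------------------------------------------------
# configuration (de)serialization


def _from_mapping(cls, data: Mapping[str, Any], path: str):
    if not isinstance(data, Mapping):
        raise ConfigError(f"{path}: expected a mapping, got {type(data).__name__}")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
    try:
        return cls(**data)
    except ConfigError as exc:
        raise ConfigError(f"{path}: {exc}") from None


def scenario_from_dict(data: Mapping[str, Any]) -> Scenario:
    """Build a Scenario from a plain mapping (parsed YAML/JSON).

    Either ``disease`` names a preset, or ``transitions`` gives explicit
    scale/shape pairs for both transitions.  Unknown keys anywhere are
    rejected.
    """
    if not isinstance(data, Mapping):
        raise ConfigError("scenario config must be a mapping")
    known = {
        "disease",
        "transitions",
        "design",
        "exposures",
        "effects",
        "frailty",
        "alpha",
        "population_scale_12",
    }
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown top-level keys {sorted(unknown)}")

    if ("disease" in data) == ("transitions" in data):
        raise ConfigError("exactly one of 'disease' or 'transitions' is required")
    if "disease" in data:
        label = data["disease"]
        try:
            transitions = make_preset(label).transitions
        except KeyError as exc:
            raise ConfigError(str(exc)) from None
    else:
        tr = data["transitions"]
        if not isinstance(tr, Mapping) or set(tr) != {
            "healthy_to_diseased",
            "healthy_to_dead",
        }:
            raise ConfigError(
                "transitions must map 'healthy_to_diseased' and 'healthy_to_dead' "
                "to {scale, shape}"
            )
        label = str(data.get("disease", "custom"))

        def _wp(key: str) -> WeibullParams:
            sub = tr[key]
            if not isinstance(sub, Mapping) or set(sub) != {"scale", "shape"}:
                raise ConfigError(f"transitions.{key} must have keys scale, shape")
            try:
                return WeibullParams(float(sub["scale"]), float(sub["shape"]))
            except ValueError as exc:
                raise ConfigError(f"transitions.{key}: {exc}") from None

        transitions = TransitionSet(_wp("healthy_to_diseased"), _wp("healthy_to_dead"))
        label = "custom"

    kwargs: dict[str, Any] = {"transitions": transitions, "disease_label": label}
    if "design" in data:
        kwargs["design"] = _from_mapping(CohortDesign, data["design"], "design")
    else:
        raise ConfigError("design section is required")
    if "exposures" in data:
        kwargs["exposures"] = _from_mapping(ExposureSpec, data["exposures"], "exposures")
    else:
        raise ConfigError("exposures section is required")
    kwargs["effects"] = _from_mapping(EffectSpec, data.get("effects", {}), "effects")
    kwargs["frailty"] = _from_mapping(FrailtySpec, data.get("frailty", {}), "frailty")
    if "alpha" in data:
        kwargs["alpha"] = float(data["alpha"])
    if "population_scale_12" in data:
        kwargs["population_scale_12"] = float(data["population_scale_12"])
    return Scenario(**kwargs)


def scenario_to_dict(scenario: Scenario) -> dict[str, Any]:
    """Serialize a Scenario to a plain dict that round-trips via scenario_from_dict."""
    tw = scenario.transitions
    out: dict[str, Any] = {
        "transitions": {
            "healthy_to_diseased": {
                "scale": tw.healthy_to_diseased.scale,
                "shape": tw.healthy_to_diseased.shape,
            },
            "healthy_to_dead": {
                "scale": tw.healthy_to_dead.scale,
                "shape": tw.healthy_to_dead.shape,
            },
        },
        "design": dataclasses.asdict(scenario.design),
        "exposures": dataclasses.asdict(scenario.exposures),
        "effects": dataclasses.asdict(scenario.effects),
        "frailty": dataclasses.asdict(scenario.frailty),
        "alpha": scenario.alpha,
        "population_scale_12": scenario.population_scale_12,
    }
    # prefer the preset spelling when the parameters are exactly the preset's
    label = scenario.disease_label
    if label in DISEASE_PRESETS and DISEASE_PRESETS[label].transitions == tw:
        del out["transitions"]
        out["disease"] = label
    return out


def load_scenario(path: str | Path) -> Scenario:
    """Load a scenario from a YAML (or JSON) configuration file."""
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"could not parse {path}: {exc}") from None
    return scenario_from_dict(data)


def save_scenario(scenario: Scenario, path: str | Path) -> None:
    path = Path(path)
    data = scenario_to_dict(scenario)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))
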