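"""Domain types and config I/O for the Swiss pork AHLE model.

Scenario parameter sets (Average, Top10, Ideal), the reconstructed price
book, population counts and the simulation/sensitivity settings are read
from a single strict YAML config.  Percentages are stored as fractions in
[0, 1]; all monetary values are CHF.  Uncertain Ideal-scenario inputs are
min/mode/max PERT triples.
"""

from __future__ import annotations

import math
from enum import Enum
from pathlib import Path
from typing import Any, Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

__all__ = [
    "ScenarioName",
    "Principle",
    "PertSpec",
    "ParameterValue",
    "BreedingParameters",
    "FatteningParameters",
    "PriceBook",
    "PopulationCounts",
    "ScenarioSet",
    "SimulationSettings",
    "SensitivitySettings",
    "AnalysisConfig",
    "ConfigError",
    "load_scenario_config",
    "save_scenario_config",
    "validate_scenario_set",
    "validate_config",
    "scenario_to_csv",
]


class ConfigError(ValueError):
    """Raised when a config file fails to parse or validate."""


class ScenarioName(str, Enum):
    AVERAGE = "Average"
    TOP10 = "Top10"
    IDEAL = "Ideal"


class Principle(str, Enum):
    """How an Ideal-scenario parameter was defined.

    A: set to zero (e.g. mortality), B: maximized (e.g. farrowing rate),
    C: PERT-distributed, D: taken from the comparison scenario,
    E: constant across scenarios, F: calculated from other inputs.
    """

    A_ZERO = "A_zero"
    B_MAXIMIZED = "B_maximized"
    C_PERT = "C_pert"
    D_FROM_COMPARISON = "D_from_comparison"
    E_CONSTANT = "E_constant"
    F_CALCULATED = "F_calculated"


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class PertSpec(_StrictModel):
    """A min/mode/max triple for a PERT-distributed (Beta-rescaled) input."""

    minimum: float
    mode: float
    maximum: float

    @model_validator(mode="after")
    def _check(self) -> "PertSpec":
        for v in (self.minimum, self.mode, self.maximum):
            if not math.isfinite(v):
                raise ValueError("PERT bounds must be finite")
        if not (self.minimum <= self.mode <= self.maximum):
            raise ValueError(
                f"PERT requires minimum <= mode <= maximum, got "
                f"({self.minimum}, {self.mode}, {self.maximum})"
            )
        return self

    @property
    def mean(self) -> float:
        """Closed-form PERT mean (min + 4*mode + max)/6 at shape lambda=4."""
        return (self.minimum + 4.0 * self.mode + self.maximum) / 6.0

    @property
    def variance(self) -> float:
        m = self.mean
        return (m - self.minimum) * (self.maximum - m) / 7.0

    @property
    def is_degenerate(self) -> bool:
        return self.minimum == self.maximum


class ParameterValue(_StrictModel):
    """A scenario input that is either a fixed number or a PERT triple."""

    kind: str = "fixed"
    value: Optional[float] = None
    spec: Optional[PertSpec] = None
    principle: Principle = Principle.D_FROM_COMPARISON

    @model_validator(mode="before")
    @classmethod
    def _coerce(cls, data: Any) -> Any:
        # shorthand forms: bare number, {"pert": [min, mode, max], ...}
        if isinstance(data, (int, float)):
            return {"kind": "fixed", "value": float(data)}
        if isinstance(data, dict) and "pert" in data:
            mn, md, mx = data["pert"]
            out = {
                "kind": "pert",
                "spec": PertSpec(minimum=mn, mode=md, maximum=mx),
                "principle": data.get("principle", Principle.C_PERT),
            }
            return out
        return data

    @model_validator(mode="after")
    def _check(self) -> "ParameterValue":
        if self.kind == "fixed":
            if self.value is None or self.spec is not None:
                raise ValueError("fixed ParameterValue must populate value only")
        elif self.kind == "pert":
            if self.spec is None or self.value is not None:
                raise ValueError("pert ParameterValue must populate spec only")
        else:
            raise ValueError(f"unknown ParameterValue kind {self.kind!r}")
        if self.principle == Principle.A_ZERO and (
            self.kind != "fixed" or self.value != 0.0
        ):
            raise ValueError("principle A_zero requires a fixed value of exactly 0")
        return self

    @property
    def point(self) -> float:
        """Most-likely value: the fixed value, or the PERT mode."""
        return self.value if self.kind == "fixed" else self.spec.mode  # type: ignore[union-attr]

    @property
    def mean(self) -> float:
        """Expected value: the fixed value, or the closed-form PERT mean."""
        return self.value if self.kind == "fixed" else self.spec.mean  # type: ignore[union-attr]


Param = Union[ParameterValue, float]


def _fraction(name: str):
    def check(v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be a fraction in [0, 1], got {v}")
        return v

    return check


class BreedingParameters(_StrictModel):
    """One scenario's input vector for a combined breeding/rearing farm.

    Durations are days, weights kg liveweight, rates per year, mortalities
    and rates fractions in [0, 1].
    """

    gestation_length: float = Field(gt=0)
    lactation_length: float = Field(gt=0)
    weaning_to_oestrus: float = Field(ge=0)
    piglet_weaning_weight: float = Field(gt=0)
    reared_sale_weight: float = Field(gt=0)
    rearing_duration: float = Field(gt=0)
    rearing_adg: ParameterValue
    rearing_fcr: ParameterValue
    sow_replacement_rate: ParameterValue
    litters_per_sow_year: ParameterValue
    return_to_oestrus_rate: float
    piglets_weaned_per_litter: float = Field(gt=0)
    piglets_weaned_per_sow_year: float = Field(gt=0)
    piglets_born_alive_per_litter: ParameterValue
    preweaning_mortality: float
    rearing_mortality: float
    farrowing_rate: float = Field(gt=0, le=1.0)
    sow_liveweight: float = 200.0

    _v1 = field_validator("return_to_oestrus_rate")(_fraction("return_to_oestrus_rate"))
    _v2 = field_validator("preweaning_mortality")(_fraction("preweaning_mortality"))
    _v3 = field_validator("rearing_mortality")(_fraction("rearing_mortality"))

    @model_validator(mode="after")
    def _cross_checks(self) -> "BreedingParameters":
        if self.reared_sale_weight <= self.piglet_weaning_weight:
            raise ValueError("reared_sale_weight must exceed piglet_weaning_weight")
        return self

    def weaned_per_sow_year(self, litters=None, born_alive=None, preweaning_mortality=None):
        """Piglets weaned per sow-year from the component multipliers.

        Accepts scalar or array overrides so Monte Carlo draws can be
        propagated; defaults to the parameters' expected values.
        """
        litters = self.litters_per_sow_year.mean if litters is None else litters
        born = self.piglets_born_alive_per_litter.mean if born_alive is None else born_alive
        pwm = self.preweaning_mortality if preweaning_mortality is None else preweaning_mortality
        return litters * born * (1.0 - pwm)


class FatteningParameters(_StrictModel):
    """One scenario's input vector for a fattening farm."""

    start_weight: float = Field(gt=0)
    slaughter_weight: float = Field(gt=0)
    fattening_duration: ParameterValue
    mortality: float
    fcr: ParameterValue
    adg: float = Field(gt=0, description="g/day, derived from weights and duration")
    service_period: float = Field(default=16.0, ge=0, description="empty days between batches")

    @field_validator("mortality")
    @classmethod
    def _mort(cls, v: float) -> float:
        if not 0.0 <= v < 1.0:
            raise ValueError(f"fattening mortality must be in [0, 1), got {v}")
        return v

    @model_validator(mode="after")
    def _cross(self) -> "FatteningParameters":
        if self.slaughter_weight <= self.start_weight:
            raise ValueError("slaughter_weight must exceed start_weight")
        return self

    @property
    def weight_gain(self) -> float:
        return self.slaughter_weight - self.start_weight


class PriceBook(_StrictModel):
    """Unit prices and cost rates (CHF) converting physical quantities to money.

    Reconstructed by inverting the printed per-sow / per-pig revenue and
    cost aggregates; each entry's provenance is documented in the fixture.
    Veterinary rates differ by scenario (herd-health visits vanish in the
    disease-free Ideal, leaving only piglet castration/iron injections).
    """

    reared_piglet_price: float = Field(ge=0)
    cull_sow_price: float = Field(ge=0)
    gilt_price: float = Field(ge=0)
    insemination_price: float = Field(ge=0)
    sow_gestation_feed_rate: float = Field(ge=0)
    sow_lactation_feed_rate: float = Field(ge=0)
    starter_feed_per_weaned: float = Field(ge=0)
    rearing_feed_price: float = Field(ge=0)
    gilt_feed_per_replacement: float = Field(ge=0)
    vet_fixed_per_farm: float = Field(ge=0)
    vet_per_sow: dict[ScenarioName, float]
    vet_per_sow_ideal: float = Field(ge=0)
    ear_tag_price: float = Field(ge=0)
    breeding_misc_fixed: float = Field(ge=0)
    slaughter_pig_revenue: float = Field(ge=0)
    fattening_piglet_base_price: float = Field(ge=0)
    fattening_piglet_base_weight: float = Field(default=27.1, gt=0)
    fattening_piglet_price_per_kg_over_base: float = Field(ge=0)
    fattening_feed_price: float = Field(ge=0)
    fattening_vet_per_pig: dict[ScenarioName, float]
    fattening_misc_per_pig: float = Field(ge=0)

    @model_validator(mode="after")
    def _nonneg(self) -> "PriceBook":
        for d in (self.vet_per_sow, self.fattening_vet_per_pig):
            for k, v in d.items():
                if v < 0:
                    raise ValueError(f"negative rate for {k}")
        return self

    def piglet_purchase_price(self, start_weight):
        """Price paid by a fattener for a reared piglet of given liveweight."""
        return self.fattening_piglet_base_price + (
            start_weight - self.fattening_piglet_base_weight
        ) * self.fattening_piglet_price_per_kg_over_base


class PopulationCounts(_StrictModel):
    """National herd counts used to scale per-animal results."""

    breeding_sows: int = Field(default=100_878, gt=0)
    slaughter_pigs: int = Field(default=2_433_981, gt=0)


class ScenarioSet(_StrictModel):
    name: ScenarioName
    breeding: BreedingParameters
    fattening: FatteningParameters


class SimulationSettings(_StrictModel):
    iterations: int = Field(default=10_000, ge=1)
    seed: int = 20230
    percentiles: tuple[float, float] = (5.0, 95.0)


class SensitivitySettings(_StrictModel):
    increments: int = Field(default=7, ge=2)
    iterations_per_increment: int = Field(default=1_000, ge=1)
    parameters: list[str] = Field(default_factory=list)


class AnalysisConfig(_StrictModel):
    """Top-level config: scenarios + price book + population + run settings."""

    meta: dict[str, Any] = Field(default_factory=dict)
    scenarios: dict[ScenarioName, ScenarioSet]
    price_book: PriceBook
    population: PopulationCounts = Field(default_factory=PopulationCounts)
    simulation: SimulationSettings = Field(default_factory=SimulationSettings)
    sensitivity: SensitivitySettings = Field(default_factory=SensitivitySettings)

    @model_validator(mode="after")
    def _names_match(self) -> "AnalysisConfig":
        for key, sc in self.scenarios.items():
            if sc.name != key:
                raise ValueError(f"scenario key {key} disagrees with name {sc.name}")
        return self


# ---------------------------------------------------------------------------
# validation report
# ---------------------------------------------------------------------------

_REL_TOL_IDENTITY = 0.01  # printed aggregates vs component products


def validate_scenario_set(
    s: ScenarioSet, reference: ScenarioSet | None = None
) -> list[str]:
    """Report every violated scenario invariant; empty list iff valid.

    ``reference`` is the Average scenario used for the Ideal-dominance
    checks (Ideal may not be worse than Average on any health-driven
    parameter).  Pure function: no mutation, deterministic.
    """
    problems: list[str] = []
    b, f = s.breeding, s.fattening

    if b.piglets_weaned_per_litter > b.piglets_born_alive_per_litter.point + 1e-9:
        problems.append(
            "piglets_weaned_per_litter exceeds piglets_born_alive_per_litter"
        )
    derived = b.weaned_per_sow_year(
        litters=b.litters_per_sow_year.point,
        born_alive=b.piglets_born_alive_per_litter.point,
    )
    if abs(derived - b.piglets_weaned_per_sow_year) > _REL_TOL_IDENTITY * derived:
        problems.append(
            f"piglets_weaned_per_sow_year {b.piglets_weaned_per_sow_year} "
            f"inconsistent with litters x born alive x (1 - preweaning mortality) "
            f"= {derived:.3f} (>1% off)"
        )

    if s.name == ScenarioName.IDEAL:
        if b.preweaning_mortality != 0.0 or b.rearing_mortality != 0.0:
            problems.append("principle A: Ideal breeding mortalities must be 0")
        if f.mortality != 0.0:
            problems.append("principle A: Ideal fattening mortality must be 0")
        if b.return_to_oestrus_rate != 0.0:
            problems.append("principle A: Ideal return-to-oestrus rate must be 0")
        if b.farrowing_rate != 1.0:
            problems.append(
                "principle B: farrowing rate must be maximized (1.0), "
                f"got {b.farrowing_rate}"
            )

    if reference is not None:
        rb, rf = reference.breeding, reference.fattening
        pairs = [
            ("preweaning_mortality", b.preweaning_mortality, rb.preweaning_mortality, "<="),
            ("rearing_mortality", b.rearing_mortality, rb.rearing_mortality, "<="),
            ("fattening mortality", f.mortality, rf.mortality, "<="),
            ("farrowing_rate", b.farrowing_rate, rb.farrowing_rate, ">="),
            ("litters_per_sow_year", b.litters_per_sow_year.point, rb.litters_per_sow_year.point, ">="),
            ("piglets_born_alive_per_litter", b.piglets_born_alive_per_litter.point, rb.piglets_born_alive_per_litter.point, ">="),
            ("rearing_fcr", b.rearing_fcr.point, rb.rearing_fcr.point, "<="),
            ("fattening fcr", f.fcr.point, rf.fcr.point, "<="),
        ]
        for label, v, ref, op in pairs:
            ok = v <= ref + 1e-12 if op == "<=" else v >= ref - 1e-12
            if not ok:
                problems.append(
                    f"dominance violation: {s.name.value} {label}={v} is worse "
                    f"than {reference.name.value} {ref}"
                )
    return problems


def validate_config(cfg: AnalysisConfig) -> list[str]:
    """Validate every scenario, using Average as the dominance reference."""
    avg = cfg.scenarios.get(ScenarioName.AVERAGE)
    problems: list[str] = []
    for name, sc in cfg.scenarios.items():
        ref = avg if (name == ScenarioName.IDEAL and avg is not None) else None
        for p in validate_scenario_set(sc, reference=ref):
            problems.append(f"{name.value}: {p}")
    # parameters held constant across scenarios (biology / regulation)
    if avg is not None:
        for name, sc in cfg.scenarios.items():
            for field in ("gestation_length", "lactation_length",
                          "piglet_weaning_weight", "reared_sale_weight"):
                if getattr(sc.breeding, field) != getattr(avg.breeding, field):
                    problems.append(
                        f"{name.value}: {field} must be constant across scenarios"
                    )
    return problems


# ---------------------------------------------------------------------------
# config I/O
# ---------------------------------------------------------------------------


def _dump_param(p: ParameterValue) -> Any:
    if p.kind == "pert":
        return {
            "pert": [p.spec.minimum, p.spec.mode, p.spec.maximum],
            "principle": p.principle.value,
        }
    if p.principle != Principle.D_FROM_COMPARISON:
        return {"kind": "fixed", "value": p.value, "principle": p.principle.value}
    return p.value


def _config_to_plain(cfg: AnalysisConfig) -> dict:
    data = cfg.model_dump(mode="json")
    for sc_key, sc in cfg.scenarios.items():
        plain = data["scenarios"][sc_key.value]
        for section, model in (("breeding", sc.breeding), ("fattening", sc.fattening)):
            for fname, fval in model:
                if isinstance(fval, ParameterValue):
                    plain[section][fname] = _dump_param(fval)
    return data


def save_scenario_config(cfg: AnalysisConfig, path: str | Path) -> None:
    """Write the config as YAML; loading it back is lossless."""
    path = Path(path)
    with path.open("w") as fh:
        yaml.safe_dump(_config_to_plain(cfg), fh, sort_keys=False)


def load_scenario_config(path: str | Path) -> AnalysisConfig:
    """Load and fully validate a YAML analysis config.

    Raises :class:`ConfigError` naming the offending field on parse or
    invariant failure; unknown keys are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        with path.open() as fh:
            raw = yaml.safe_load(fh)
    except yaml.YAMLError as exc:  # keep the parser's line/column info
        raise ConfigError(f"YAML parse error in {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        cfg = AnalysisConfig.model_validate(raw)
    except Exception as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    problems = validate_config(cfg)
    if problems:
        raise ConfigError(f"{path}: invalid scenario parameters:\n- " + "\n- ".join(problems))
    return cfg


def scenario_to_csv(s: ScenarioSet, path: str | Path) -> None:
    """Export one scenario as a two-column (parameter, value) CSV."""
    import csv

    rows: list[tuple[str, str]] = []
    for section, model in (("breeding", s.breeding), ("fattening", s.fattening)):
        for fname, fval in model:
            if isinstance(fval, ParameterValue):
                if fval.kind == "pert":
                    sp = fval.spec
                    txt = f"{sp.mode} ({sp.minimum}-{sp.maximum})"
                else:
                    txt = str(fval.value)
            else:
                txt = str(fval)
            rows.append((f"{section}.{fname}", txt))
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["parameter", "value"])
        w.writerows(rows)
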