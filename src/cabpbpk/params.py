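"""Model parameters: drug constants, formulations, EHC, dosing and physiology.

All quantities are stored in the package's internal unit system — time in
hours, amounts in micromoles, concentrations in µmol/L — except where a field
name says otherwise (rate constants from in-vitro sources are kept in 1/min,
gallbladder times in minutes, as printed on their source scale; the engine
converts once at assembly time).  ng/mL appears only at I/O boundaries.

The packaged defaults (``data/cabozantinib.yaml``, ``data/physiology_human.yaml``,
``data/ehc.yaml``) carry the cabozantinib profile of the underlying clinical
PBPK analysis plus a standard ICRP-type adult physiology.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "ConfigError",
    "MissingFieldError",
    "RangeError",
    "DrugParameters",
    "FormulationSpec",
    "EHCParameters",
    "DoseRegimen",
    "Organ",
    "GISegment",
    "PhysiologyModel",
    "load_config",
    "save_config",
    "default_config_path",
    "load_default_config",
    "ng_per_ml_to_umol_per_l",
    "umol_per_l_to_ng_per_ml",
    "mg_to_umol",
    "umol_to_mg",
]


class ConfigError(ValueError):
    """Base class for configuration problems."""


class MissingFieldError(ConfigError):
    """A mandatory configuration field is absent."""

    def __init__(self, section: str, name: str):
        self.section, self.name = section, name
        super().__init__(f"missing mandatory field '{name}' in section '{section}'")


class RangeError(ConfigError):
    """A value violates a stated invariant."""

    def __init__(self, name: str, value: Any, invariant: str):
        self.name, self.value, self.invariant = name, value, invariant
        super().__init__(f"'{name}' = {value!r} violates invariant: {invariant}")


def _require_positive(name: str, value: float) -> float:
    if not (value > 0):
        raise RangeError(name, value, "must be > 0")
    return float(value)


def _require_fraction(name: str, value: float, *, open_low=True, open_high=False) -> float:
    lo_ok = value > 0 if open_low else value >= 0
    hi_ok = value < 1 if open_high else value <= 1
    if not (lo_ok and hi_ok):
        lo, hi = ("(" if open_low else "["), (")" if open_high else "]")
        raise RangeError(name, value, f"must lie in {lo}0,1{hi}")
    return float(value)


# ---------------------------------------------------------------------------
# unit conversions
# ---------------------------------------------------------------------------

def ng_per_ml_to_umol_per_l(value: float, mw: float) -> float:
    """Convert a mass concentration (ng/mL) to µmol/L.

    1 ng/mL = 1 µg/L, so c[µmol/L] = c[ng/mL] / MW[g/mol].
    """
    _require_positive("molecular_weight", mw)
    return value / mw


def umol_per_l_to_ng_per_ml(value: float, mw: float) -> float:
    """Inverse of :func:`ng_per_ml_to_umol_per_l`."""
    _require_positive("molecular_weight", mw)
    return value * mw


def mg_to_umol(mg: float, mw: float) -> float:
    _require_positive("molecular_weight", mw)
    return mg * 1000.0 / mw


def umol_to_mg(umol: float, mw: float) -> float:
    _require_positive("molecular_weight", mw)
    return umol * mw / 1000.0


# ---------------------------------------------------------------------------
# drug / formulation / EHC / dosing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DrugParameters:
    """Physicochemical and kinetic constants of the victim compound.

    ``fu_plasma`` is stored as a *fraction*.  Cabozantinib is 99.7% bound to
    human plasma proteins, so the packaged default is 0.0024 (0.24% unbound) —
    the printed "0.24" of the source profile is read as percent unbound.  This
    reading is deliberate, loudly documented and configurable.
    """

    molecular_weight: float        # g/mol
    pka_base: float                # monoprotic base
    fu_plasma: float               # fraction unbound in plasma, (0, 1]
    logp: float                    # octanol:water log partition coefficient
    solubility_ref: float          # mg/mL at solubility_ref_ph
    solubility_ref_ph: float
    km_cyp3a4: float               # µmol/L
    kcat_cyp3a4: float             # 1/min
    km_mrp2: float                 # µmol/L
    kcat_mrp2: float               # 1/min
    mrp2_ref_conc: float           # µmol transporter / L tissue (liver)
    transcellular_permeability: float  # cm/min
    partition_method: str = "rodgers-rowland"
    permeability_method: str = "perfusion-limited"
    kp_rbc: float = 0.0            # red-cell:unbound-plasma partition, default plasma-restricted
    # bile-salt micellar solubilization multiplies the aqueous solubility in
    # the intestinal lumen (biorelevant-media enhancement for a lipophilic
    # base); applied only to the luminal saturation cap, not to the
    # reference aqueous solubility itself
    luminal_solubilization_factor: float = 200.0

    def __post_init__(self):
        for name in ("molecular_weight", "pka_base", "logp", "solubility_ref",
                     "km_cyp3a4", "kcat_cyp3a4", "km_mrp2", "kcat_mrp2",
                     "mrp2_ref_conc", "transcellular_permeability",
                     "luminal_solubilization_factor"):
            _require_positive(name, getattr(self, name))
        _require_fraction("fu_plasma", self.fu_plasma)
        if not (1.0 <= self.solubility_ref_ph <= 9.0):
            raise RangeError("solubility_ref_ph", self.solubility_ref_ph, "must lie in [1,9]")
        if self.kp_rbc < 0:
            raise RangeError("kp_rbc", self.kp_rbc, "must be >= 0")
        if self.partition_method not in ("rodgers-rowland",):
            raise RangeError("partition_method", self.partition_method,
                             "must be 'rodgers-rowland'")
        if self.permeability_method not in ("perfusion-limited", "permeability-limited"):
            raise RangeError("permeability_method", self.permeability_method,
                             "must be 'perfusion-limited' or 'permeability-limited'")


@dataclass(frozen=True)
class FormulationSpec:
    """Oral formulation: Weibull dissolution for solids, instant for solution.

    ``solution_solubility_scale`` (< 1, solution only) mimics the reduced
    gastrointestinal solubility used for the oral-solution arm, where the
    administered "solution" likely behaved as a suspension.
    """

    kind: str                                  # solution | tablet | capsule
    weibull_t50: float | None = None           # min
    weibull_shape: float | None = None
    solution_solubility_scale: float | None = None

    def __post_init__(self):
        if self.kind not in ("solution", "tablet", "capsule"):
            raise RangeError("formulation.kind", self.kind,
                             "must be one of solution/tablet/capsule")
        if self.kind == "solution":
            if self.weibull_t50 is not None or self.weibull_shape is not None:
                raise RangeError("formulation", self.kind,
                                 "weibull fields must be absent for a solution")
            scale = 0.5 if self.solution_solubility_scale is None else self.solution_solubility_scale
            _require_fraction("solution_solubility_scale", scale)
            object.__setattr__(self, "solution_solubility_scale", float(scale))
        else:
            if self.weibull_t50 is None or self.weibull_shape is None:
                raise MissingFieldError(f"formulation[{self.kind}]", "weibull_t50/weibull_shape")
            _require_positive("weibull_t50", self.weibull_t50)
            _require_positive("weibull_shape", self.weibull_shape)
            if self.solution_solubility_scale is not None:
                raise RangeError("solution_solubility_scale", self.solution_solubility_scale,
                                 "only allowed for solution formulations")


@dataclass(frozen=True)
class EHCParameters:
    """Gallbladder emptying / enterohepatic recirculation constants."""

    emptying_half_time: float      # min, exponential release half-time
    continuous_fraction: float     # bile fraction bypassing the gallbladder
    ejection_fraction: float       # fraction of stored content ejected per meal
    refill_time: float             # min, refractory period before refilling
    meal_times: tuple[float, ...]  # h post-dose, first-day schedule, repeats daily

    def __post_init__(self):
        _require_positive("emptying_half_time", self.emptying_half_time)
        _require_positive("refill_time", self.refill_time)
        _require_fraction("continuous_fraction", self.continuous_fraction, open_low=False)
        _require_fraction("ejection_fraction", self.ejection_fraction, open_low=False)
        mt = tuple(float(t) for t in self.meal_times)
        if len(mt) == 0:
            raise MissingFieldError("ehc", "meal_times")
        if any(t <= 0 for t in mt):
            raise RangeError("meal_times", mt, "times must be positive")
        if any(b <= a for a, b in zip(mt, mt[1:])):
            raise RangeError("meal_times", mt, "must be strictly increasing")
        object.__setattr__(self, "meal_times", mt)


@dataclass(frozen=True)
class DoseRegimen:
    dose: float                    # mg
    formulation: FormulationSpec | None  # None for iv
    route: str = "oral"            # oral | iv
    interval: float = 24.0         # h
    n_doses: int = 1

    def __post_init__(self):
        if self.dose < 0:
            raise RangeError("dose", self.dose, "must be >= 0")
        if self.route not in ("oral", "iv"):
            raise RangeError("route", self.route, "must be 'oral' or 'iv'")
        if self.route == "oral" and self.formulation is None:
            raise MissingFieldError("regimen", "formulation")
        if int(self.n_doses) < 1:
            raise RangeError("n_doses", self.n_doses, "must be >= 1")
        object.__setattr__(self, "n_doses", int(self.n_doses))
        if self.n_doses > 1:
            _require_positive("interval", self.interval)

    def dose_times(self) -> list[float]:
        return [i * self.interval for i in range(self.n_doses)]


# ---------------------------------------------------------------------------
# physiology
# ---------------------------------------------------------------------------

@dataclass
class Organ:
    name: str
    volume_l: float
    flow_l_h: float
    f_vascular: float = 0.05
    f_interstitial: float = 0.15
    f_intracellular: float = 0.80

    def __post_init__(self):
        _require_positive(f"{self.name}.volume_l", self.volume_l)
        if self.flow_l_h < 0:
            raise RangeError(f"{self.name}.flow_l_h", self.flow_l_h, "must be >= 0")


@dataclass
class GISegment:
    name: str
    volume_l: float
    area_cm2: float
    ph: float
    transit_h: float

    def __post_init__(self):
        _require_positive(f"{self.name}.volume_l", self.volume_l)
        if self.area_cm2 < 0:
            raise RangeError(f"{self.name}.area_cm2", self.area_cm2, "must be >= 0")
        if not (1.0 <= self.ph <= 9.0):
            raise RangeError(f"{self.name}.ph", self.ph, "must lie in [1,9]")
        _require_positive(f"{self.name}.transit_h", self.transit_h)


SPLANCHNIC = ("gut", "spleen", "pancreas", "stomach")
SYSTEMIC = ("adipose", "bone", "brain", "heart", "kidney", "muscle", "skin", "rest")


@dataclass
class PhysiologyModel:
    """Whole-body physiology: organ volumes/flows, blood pools, GI geometry,
    enzyme and transporter expression.  Mutable by impairment scaling.

    ``organs`` must include the systemic tissues, the splanchnic tissues, the
    liver (its ``flow_l_h`` is the hepatic *arterial* flow; portal inflow is
    the sum of splanchnic outflows) and the lung (its flow is ignored — the
    lung carries total cardiac output).
    """

    organs: dict[str, Organ]
    gi_segments: list[GISegment]
    hematocrit: float
    volume_venous_l: float
    volume_arterial_l: float
    cyp3a4_expression: dict[str, float]   # organ -> µmol enzyme / L tissue
    mrp2_expression: dict[str, float]     # organ -> µmol transporter / L tissue
    plasma_protein_scale: float = 1.0
    body_weight_kg: float = 73.0
    species: str = "human"

    def __post_init__(self):
        _require_fraction("hematocrit", self.hematocrit, open_high=True)
        _require_positive("volume_venous_l", self.volume_venous_l)
        _require_positive("volume_arterial_l", self.volume_arterial_l)
        if self.plasma_protein_scale < 0:
            raise RangeError("plasma_protein_scale", self.plasma_protein_scale, "must be >= 0")
        if self.species != "human":
            raise RangeError("species", self.species, "only 'human' physiology is supported")
        required = set(SYSTEMIC) | set(SPLANCHNIC) | {"liver", "lung"}
        missing = required - set(self.organs)
        if missing:
            raise MissingFieldError("physiology.organs", ", ".join(sorted(missing)))
        if not self.gi_segments:
            raise MissingFieldError("physiology", "gi_segments")

    @property
    def cardiac_output_l_h(self) -> float:
        """Total systemic flow = lung flow; sum over all organs except lung."""
        return sum(o.flow_l_h for n, o in self.organs.items() if n != "lung")

    @property
    def liver_total_flow_l_h(self) -> float:
        return self.organs["liver"].flow_l_h + sum(
            self.organs[n].flow_l_h for n in SPLANCHNIC)

    def validate_flows(self, tolerance: float = 0.01) -> None:
        """Organ flows must sum to cardiac output within ``tolerance``.

        Cardiac output is defined as that sum, so this guards against a
        caller-supplied ``cardiac_output`` override drifting from the table.
        """
        co = self.cardiac_output_l_h
        if not co > 0:
            raise RangeError("cardiac_output", co, "must be > 0")

    def copy(self) -> "PhysiologyModel":
        return PhysiologyModel(
            organs={n: dataclasses.replace(o) for n, o in self.organs.items()},
            gi_segments=[dataclasses.replace(s) for s in self.gi_segments],
            hematocrit=self.hematocrit,
            volume_venous_l=self.volume_venous_l,
            volume_arterial_l=self.volume_arterial_l,
            cyp3a4_expression=dict(self.cyp3a4_expression),
            mrp2_expression=dict(self.mrp2_expression),
            plasma_protein_scale=self.plasma_protein_scale,
            body_weight_kg=self.body_weight_kg,
            species=self.species,
        )


# ---------------------------------------------------------------------------
# config I/O
# ---------------------------------------------------------------------------

_DRUG_FIELDS = {f.name for f in dataclasses.fields(DrugParameters)}
_MANDATORY_DRUG = _DRUG_FIELDS - {"partition_method", "permeability_method",
                                  "kp_rbc", "luminal_solubilization_factor"}


def default_config_path() -> Path:
    """Path of the packaged cabozantinib configuration."""
    return Path(resources.files("cabpbpk") / "data" / "cabozantinib.yaml")


def _read_structured(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def _build_drug(section: dict) -> DrugParameters:
    for name in sorted(_MANDATORY_DRUG):
        if name not in section:
            raise MissingFieldError("drug", name)
    unknown = set(section) - _DRUG_FIELDS
    if unknown:
        raise ConfigError(f"unknown drug fields: {sorted(unknown)}")
    return DrugParameters(**section)


def _build_formulation(section: dict) -> FormulationSpec:
    if "kind" not in section:
        raise MissingFieldError("formulation", "kind")
    return FormulationSpec(**section)


def _build_ehc(section: dict) -> EHCParameters:
    for name in ("emptying_half_time", "continuous_fraction",
                 "ejection_fraction", "refill_time", "meal_times"):
        if name not in section:
            raise MissingFieldError("ehc", name)
    return EHCParameters(
        emptying_half_time=section["emptying_half_time"],
        continuous_fraction=section["continuous_fraction"],
        ejection_fraction=section["ejection_fraction"],
        refill_time=section["refill_time"],
        meal_times=tuple(section["meal_times"]),
    )


def _build_regimen(section: dict, formulations: dict[str, FormulationSpec]) -> DoseRegimen:
    if "dose" not in section:
        raise MissingFieldError("regimen", "dose")
    route = section.get("route", "oral")
    form = None
    if route == "oral":
        fname = section.get("formulation")
        if fname is None:
            raise MissingFieldError("regimen", "formulation")
        if fname not in formulations:
            raise ConfigError(f"regimen formulation '{fname}' not defined in config")
        form = formulations[fname]
    return DoseRegimen(
        dose=section["dose"], formulation=form, route=route,
        interval=section.get("interval", 24.0), n_doses=section.get("n_doses", 1),
    )


def _build_physiology(section: dict) -> PhysiologyModel:
    for name in ("organs", "gi_segments", "hematocrit",
                 "volume_venous_l", "volume_arterial_l", "cyp3a4_expression"):
        if name not in section:
            raise MissingFieldError("physiology", name)
    organs = {n: Organ(name=n, **rec) for n, rec in section["organs"].items()}
    segments = [GISegment(name=rec["name"], volume_l=rec["volume_l"],
                          area_cm2=rec["area_cm2"], ph=rec["ph"],
                          transit_h=rec["transit_h"])
                for rec in section["gi_segments"]]
    model = PhysiologyModel(
        organs=organs,
        gi_segments=segments,
        hematocrit=section["hematocrit"],
        volume_venous_l=section["volume_venous_l"],
        volume_arterial_l=section["volume_arterial_l"],
        cyp3a4_expression=dict(section["cyp3a4_expression"]),
        mrp2_expression=dict(section.get("mrp2_expression", {})),
        plasma_protein_scale=section.get("plasma_protein_scale", 1.0),
        body_weight_kg=section.get("body_weight_kg", 73.0),
        species=section.get("species", "human"),
    )
    model.validate_flows()
    return model


def load_config(path: str | Path) -> tuple[DrugParameters, PhysiologyModel,
                                           EHCParameters, DoseRegimen]:
    """Load and validate a YAML/JSON configuration file.

    The file may reference the packaged physiology/EHC defaults via
    ``physiology: default`` / ``ehc: default``; unspecified optional fields are
    filled with documented defaults.
    """
    raw = _read_structured(path)
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    if "drug" not in raw:
        raise MissingFieldError("<root>", "drug")
    drug = _build_drug(raw["drug"])

    formulations = {name: _build_formulation(dict(kind=name) | dict(rec or {}))
                    for name, rec in raw.get("formulations", {}).items()}
    if "formulations" not in raw:
        # unspecified formulations fall back to the packaged defaults
        formulations = load_default_formulations()

    data_dir = resources.files("cabpbpk") / "data"
    phys_section = raw.get("physiology", "default")
    if phys_section == "default":
        phys_section = yaml.safe_load((data_dir / "physiology_human.yaml").read_text())["physiology"]
    physiology = _build_physiology(phys_section)

    ehc_section = raw.get("ehc", "default")
    if ehc_section == "default":
        ehc_section = yaml.safe_load((data_dir / "ehc.yaml").read_text())["ehc"]
    ehc = _build_ehc(ehc_section)

    regimen_section = raw.get("regimen", {"dose": 140.0, "formulation": "tablet"})
    regimen = _build_regimen(regimen_section, formulations)
    return drug, physiology, ehc, regimen


def save_config(path: str | Path,
                drug: DrugParameters,
                physiology: PhysiologyModel | None = None,
                ehc: EHCParameters | None = None,
                regimen: DoseRegimen | None = None,
                formulations: dict[str, FormulationSpec] | None = None) -> None:
    """Serialize a parameter set back to YAML (lossless round trip)."""
    doc: dict[str, Any] = {"drug": dataclasses.asdict(drug)}
    if formulations:
        doc["formulations"] = {}
        for name, f in formulations.items():
            rec = {k: v for k, v in dataclasses.asdict(f).items()
                   if k != "kind" and v is not None}
            doc["formulations"][name] = rec
    if physiology is not None:
        doc["physiology"] = {
            "organs": {n: {"volume_l": o.volume_l, "flow_l_h": o.flow_l_h,
                           "f_vascular": o.f_vascular,
                           "f_interstitial": o.f_interstitial,
                           "f_intracellular": o.f_intracellular}
                       for n, o in physiology.organs.items()},
            "gi_segments": [dataclasses.asdict(s) for s in physiology.gi_segments],
            "hematocrit": physiology.hematocrit,
            "volume_venous_l": physiology.volume_venous_l,
            "volume_arterial_l": physiology.volume_arterial_l,
            "cyp3a4_expression": dict(physiology.cyp3a4_expression),
            "mrp2_expression": dict(physiology.mrp2_expression),
            "plasma_protein_scale": physiology.plasma_protein_scale,
            "body_weight_kg": physiology.body_weight_kg,
            "species": physiology.species,
        }
    if ehc is not None:
        doc["ehc"] = {
            "emptying_half_time": ehc.emptying_half_time,
            "continuous_fraction": ehc.continuous_fraction,
            "ejection_fraction": ehc.ejection_fraction,
            "refill_time": ehc.refill_time,
            "meal_times": list(ehc.meal_times),
        }
    if regimen is not None:
        rec: dict[str, Any] = {"dose": regimen.dose, "route": regimen.route,
                               "interval": regimen.interval, "n_doses": regimen.n_doses}
        if regimen.formulation is not None:
            rec["formulation"] = regimen.formulation.kind
        doc["regimen"] = rec
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_default_config():
    """Convenience: the packaged cabozantinib defaults."""
    return load_config(default_config_path())


def load_default_formulations() -> dict[str, FormulationSpec]:
    raw = _read_structured(default_config_path())
    return {name: _build_formulation(dict(kind=name) | dict(rec or {}))
            for name, rec in raw.get("formulations", {}).items()}
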