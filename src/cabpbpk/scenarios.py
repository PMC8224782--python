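"""Scenario layer: CYP3A4-induction DDI with rifampin, hepatic-impairment
physiology scaling, and local sensitivity analysis.

The perpetrator is modelled as a simplified one-compartment oral drug whose
unbound concentration drives an Emax induction of CYP3A4 synthesis in a
standard turnover model, dE/dt = kdeg*(E0*fold - E).  The induction
parameters are literature defaults from the published rifampin PBPK model
(external to the cabozantinib analysis itself) and are plainly marked as
such.  Rifampin's weaker competitive-inhibition component is omitted by
default; induction is the dominant interaction mechanism.

Hepatic-impairment scaling follows the clinical grading (mild ~ Child-Pugh A,
moderate ~ B): reduced portal and renal flows, increased hepatic-arterial and
other-organ flows (brain untouched), reduced functional liver volume, reduced
CYP3A4 activity (moderate), altered hematocrit and plasma protein binding.
Cardiac output after scaling is recomputed as the sum of the scaled flows.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .engine import PBPKSystem, SimulationOptions, SimulationResult
from .params import (SPLANCHNIC, DoseRegimen, DrugParameters, EHCParameters,
                     PhysiologyModel, RangeError)

__all__ = [
    "InductionModel",
    "ImpairmentScaling",
    "IMPAIRMENT_GRADES",
    "apply_impairment",
    "induction_fold",
    "enzyme_turnover_step",
    "simulate_ddi",
    "local_sensitivity",
    "apply_overrides",
    "pbpk_output_fn",
]


@dataclass(frozen=True)
class InductionModel:
    """Perpetrator regimen, simplified perpetrator PK and induction constants.

    Defaults describe 600 mg oral rifampin once daily with a 9-day lead-in
    before the victim dose; Emax/EC50 and CYP3A4 turnover half-lives (liver
    36 h, gut 23 h) are literature values from the published rifampin
    PBPK/induction model — they are external defaults, not constants of the
    cabozantinib analysis.
    """

    dose_mg: float = 600.0
    interval_h: float = 24.0
    n_doses: int = 24
    start_h: float = -216.0          # perpetrator lead-in relative to victim dose
    absorption_rate_h: float = 1.7   # 1/h
    clearance_l_h: float = 12.0
    volume_l: float = 55.0
    fu: float = 0.17
    molecular_weight: float = 822.94
    emax: float = 9.0
    ec50: float = 0.34               # µmol/L unbound
    kdeg_liver_h: float = 0.0193     # 1/h (turnover half-life ~36 h)
    kdeg_gut_h: float = 0.0301      # 1/h (~23 h)
    targets: tuple[str, ...] = ("liver", "gut")

    def __post_init__(self):
        if self.emax < 0:
            raise RangeError("emax", self.emax, "must be >= 0")
        for name in ("ec50", "kdeg_liver_h", "kdeg_gut_h", "volume_l",
                     "clearance_l_h", "absorption_rate_h", "molecular_weight"):
            if not getattr(self, name) > 0:
                raise RangeError(name, getattr(self, name), "must be > 0")


@dataclass(frozen=True)
class ImpairmentScaling:
    """Physiological scaling factors for one hepatic-impairment grade.

    ``plasma_protein_factor`` follows the clinical narrative: values above 1
    raise the unbound fraction (and with it distribution volume and
    clearance), values below 1 lower it.  Internally it is applied as a
    binding-protein concentration scale of 1/factor.
    """

    grade: str
    hematocrit: float | None = None          # None keeps the baseline value
    flow_portal: float = 1.0
    flow_renal: float = 1.0
    flow_hepatic_arterial: float = 1.0
    flow_other: float = 1.0                   # all remaining organs except brain
    liver_volume_fraction: float = 1.0
    cyp3a4_activity: float = 1.0
    plasma_protein_factor: float = 1.0

    def __post_init__(self):
        for name in ("flow_portal", "flow_renal", "flow_hepatic_arterial",
                     "flow_other", "liver_volume_fraction", "cyp3a4_activity",
                     "plasma_protein_factor"):
            if not getattr(self, name) > 0:
                raise RangeError(name, getattr(self, name), "must be > 0")
        if self.hematocrit is not None and not (0 < self.hematocrit < 1):
            raise RangeError("hematocrit", self.hematocrit, "must lie in (0,1)")


IMPAIRMENT_GRADES: dict[str, ImpairmentScaling] = {
    "control": ImpairmentScaling(grade="control"),
    "mild": ImpairmentScaling(
        grade="mild", hematocrit=0.39, flow_portal=0.40, flow_renal=0.88,
        flow_hepatic_arterial=1.30, flow_other=1.75,
        liver_volume_fraction=0.81, cyp3a4_activity=1.00,
        plasma_protein_factor=0.85),
    "moderate": ImpairmentScaling(
        grade="moderate", hematocrit=0.37, flow_portal=0.36, flow_renal=0.65,
        flow_hepatic_arterial=2.30, flow_other=2.25,
        liver_volume_fraction=0.65, cyp3a4_activity=0.40,
        plasma_protein_factor=1.25),
}


def apply_impairment(physiology: PhysiologyModel,
                     scaling: ImpairmentScaling | str) -> PhysiologyModel:
    """Return a new physiology with the impairment grade applied.

    Control is the field-wise identity.  Portal (splanchnic) and renal flows
    are multiplied by their scalars, the hepatic arterial flow and all other
    organ flows (except brain) by theirs; the liver volume shrinks by the
    liver-volume fraction (transporter/enzyme amounts scale with it);
    hepatic CYP3A4 activity and the plasma-protein factor are applied on
    top.  Cardiac output is recomputed as the sum of the scaled flows.
    """
    if isinstance(scaling, str):
        try:
            scaling = IMPAIRMENT_GRADES[scaling]
        except KeyError:
            raise RangeError("grade", scaling,
                             f"must be one of {sorted(IMPAIRMENT_GRADES)}") from None
    phys = physiology.copy()
    if scaling.grade == "control":
        return phys
    if scaling.hematocrit is not None:
        phys.hematocrit = scaling.hematocrit
    for name, organ in phys.organs.items():
        if name in SPLANCHNIC:
            organ.flow_l_h *= scaling.flow_portal
        elif name == "kidney":
            organ.flow_l_h *= scaling.flow_renal
        elif name == "liver":
            organ.flow_l_h *= scaling.flow_hepatic_arterial
        elif name in ("brain", "lung"):
            pass
        else:
            organ.flow_l_h *= scaling.flow_other
    phys.organs["liver"].volume_l *= scaling.liver_volume_fraction
    if "liver" in phys.cyp3a4_expression:
        phys.cyp3a4_expression["liver"] *= scaling.cyp3a4_activity
    # factor > 1 raises fu: applied as binding-protein scale 1/factor
    phys.plasma_protein_scale = physiology.plasma_protein_scale / scaling.plasma_protein_factor
    phys.validate_flows()
    return phys


def induction_fold(c_unbound: float, emax: float, ec50: float) -> float:
    """Emax induction of enzyme synthesis: fold = 1 + emax*c/(ec50 + c)."""
    if c_unbound < 0:
        raise RangeError("c_unbound", c_unbound, "must be >= 0")
    if emax < 0 or not ec50 > 0:
        raise RangeError("emax/ec50", (emax, ec50), "emax >= 0 and ec50 > 0")
    return 1.0 + emax * c_unbound / (ec50 + c_unbound)


def enzyme_turnover_step(e: float, e0: float, fold: float, kdeg: float) -> float:
    """Turnover derivative dE/dt = kdeg*E0*fold - kdeg*E (µmol/h).

    The steady state at constant perpetrator exposure is E_ss = E0*fold;
    after washout (fold = 1) E returns to E0 with half-life ln2/kdeg.
    """
    if not (e0 > 0 and e > 0):
        raise RangeError("E/E0", (e, e0), "must be > 0")
    if not kdeg > 0:
        raise RangeError("kdeg", kdeg, "must be > 0")
    return kdeg * e0 * fold - kdeg * e


def simulate_ddi(drug: DrugParameters, physiology: PhysiologyModel,
                 ehc: EHCParameters, regimen: DoseRegimen,
                 induction: InductionModel, t_end: float,
                 options: SimulationOptions | None = None
                 ) -> tuple[SimulationResult, SimulationResult]:
    """Co-simulate the victim with and without the perpetrator.

    Returns (with_rif, without_rif).  The perpetrator arm starts at the
    perpetrator lead-in time so liver and gut CYP3A4 are pre-induced when
    the victim dose falls at t = 0.
    """
    base = options or SimulationOptions()
    opt_with = dataclasses.replace(base, induction=induction)
    opt_without = dataclasses.replace(base, induction=None)
    sys_with = PBPKSystem(drug, physiology, ehc, opt_with)
    sys_without = PBPKSystem(drug, physiology, ehc, opt_without)
    res_with = sys_with.simulate(regimen, t_end,
                                 t_start=min(induction.start_h, 0.0))
    res_without = sys_without.simulate(regimen, t_end)
    return res_with, res_without


# ---------------------------------------------------------------------------
# local sensitivity
# ---------------------------------------------------------------------------

def local_sensitivity(output_fn, params: dict[str, float], name: str,
                      delta: float = 0.1) -> float:
    """Dimensionless local sensitivity by central finite difference.

    S = (dOutput/Output)/(dp/p) evaluated at the baseline ``params``;
    ``output_fn(params) -> float`` re-runs the model.
    """
    if name not in params:
        raise RangeError("parameter", name, "not present in the parameter set")
    if not (0.0 < delta <= 0.5):
        raise RangeError("delta", delta, "must lie in (0, 0.5]")
    p0 = params[name]
    if p0 == 0:
        raise RangeError(name, p0, "cannot perturb a zero-valued parameter relatively")
    up = dict(params); up[name] = p0 * (1.0 + delta)
    dn = dict(params); dn[name] = p0 * (1.0 - delta)
    out0 = output_fn(params)
    if out0 == 0:
        raise RangeError("output", out0, "baseline output is zero")
    return float((output_fn(up) - output_fn(dn)) / (2.0 * delta * out0))


def apply_overrides(drug: DrugParameters, physiology: PhysiologyModel,
                    ehc: EHCParameters, regimen: DoseRegimen,
                    overrides: dict[str, float]):
    """Apply dotted-path parameter overrides, e.g. ``drug.kcat_cyp3a4``,
    ``physiology.cyp3a4_expression.liver``, ``regimen.dose``."""
    drug_over = {k.split(".", 1)[1]: v for k, v in overrides.items()
                 if k.startswith("drug.")}
    ehc_over = {k.split(".", 1)[1]: v for k, v in overrides.items()
                if k.startswith("ehc.")}
    reg_over = {k.split(".", 1)[1]: v for k, v in overrides.items()
                if k.startswith("regimen.")}
    if drug_over:
        drug = dataclasses.replace(drug, **drug_over)
    if ehc_over:
        ehc = dataclasses.replace(ehc, **ehc_over)
    if reg_over:
        regimen = dataclasses.replace(regimen, **reg_over)
    phys = physiology.copy()
    for key, value in overrides.items():
        if not key.startswith("physiology."):
            continue
        parts = key.split(".")[1:]
        if parts[0] == "organs":
            setattr(phys.organs[parts[1]], parts[2], value)
        elif parts[0] in ("cyp3a4_expression", "mrp2_expression"):
            getattr(phys, parts[0])[parts[1]] = value
        else:
            setattr(phys, parts[0], value)
    return drug, phys, ehc, regimen


def pbpk_output_fn(drug: DrugParameters, physiology: PhysiologyModel,
                   ehc: EHCParameters, regimen: DoseRegimen, t_end: float,
                   output: str = "auc_last",
                   options: SimulationOptions | None = None):
    """Build ``params -> scalar`` for sensitivity analysis of the PBPK model.

    ``params`` keys are dotted override paths; ``output`` is 'auc_last' or
    'cmax'.
    """
    from .metrics import auc_last as _auc, cmax_tmax as _cmax

    def fn(params: dict[str, float]) -> float:
        d, p, e, r = apply_overrides(drug, physiology, ehc, regimen, params)
        system = PBPKSystem(d, p, e, options)
        res = system.simulate(r, t_end)
        if output == "auc_last":
            return _auc(res.times, res.conc_plasma_ng_ml)
        if output == "cmax":
            return _cmax(res)[0]
        raise RangeError("output", output, "must be 'auc_last' or 'cmax'")

    return fn
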