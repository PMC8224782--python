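"""Whole-body PBPK engine: assembles the multi-organ ODE system (blood pools,
perfusion-limited organs, segmented GI lumen, gallbladder) and integrates it
with discrete dose and meal events.

Topology: venous blood -> lung -> arterial blood -> organs.  Gut, spleen,
pancreas and stomach drain into the portal inflow of the liver together with
the intestinal absorption flux; the liver additionally receives hepatic
arterial blood.  Elimination routes are exactly saturable CYP3A4 metabolism
(liver and gut wall) and fecal excretion of unabsorbed or biliary-secreted
drug — the parent compound has no renal clearance.  Liver MRP2 feeds the
gallbladder/bile loop.  Events (doses, gallbladder emptying, refill ends) are
implemented as integrator restarts so the discrete logic stays exact.

Internal units: h, µmol, µmol/L; plasma outputs additionally in ng/mL.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Any

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import distribution
from .distribution import TissueComposition, blood_plasma_ratio, kp_rodgers_rowland, scaled_fu
from .ehc import meal_schedule, nonfilling_windows
from .gi import GutModel
from .params import (SPLANCHNIC, SYSTEMIC, DoseRegimen, DrugParameters,
                     EHCParameters, PhysiologyModel, RangeError, mg_to_umol)

__all__ = [
    "TopologyError",
    "SolverError",
    "NotApplicableError",
    "SimulationOptions",
    "PBPKSystem",
    "OneCompartmentModel",
    "SimulationResult",
    "PopulationResult",
    "assemble",
    "simulate",
    "simulate_population",
    "fraction_absorbed",
]

LN2 = math.log(2.0)

ORGAN_ORDER = ("lung",) + SYSTEMIC + SPLANCHNIC + ("liver",)


class TopologyError(ValueError):
    """The assembled system is not a valid closed circulatory topology."""


class SolverError(RuntimeError):
    """The integrator failed; carries the last accepted time."""

    def __init__(self, message: str, last_time: float):
        self.last_time = last_time
        super().__init__(f"{message} (last accepted time {last_time:.4g} h)")


class NotApplicableError(ValueError):
    """Requested output does not apply to this regimen (e.g. fabs for iv)."""


@dataclass
class SimulationOptions:
    """Engine switches and solver settings.

    ``ehc_enabled=False`` keeps biliary (MRP2) excretion but routes it
    directly to feces — biliary elimination without recirculation, the
    comparison arm of the EHC on/off contrast.  ``mrp2_enabled=False`` removes
    canalicular efflux entirely (kcat_mrp2 leaves the active model).
    ``exchange_mode='permeability-limited'`` replaces the perfusion
    conductance Q of selected organs by min(Q, PS) with user-supplied PS
    (L/h); unlisted organs stay perfusion-limited.
    """

    ehc_enabled: bool = True
    mrp2_enabled: bool = True
    metabolism_enabled: bool = True
    induction: Any | None = None          # scenarios.InductionModel (duck-typed)
    exchange_mode: str = "perfusion"      # or "permeability-limited"
    ps_l_h: dict[str, float] | None = None
    grid_dt: float = 0.1                  # h, output spacing (event times added)
    rtol: float = 1e-9
    atol: float = 1e-12
    solver: str = "LSODA"


class PBPKSystem:
    """Assembled whole-body ODE system with an immutable state layout."""

    def __init__(self, drug: DrugParameters, physiology: PhysiologyModel,
                 ehc: EHCParameters, options: SimulationOptions | None = None,
                 composition: TissueComposition | None = None):
        self.drug = drug
        self.physiology = physiology
        self.ehc = ehc
        self.options = options or SimulationOptions()
        comp = composition or TissueComposition.default()

        phys = physiology
        phys.validate_flows()
        for name in ORGAN_ORDER:
            if name not in phys.organs:
                raise TopologyError(f"organ '{name}' missing from physiology")

        # effective protein binding and partitioning
        self.fu = scaled_fu(drug.fu_plasma, phys.plasma_protein_scale)
        drug_eff = dataclasses.replace(drug, fu_plasma=self.fu)
        pset = kp_rodgers_rowland(drug_eff, comp, tissues=list(ORGAN_ORDER))
        self.kp = np.array([pset.kp[n] for n in ORGAN_ORDER])
        self.bp = blood_plasma_ratio(self.fu, phys.hematocrit, drug.kp_rbc)

        self.v_organ = np.array([phys.organs[n].volume_l for n in ORGAN_ORDER])
        q = np.array([phys.organs[n].flow_l_h for n in ORGAN_ORDER])
        self.co = phys.cardiac_output_l_h
        q[0] = self.co  # lung carries total cardiac output
        if not self.co > 0:
            raise TopologyError("cardiac output must be positive")
        flow_sum = q[1:].sum()
        if abs(flow_sum - self.co) > 0.01 * self.co:
            raise TopologyError(
                f"organ flows ({flow_sum:.3g} L/h) do not sum to cardiac "
                f"output ({self.co:.3g} L/h) within 1%")
        self.q_organ = q
        self.g_organ = q.copy()
        if self.options.exchange_mode == "permeability-limited":
            for name, ps in (self.options.ps_l_h or {}).items():
                i = ORGAN_ORDER.index(name)
                self.g_organ[i] = min(q[i], ps)
        elif self.options.exchange_mode != "perfusion":
            raise RangeError("exchange_mode", self.options.exchange_mode,
                             "must be 'perfusion' or 'permeability-limited'")

        self.i_systemic = np.array([ORGAN_ORDER.index(n) for n in SYSTEMIC])
        self.i_splanchnic = np.array([ORGAN_ORDER.index(n) for n in SPLANCHNIC])
        self.i_liver = ORGAN_ORDER.index("liver")
        self.i_gut = ORGAN_ORDER.index("gut")
        self.q_liver_total = phys.liver_total_flow_l_h
        self.g_liver_total = self.q_liver_total
        if self.options.exchange_mode == "permeability-limited" and \
                "liver" in (self.options.ps_l_h or {}):
            self.g_liver_total = min(self.q_liver_total,
                                     self.options.ps_l_h["liver"])
        # blood-side concentration leaving an organ: A/(V * Kp/BP)
        self.kpb = self.kp / self.bp

        # enzyme / transporter amounts (µmol) and Vmax coefficients (1/h basis)
        v_liv = self.v_organ[self.i_liver]
        v_gut = self.v_organ[self.i_gut]
        self.e_cyp_liver = phys.cyp3a4_expression.get("liver", 0.0) * v_liv
        self.e_cyp_gut = phys.cyp3a4_expression.get("gut", 0.0) * v_gut
        self.e_mrp2 = phys.mrp2_expression.get("liver", 0.0) * v_liv
        self.vmax_cyp_liver = drug.kcat_cyp3a4 * 60.0 * self.e_cyp_liver
        self.vmax_cyp_gut = drug.kcat_cyp3a4 * 60.0 * self.e_cyp_gut
        self.vmax_mrp2 = drug.kcat_mrp2 * 60.0 * self.e_mrp2
        self.km_cyp = drug.km_cyp3a4
        self.km_mrp2 = drug.km_mrp2
        # unbound intracellular driving concentration: fu_cell derived from
        # Kp partitioning, C_u = fu * C_tissue / Kp (documented assumption)
        self.fu_cell_liver = self.fu / self.kp[self.i_liver]
        self.fu_cell_gut = self.fu / self.kp[self.i_gut]

        self.gb_k_empty = LN2 / (ehc.emptying_half_time / 60.0)  # 1/h

        self.renal_clearance = 0.0  # parent compound: no renal excretion
        routes = {"fecal"}
        if self.options.metabolism_enabled:
            routes |= {"cyp3a4_liver", "cyp3a4_gut"}
        self.elimination_routes = routes

        # ---- state layout (immutable once assembled) ----
        self.gut_segments = phys.gi_segments
        n_seg = len(self.gut_segments)
        self.n_seg = n_seg
        idx: dict[str, Any] = {}
        cursor = 0

        def take(name, k=1):
            nonlocal cursor
            idx[name] = cursor if k == 1 else slice(cursor, cursor + k)
            cursor += k

        take("ven"); take("art")
        take("organs", len(ORGAN_ORDER))
        take("lumen_solid", n_seg); take("lumen_dissolved", n_seg)
        take("lumen_recycled", n_seg)
        take("gb_store"); take("gb_eject")
        take("cum_met_liver"); take("cum_met_gut"); take("cum_fecal")
        take("cum_absorbed", n_seg); take("cum_absorbed_recycled")
        take("rif_gut"); take("rif_central")
        take("e_rel_liver"); take("e_rel_gut")
        self.idx = idx
        self.n_states = cursor
        self.v_ven = phys.volume_venous_l
        self.v_art = phys.volume_arterial_l
        self.duo_index = 1  # duodenum is the segment after the stomach

        self._gut_cache: dict[str, GutModel] = {}

    # -- helpers ---------------------------------------------------------

    def initial_state(self) -> np.ndarray:
        y = np.zeros(self.n_states)
        y[self.idx["e_rel_liver"]] = 1.0
        y[self.idx["e_rel_gut"]] = 1.0
        return y

    def gut_model(self, formulation) -> GutModel:
        key = "iv" if formulation is None else formulation.kind
        if key not in self._gut_cache:
            self._gut_cache[key] = GutModel(self.drug, self.gut_segments, formulation)
        return self._gut_cache[key]

    def drug_mass(self, y: np.ndarray) -> float:
        """Total victim-drug mass (µmol) in compartments plus eliminated."""
        i = self.idx
        return float(y[i["ven"]] + y[i["art"]] + y[i["organs"]].sum()
                     + y[i["lumen_solid"]].sum() + y[i["lumen_dissolved"]].sum()
                     + y[i["lumen_recycled"]].sum()
                     + y[i["gb_store"]] + y[i["gb_eject"]]
                     + y[i["cum_met_liver"]] + y[i["cum_met_gut"]]
                     + y[i["cum_fecal"]])

    # -- right-hand side -------------------------------------------------

    def rhs(self, t: float, y: np.ndarray, ctx: dict) -> np.ndarray:
        i = self.idx
        opt = self.options
        dy = np.zeros_like(y)

        c_ven = y[i["ven"]] / self.v_ven
        c_art = y[i["art"]] / self.v_art
        a_org = y[i["organs"]]
        c_out = a_org / (self.v_organ * self.kpb)

        q, g = self.q_organ, self.g_organ
        d_org = np.zeros(len(ORGAN_ORDER))
        # lung: venous inflow at total cardiac output
        d_org[0] = self.co * (c_ven - c_out[0])
        # systemic + splanchnic exchange with arterial blood
        rest = np.arange(1, len(ORGAN_ORDER))
        d_org[rest] = g[rest] * (c_art - c_out[rest])

        # venous return from systemic organs (bypass share (Q-G) short-circuits)
        isys = self.i_systemic
        ven_in = float(np.sum(g[isys] * c_out[isys] + (q[isys] - g[isys]) * c_art))

        # GI lumen (dose-origin solids/dissolved plus bile-origin recycled pool)
        gut = ctx["gut_model"]
        t_dose = ctx["t_dose"]
        solids = y[i["lumen_solid"]]
        dis = y[i["lumen_dissolved"]]
        rec = y[i["lumen_recycled"]]
        d_un, d_dis, d_rec, absorb, absorb_rec, fecal_rate = gut.rates(
            (t - t_dose) if t_dose is not None else 0.0,
            np.maximum(solids, 0.0), np.maximum(dis, 0.0),
            np.maximum(rec, 0.0))
        abs_total = float(absorb.sum() + absorb_rec.sum())

        # portal stream: splanchnic outflow plus absorbed drug
        ispl = self.i_splanchnic
        portal_mass = float(np.sum(g[ispl] * c_out[ispl] + (q[ispl] - g[ispl]) * c_art)) \
            + abs_total
        q_ha = q[self.i_liver]
        c_in_liver = (q_ha * c_art + portal_mass) / self.q_liver_total

        il = self.i_liver
        g_liv = self.g_liver_total
        d_org[il] = g_liv * (c_in_liver - c_out[il])
        ven_in += g_liv * c_out[il] + (self.q_liver_total - g_liv) * c_in_liver

        # saturable intracellular processes (unbound intracellular driving)
        cu_liv = max(a_org[il], 0.0) / self.v_organ[il] * self.fu_cell_liver
        cu_gut = max(a_org[self.i_gut], 0.0) / self.v_organ[self.i_gut] * self.fu_cell_gut
        met_liv = met_gut = 0.0
        if opt.metabolism_enabled:
            e_l = y[i["e_rel_liver"]] if ctx["induction"] else 1.0
            e_g = y[i["e_rel_gut"]] if ctx["induction"] else 1.0
            met_liv = self.vmax_cyp_liver * e_l * cu_liv / (self.km_cyp + cu_liv)
            met_gut = self.vmax_cyp_gut * e_g * cu_gut / (self.km_cyp + cu_gut)
        efflux = 0.0
        if opt.mrp2_enabled:
            efflux = self.vmax_mrp2 * cu_liv / (self.km_mrp2 + cu_liv)

        d_org[il] -= met_liv + efflux
        d_org[self.i_gut] -= met_gut
        dy[i["cum_met_liver"]] = met_liv
        dy[i["cum_met_gut"]] = met_gut

        # bile routing
        eject_rate = self.gb_k_empty * max(y[i["gb_eject"]], 0.0)
        if opt.ehc_enabled:
            if ctx["filling"]:
                to_duo = efflux * self.ehc.continuous_fraction
                dy[i["gb_store"]] = efflux - to_duo
            else:
                to_duo = efflux
            dy[i["gb_eject"]] = -eject_rate
            d_rec[self.duo_index] += to_duo + eject_rate
        else:
            dy[i["cum_fecal"]] += efflux  # biliary loss without recirculation

        dy[i["organs"]] = d_org
        dy[i["ven"]] = ven_in - self.co * c_ven
        dy[i["art"]] = self.co * c_out[0] - float(q[rest].sum()) * c_art
        dy[i["lumen_solid"]] = d_un
        dy[i["lumen_dissolved"]] = d_dis
        dy[i["lumen_recycled"]] = d_rec
        dy[i["cum_absorbed"]] = absorb
        dy[i["cum_absorbed_recycled"]] = float(absorb_rec.sum())
        dy[i["cum_fecal"]] += fecal_rate

        ind = ctx["induction"]
        if ind is not None:
            rif_gut = max(y[i["rif_gut"]], 0.0)
            rif_cent = max(y[i["rif_central"]], 0.0)
            dy[i["rif_gut"]] = -ind.absorption_rate_h * rif_gut
            dy[i["rif_central"]] = (ind.absorption_rate_h * rif_gut
                                    - ind.clearance_l_h / ind.volume_l * rif_cent)
            cu_rif = ind.fu * rif_cent / ind.volume_l
            fold = 1.0 + ind.emax * cu_rif / (ind.ec50 + cu_rif)
            f_liv = fold if "liver" in ind.targets else 1.0
            f_gut = fold if "gut" in ind.targets else 1.0
            dy[i["e_rel_liver"]] = ind.kdeg_liver_h * (f_liv - y[i["e_rel_liver"]])
            dy[i["e_rel_gut"]] = ind.kdeg_gut_h * (f_gut - y[i["e_rel_gut"]])
        return dy

    # -- event machinery -------------------------------------------------

    def _event_list(self, regimen: DoseRegimen, t_start: float, t_end: float):
        events: list[tuple[float, str, Any]] = []
        dose_umol = mg_to_umol(regimen.dose, self.drug.molecular_weight)
        for td in regimen.dose_times():
            if t_start <= td <= t_end:
                events.append((td, "dose", dose_umol))
        if self.options.ehc_enabled and self.options.mrp2_enabled:
            for tm in meal_schedule(self.ehc, t_end):
                if tm <= t_end:
                    events.append((tm, "meal", None))
            for _, w_end in nonfilling_windows(meal_schedule(self.ehc, t_end),
                                               self.ehc.refill_time):
                if w_end < t_end:
                    events.append((w_end, "refill_end", None))
        ind = self.options.induction
        if ind is not None:
            perp_umol = ind.dose_mg * 1000.0 / ind.molecular_weight
            for k in range(ind.n_doses):
                tp = ind.start_h + k * ind.interval_h
                if t_start <= tp <= t_end:
                    events.append((tp, "perp_dose", perp_umol))
        events.sort(key=lambda e: e[0])
        return events

    def simulate(self, regimen: DoseRegimen, t_end: float,
                 t_start: float = 0.0, grid_dt: float | None = None
                 ) -> "SimulationResult":
        """Integrate the system over [t_start, t_end] with event restarts."""
        if not t_end > t_start:
            raise RangeError("t_end", t_end, "must be > t_start")
        opt = self.options
        grid_dt = grid_dt or opt.grid_dt

        events = self._event_list(regimen, t_start, t_end)
        boundaries = sorted({t_start, t_end, *(e[0] for e in events)})
        grid = np.arange(t_start, t_end, grid_dt)
        grid = np.unique(np.concatenate([grid, np.array(boundaries)]))

        windows = nonfilling_windows(meal_schedule(self.ehc, t_end),
                                     self.ehc.refill_time) \
            if (opt.ehc_enabled and opt.mrp2_enabled) else []

        y = self.initial_state()
        i = self.idx
        times_out: list[np.ndarray] = []
        states_out: list[np.ndarray] = []
        event_log: list[dict] = []
        administered = 0.0
        admin_out: list[np.ndarray] = []
        t_dose: float | None = None
        formulation = regimen.formulation if regimen.route == "oral" else None
        gut = self.gut_model(formulation)

        by_time: dict[float, list] = {}
        for t_e, kind, payload in events:
            by_time.setdefault(t_e, []).append((kind, payload))

        for t0, t1 in zip(boundaries[:-1], boundaries[1:]):
            for kind, payload in by_time.get(t0, []):
                if kind == "dose":
                    if regimen.route == "iv":
                        y[i["ven"]] += payload
                    elif formulation is not None and formulation.kind == "solution":
                        y[i["lumen_dissolved"]][0] += payload
                    else:
                        y[i["lumen_solid"]][0] += payload
                    administered += payload
                    t_dose = t0
                    event_log.append({"time_h": t0, "type": "dose",
                                      "amount_umol": payload})
                elif kind == "meal":
                    committed = self.ehc.ejection_fraction * y[i["gb_store"]]
                    y[i["gb_store"]] -= committed
                    y[i["gb_eject"]] += committed
                    event_log.append({"time_h": t0, "type": "meal",
                                      "amount_umol": committed})
                elif kind == "perp_dose":
                    y[i["rif_gut"]] += payload
                    event_log.append({"time_h": t0, "type": "perpetrator_dose",
                                      "amount_umol": payload})
                elif kind == "refill_end":
                    event_log.append({"time_h": t0, "type": "refill_end",
                                      "amount_umol": 0.0})

            mid = 0.5 * (t0 + t1)
            filling = not any(lo <= mid < hi for lo, hi in windows)
            ctx = {"filling": filling, "t_dose": t_dose, "gut_model": gut,
                   "induction": opt.induction}

            seg_mask = (grid >= t0) & (grid < t1)
            t_eval = grid[seg_mask]
            if t_eval.size == 0 or t_eval[0] > t0:
                t_eval = np.concatenate([[t0], t_eval])
            # always integrate through to the boundary so the continuation
            # state is y(t1); the boundary point itself is stored only for
            # the final segment (the next segment re-emits it post-event)
            t_eval = np.concatenate([t_eval, [t1]])

            sol = solve_ivp(lambda t, yy: self.rhs(t, yy, ctx), (t0, t1), y,
                            method=opt.solver, t_eval=t_eval,
                            rtol=opt.rtol, atol=opt.atol)
            if not sol.success:
                raise SolverError(f"integration failed: {sol.message}",
                                  sol.t[-1] if sol.t.size else t0)
            y = sol.y[:, -1].copy()
            keep = slice(None) if t1 == boundaries[-1] else slice(0, -1)
            times_out.append(sol.t[keep])
            states_out.append(sol.y.T[keep])
            admin_out.append(np.full(sol.t[keep].size, administered))

        times = np.concatenate(times_out)
        states = np.concatenate(states_out, axis=0)
        admin = np.concatenate(admin_out)
        return SimulationResult(system=self, regimen=regimen, times=times,
                                states=states, administered_umol=admin,
                                event_log=event_log)


@dataclass
class SimulationResult:
    """Time grid, per-compartment amounts and derived outputs of one run."""

    system: PBPKSystem
    regimen: DoseRegimen
    times: np.ndarray
    states: np.ndarray           # (n_t, n_states), amounts in µmol
    administered_umol: np.ndarray
    event_log: list[dict]

    @property
    def conc_plasma_umol_l(self) -> np.ndarray:
        """Venous plasma concentration = venous blood conc / B:P ratio."""
        s = self.system
        return self.states[:, s.idx["ven"]] / s.v_ven / s.bp

    @property
    def conc_plasma_ng_ml(self) -> np.ndarray:
        return self.conc_plasma_umol_l * self.system.drug.molecular_weight

    @property
    def metabolized_umol(self) -> np.ndarray:
        i = self.system.idx
        return self.states[:, i["cum_met_liver"]] + self.states[:, i["cum_met_gut"]]

    @property
    def fecal_umol(self) -> np.ndarray:
        return self.states[:, self.system.idx["cum_fecal"]]

    @property
    def absorbed_per_segment_umol(self) -> np.ndarray:
        return self.states[:, self.system.idx["cum_absorbed"]]

    def total_mass_umol(self) -> np.ndarray:
        return np.array([self.system.drug_mass(row) for row in self.states])

    def mass_balance_max_rel_error(self) -> float:
        """max_t |mass(t) - administered(t)| / total administered dose."""
        total = self.total_mass_umol()
        scale = self.administered_umol.max()
        if scale == 0.0:
            return float(np.max(np.abs(total)))
        return float(np.max(np.abs(total - self.administered_umol)) / scale)

    def to_dataframe(self, include_compartments: bool = False) -> pd.DataFrame:
        df = pd.DataFrame({"time_h": self.times,
                           "conc_ng_ml": self.conc_plasma_ng_ml,
                           "conc_umol_l": self.conc_plasma_umol_l})
        if include_compartments:
            for k, name in enumerate(ORGAN_ORDER):
                df[f"amount_{name}_umol"] = self.states[:, self.system.idx["organs"]][:, k]
            df["amount_gallbladder_umol"] = (
                self.states[:, self.system.idx["gb_store"]]
                + self.states[:, self.system.idx["gb_eject"]])
            df["metabolized_umol"] = self.metabolized_umol
            df["fecal_umol"] = self.fecal_umol
        return df

    def event_log_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.event_log,
                            columns=["time_h", "type", "amount_umol"])


@dataclass
class PopulationResult:
    """Ensemble of individual runs plus geometric summary curves."""

    times: np.ndarray
    conc_ng_ml: np.ndarray       # (n_individuals, n_t)
    results: list[SimulationResult]

    @property
    def geometric_mean(self) -> np.ndarray:
        c = self.conc_ng_ml
        with np.errstate(divide="ignore"):
            logs = np.log(c)
        out = np.exp(np.mean(logs, axis=0))
        out[~np.all(c > 0, axis=0)] = 0.0
        return out

    @property
    def geometric_sd(self) -> np.ndarray:
        c = self.conc_ng_ml
        ok = np.all(c > 0, axis=0)
        out = np.ones(c.shape[1])
        if c.shape[0] > 1:
            logs = np.log(np.where(c > 0, c, 1.0))
            out[ok] = np.exp(np.std(logs[:, ok], axis=0, ddof=1))
        return out

    def band(self) -> tuple[np.ndarray, np.ndarray]:
        g, s = self.geometric_mean, self.geometric_sd
        return g / s, g * s


def assemble(drug: DrugParameters, physiology: PhysiologyModel,
             ehc: EHCParameters, options: SimulationOptions | None = None
             ) -> PBPKSystem:
    """Build and validate the whole-body system (topology checks included)."""
    return PBPKSystem(drug, physiology, ehc, options)


def simulate(system, regimen: DoseRegimen, t_end: float, **kwargs):
    """Run ``system.simulate`` — shared contract for whole-body and
    degenerate systems."""
    return system.simulate(regimen, t_end, **kwargs)


def simulate_population(drug: DrugParameters, physiology: PhysiologyModel,
                        ehc: EHCParameters, regimen: DoseRegimen,
                        pop, t_end: float,
                        options: SimulationOptions | None = None
                        ) -> PopulationResult:
    """Simulate a virtual population and summarize with geometric statistics.

    Individual parameter sets come from ``synth.sample_population``; summary
    curves are the pointwise geometric mean and geometric-SD band.
    """
    from .synth import apply_individual, sample_population
    individuals = sample_population(pop)
    results = []
    times = None
    concs = []
    for ind in individuals:
        d_i, p_i, e_i = apply_individual(drug, physiology, ehc, ind)
        system = PBPKSystem(d_i, p_i, e_i, options)
        res = system.simulate(regimen, t_end)
        if times is None:
            times = res.times
        concs.append(np.interp(times, res.times, res.conc_plasma_ng_ml))
        results.append(res)
    return PopulationResult(times=times, conc_ng_ml=np.array(concs),
                            results=results)


def fraction_absorbed(result: SimulationResult) -> pd.DataFrame:
    """Per-segment cumulative fraction-of-dose absorbed curves.

    Nondecreasing, summing to the total fraction absorbed (<= 1).  Only
    defined for oral regimens.
    """
    if result.regimen.route != "oral":
        raise NotApplicableError("fraction absorbed is defined for oral dosing only")
    dose_umol = result.administered_umol.max()
    if dose_umol == 0:
        raise NotApplicableError("no dose administered")
    seg_names = [s.name for s in result.system.gut_segments]
    frac = result.absorbed_per_segment_umol / dose_umol
    df = pd.DataFrame(frac, columns=[f"fabs_{n}" for n in seg_names])
    df.insert(0, "time_h", result.times)
    df["fabs_total"] = frac.sum(axis=1)
    return df


class OneCompartmentModel:
    """Degenerate well-stirred configuration used for closed-form validation.

    A single compartment of volume ``V`` with linear clearance ``CL`` and,
    optionally, first-order oral absorption ``ka``.  Shares the ``simulate``
    contract of the whole-body system; for an iv bolus D the closed forms are
    C(0) = D/V and AUC_inf = D/CL.
    """

    def __init__(self, volume_l: float, clearance_l_h: float,
                 ka_h: float | None = None, mw: float = 501.50):
        if not volume_l > 0:
            raise RangeError("volume_l", volume_l, "must be > 0")
        if clearance_l_h < 0:
            raise RangeError("clearance_l_h", clearance_l_h, "must be >= 0")
        self.v = volume_l
        self.cl = clearance_l_h
        self.ka = ka_h
        self.mw = mw

    def simulate(self, regimen: DoseRegimen, t_end: float,
                 t_start: float = 0.0, grid_dt: float = 0.05
                 ) -> "OneCompartmentResult":
        if not t_end > t_start:
            raise RangeError("t_end", t_end, "must be > t_start")
        dose_umol = mg_to_umol(regimen.dose, self.mw)
        dose_times = [td for td in regimen.dose_times() if t_start <= td <= t_end]
        boundaries = sorted({t_start, t_end, *dose_times})
        grid = np.unique(np.concatenate([np.arange(t_start, t_end, grid_dt),
                                         np.array(boundaries)]))
        ke = self.cl / self.v

        def rhs(t, y):
            gut, cent, elim = y
            ab = (self.ka or 0.0) * gut
            return [-ab, ab - ke * cent, ke * cent]

        y = np.zeros(3)
        ts, ys, admins = [], [], []
        administered = 0.0
        for t0, t1 in zip(boundaries[:-1], boundaries[1:]):
            if t0 in dose_times:
                if regimen.route == "oral":
                    if self.ka is None:
                        raise RangeError("ka_h", None, "oral dosing requires ka")
                    y[0] += dose_umol
                else:
                    y[1] += dose_umol
                administered += dose_umol
            mask = (grid >= t0) & (grid < t1)
            t_eval = grid[mask]
            if t_eval.size == 0 or t_eval[0] > t0:
                t_eval = np.concatenate([[t0], t_eval])
            t_eval = np.concatenate([t_eval, [t1]])
            sol = solve_ivp(rhs, (t0, t1), y, method="LSODA", t_eval=t_eval,
                            rtol=1e-10, atol=1e-12)
            if not sol.success:
                raise SolverError(sol.message, sol.t[-1] if sol.t.size else t0)
            y = sol.y[:, -1].copy()
            keep = slice(None) if t1 == boundaries[-1] else slice(0, -1)
            ts.append(sol.t[keep]); ys.append(sol.y.T[keep])
            admins.append(np.full(sol.t[keep].size, administered))
        times = np.concatenate(ts)
        states = np.concatenate(ys, axis=0)
        return OneCompartmentResult(model=self, times=times, states=states,
                                    administered_umol=np.concatenate(admins))


@dataclass
class OneCompartmentResult:
    model: OneCompartmentModel
    times: np.ndarray
    states: np.ndarray           # columns: gut, central, eliminated
    administered_umol: np.ndarray

    @property
    def conc_plasma_umol_l(self) -> np.ndarray:
        return self.states[:, 1] / self.model.v

    @property
    def conc_plasma_ng_ml(self) -> np.ndarray:
        return self.conc_plasma_umol_l * self.model.mw

    def mass_balance_max_rel_error(self) -> float:
        total = self.states.sum(axis=1)
        scale = self.administered_umol.max()
        if scale == 0.0:
            return float(np.max(np.abs(total)))
        return float(np.max(np.abs(total - self.administered_umol)) / scale)
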