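"""Segmented gastrointestinal model: Weibull dissolution, pH-dependent luminal
solubility, first-order transit and transcellular absorption flux.

The lumen is a chain of well-stirred segments (stomach, duodenum, upper/lower
jejunum, upper/lower ileum, caecum, colon).  Undissolved and dissolved drug
both move downstream at 1/transit_time; the terminal segment routes to fecal
elimination.  Dissolution follows a Weibull profile implemented as a
time-varying first-order hazard, paused when a segment reaches its saturation
concentration (precipitation-free clamp).  Dissolved drug is absorbed across
the mucosa at P*A*C into the portal inflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import DrugParameters, FormulationSpec, GISegment, RangeError

__all__ = [
    "weibull_fraction",
    "weibull_hazard",
    "luminal_solubility",
    "absorption_rate",
    "GutState",
    "GutModel",
]

LN2 = math.log(2.0)
_T_FLOOR_MIN = 1e-9  # avoids the singular hazard at t=0 for shape < 1

# upper bound on the instantaneous dissolution rate (1/h).  The Weibull
# hazard diverges at late times for shape > 1, an artifact of the empirical
# form; physically the rate is bounded by surface area and agitation.  The
# cap preserves the early-dissolution advantage of fast formulations.
MAX_DISSOLUTION_RATE_H = 2.5


def weibull_fraction(t: float, t50: float, shape: float) -> float:
    """Cumulative dissolved fraction F(t) = 1 - 2^(-(t/t50)^shape), t in min.

    Parameterized by the half-dissolution time: F(t50) = 0.5 exactly.
    """
    if t < 0:
        raise RangeError("t", t, "must be >= 0")
    if not (t50 > 0 and shape > 0):
        raise RangeError("t50/shape", (t50, shape), "must be > 0")
    return 1.0 - 2.0 ** (-((t / t50) ** shape))


def weibull_hazard(t_min: float, t50: float, shape: float) -> float:
    """Instantaneous first-order dissolution rate (1/min): f(t)/(1-F(t)).

    Applying this hazard to the remaining undissolved amount reproduces the
    Weibull cumulative profile while letting transit carry solids downstream.
    """
    t = max(t_min, _T_FLOOR_MIN)
    return LN2 * shape * t ** (shape - 1.0) / t50 ** shape


def luminal_solubility(drug: DrugParameters, ph: float) -> float:
    """Solubility of a monoprotic base at luminal pH, in mg/mL.

    Henderson-Hasselbalch anchored at the reference measurement:
    S(pH) = S_ref * (1 + 10^(pKa-pH)) / (1 + 10^(pKa-pH_ref)).
    """
    if not (1.0 <= ph <= 9.0):
        raise RangeError("ph", ph, "must lie in [1,9]")
    pka = drug.pka_base
    return drug.solubility_ref * (1.0 + 10.0 ** (pka - ph)) / \
        (1.0 + 10.0 ** (pka - drug.solubility_ref_ph))


def absorption_rate(permeability_cm_min: float, area_cm2: float,
                    c_lumen_umol_l: float) -> float:
    """Transcellular absorption flux in µmol/h.

    rate = P[cm/min]*60 * A[cm^2] * C[µmol/L] / 1000[cm^3/L]; linear in each
    argument.
    """
    if permeability_cm_min < 0 or area_cm2 < 0 or c_lumen_umol_l < 0:
        raise RangeError("absorption_rate args",
                         (permeability_cm_min, area_cm2, c_lumen_umol_l),
                         "must be >= 0")
    return permeability_cm_min * 60.0 * area_cm2 * c_lumen_umol_l / 1000.0


@dataclass
class GutState:
    """Snapshot of the GI lumen (amounts in µmol)."""

    segments: list[str]
    undissolved: np.ndarray
    dissolved: np.ndarray
    absorbed: np.ndarray       # cumulative, per segment
    fecal: float = 0.0

    def total(self) -> float:
        return float(self.undissolved.sum() + self.dissolved.sum()
                     + self.absorbed.sum() + self.fecal)


class GutModel:
    """Precomputed per-segment constants and the lumen derivative terms."""

    def __init__(self, drug: DrugParameters, segments: list[GISegment],
                 formulation: FormulationSpec | None = None,
                 max_hazard_h: float = MAX_DISSOLUTION_RATE_H):
        if not segments:
            raise RangeError("gi_segments", segments, "must be non-empty")
        self.drug = drug
        self.formulation = formulation
        self.max_hazard_h = max_hazard_h
        self.names = [s.name for s in segments]
        self.n = len(segments)
        self.volumes = np.array([s.volume_l for s in segments])
        self.k_transit = np.array([1.0 / s.transit_h for s in segments])
        # absorption clearance L/h per segment (stomach has area 0)
        self.cl_abs = np.array([
            drug.transcellular_permeability * 60.0 * s.area_cm2 / 1000.0
            for s in segments])
        scale = drug.luminal_solubilization_factor
        if formulation is not None and formulation.kind == "solution":
            scale *= formulation.solution_solubility_scale
        # saturation concentration per segment, µmol/L: aqueous
        # Henderson-Hasselbalch solubility times the bile-salt
        # solubilization factor (and the solution-arm reduction)
        self.sat_umol_l = np.array([
            luminal_solubility(drug, s.ph) * scale * 1e6 / drug.molecular_weight
            for s in segments])

    def hazard_h(self, t_since_dose_h: float) -> float:
        """Dissolution hazard in 1/h at elapsed time since the last oral dose."""
        f = self.formulation
        if f is None or f.kind == "solution":
            return 0.0  # solutions enter the stomach already dissolved
        lam = 60.0 * weibull_hazard(t_since_dose_h * 60.0,
                                    f.weibull_t50, f.weibull_shape)
        return min(lam, self.max_hazard_h)

    def rates(self, t_since_dose_h: float, undissolved: np.ndarray,
              dissolved: np.ndarray, recycled: np.ndarray | None = None):
        """Derivative contributions of the lumen.

        ``recycled`` is the bile-origin dissolved pool (kept separate from
        the dose-origin pool so fraction-absorbed bookkeeping refers to the
        administered dose); it transits and absorbs with the same constants
        and contributes to the saturation clamp.

        Returns (d_undissolved, d_dissolved, d_recycled, absorb_per_segment,
        absorb_recycled_per_segment, fecal_rate), all µmol/h.  Mass is
        conserved exactly: the six contributions sum to zero.
        """
        if recycled is None:
            recycled = np.zeros_like(dissolved)
        lam = self.hazard_h(t_since_dose_h)
        conc_dis = dissolved / self.volumes
        conc_rec = recycled / self.volumes
        conc_tot = conc_dis + conc_rec
        sat = np.clip(1.0 - conc_tot / self.sat_umol_l, 0.0, 1.0)
        dis_rate = lam * undissolved * sat

        out_un = self.k_transit * undissolved
        out_dis = self.k_transit * dissolved
        out_rec = self.k_transit * recycled
        # only molecularly dissolved drug (<= saturation) permeates; any
        # supersaturated excess transits until capacity frees up
        c_eff = np.minimum(conc_tot, self.sat_umol_l)
        with np.errstate(invalid="ignore", divide="ignore"):
            share_dis = np.where(conc_tot > 0, conc_dis / conc_tot, 0.0)
        flux = self.cl_abs * c_eff
        absorb = flux * share_dis
        absorb_rec = flux * (1.0 - share_dis)

        d_un = -out_un - dis_rate
        d_un[1:] += out_un[:-1]
        d_dis = dis_rate - out_dis - absorb
        d_dis[1:] += out_dis[:-1]
        d_rec = -out_rec - absorb_rec
        d_rec[1:] += out_rec[:-1]
        fecal_rate = out_un[-1] + out_dis[-1] + out_rec[-1]
        return d_un, d_dis, d_rec, absorb, absorb_rec, fecal_rate
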