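"""Tissue:plasma partitioning (Rodgers & Rowland), blood:plasma ratio and
protein-binding scaling.

The partition model predicts the tissue-to-unbound-plasma ratio Kpu from
tissue composition (water, neutral lipid and neutral phospholipid fractions,
acidic phospholipids, tissue:plasma albumin ratio) and the drug's pKa, logP
and plasma protein binding, then Kp = Kpu * fu.  Two branches exist:

* weak bases (pKa < 7) and neutrals — ionization in intracellular water plus
  neutral-lipid partitioning plus extracellular albumin binding;
* moderate-to-strong bases (pKa >= 7) — electrostatic association of the
  cation with acidic phospholipids, calibrated from blood-cell partitioning.

Cabozantinib (pKa 6.32) uses the weak-base branch.  The branch threshold at
pKa 7 follows the published equations.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

from .params import DrugParameters, RangeError, _require_fraction

__all__ = [
    "TissueRow",
    "TissueComposition",
    "PartitionSet",
    "kp_rodgers_rowland",
    "blood_plasma_ratio",
    "scaled_fu",
]

PH_PLASMA = 7.4
PH_INTRACELLULAR = 7.0
PH_BLOOD_CELL = 7.22

# blood-cell composition constants used to back out the acidic-phospholipid
# association constant in the strong-base branch
_BC_F_IW = 0.603
_BC_F_NL = 0.0017
_BC_F_NP = 0.0029
_BC_AP = 0.5  # mg/g


@dataclass(frozen=True)
class TissueRow:
    f_ew: float        # extracellular water fraction
    f_iw: float        # intracellular water fraction
    f_nl: float        # neutral lipids fraction
    f_np: float        # neutral phospholipids fraction
    ap_mg_g: float     # acidic phospholipids, mg/g tissue
    ra_albumin: float  # tissue:plasma albumin ratio

    def __post_init__(self):
        for name in ("f_ew", "f_iw", "f_nl", "f_np"):
            v = getattr(self, name)
            if v < 0:
                raise RangeError(name, v, "must be >= 0")
        if self.f_ew + self.f_iw + self.f_nl + self.f_np > 1.0 + 1e-9:
            raise RangeError("composition", self, "water + lipid fractions must be <= 1")
        if self.ap_mg_g < 0 or self.ra_albumin < 0:
            raise RangeError("ap_mg_g/ra_albumin", self, "must be >= 0")


class TissueComposition:
    """Per-tissue composition table plus the plasma lipid fractions."""

    def __init__(self, rows: dict[str, TissueRow]):
        if "plasma" not in rows:
            raise RangeError("tissue_composition", sorted(rows), "must include a 'plasma' row")
        self.rows = dict(rows)

    @classmethod
    def default(cls) -> "TissueComposition":
        """Load the packaged composition table (provenance in the CSV)."""
        path = resources.files("cabpbpk") / "data" / "tissue_composition.csv"
        rows: dict[str, TissueRow] = {}
        with path.open() as fh:
            for rec in csv.DictReader(fh):
                rows[rec["tissue"]] = TissueRow(
                    f_ew=float(rec["f_ew"]), f_iw=float(rec["f_iw"]),
                    f_nl=float(rec["f_nl"]), f_np=float(rec["f_np"]),
                    ap_mg_g=float(rec["ap_mg_g"]),
                    ra_albumin=float(rec["ra_albumin"]),
                )
        return cls(rows)

    def __getitem__(self, tissue: str) -> TissueRow:
        try:
            return self.rows[tissue]
        except KeyError:
            raise KeyError(f"no tissue-composition row for '{tissue}'") from None

    def tissues(self) -> list[str]:
        return [t for t in self.rows if t != "plasma"]


@dataclass(frozen=True)
class PartitionSet:
    """Tissue:plasma partition coefficients and the blood:plasma ratio."""

    kp: dict[str, float]
    blood_plasma: float

    def __post_init__(self):
        for tissue, v in self.kp.items():
            if not v > 0:
                raise RangeError(f"kp[{tissue}]", v, "must be > 0")


def _lipid_term(p: float, f_nl: float, f_np: float) -> float:
    return p * f_nl + (0.3 * p + 0.7) * f_np


def kp_rodgers_rowland(drug: DrugParameters,
                       comp: TissueComposition,
                       tissues: list[str] | None = None,
                       ph_iw: float = PH_INTRACELLULAR,
                       ph_plasma: float = PH_PLASMA) -> PartitionSet:
    """Tissue:plasma partition coefficients for a monoprotic base.

    Returns one Kp per requested tissue (default: every tissue in the table)
    and the blood:plasma ratio derived from ``drug.kp_rbc``.
    """
    fu = _require_fraction("fu_plasma", drug.fu_plasma)
    p = 10.0 ** drug.logp
    pka = drug.pka_base
    x = 1.0 + 10.0 ** (pka - ph_plasma)   # 1/neutral fraction in plasma
    y = 1.0 + 10.0 ** (pka - ph_iw)       # 1/neutral fraction in cell water
    plasma = comp["plasma"]
    plasma_lipid = _lipid_term(p, plasma.f_nl, plasma.f_np) / x

    use_ap_branch = pka >= 7.0
    ka_ap = None
    if use_ap_branch:
        if drug.kp_rbc <= 0:
            raise RangeError(
                "kp_rbc", drug.kp_rbc,
                "moderate-to-strong base branch (pKa >= 7) requires a measured "
                "blood-cell-to-unbound-plasma partition kp_rbc > 0")
        y_bc = 1.0 + 10.0 ** (pka - PH_BLOOD_CELL)
        ka_ap = (drug.kp_rbc - (y_bc / x) * _BC_F_IW
                 - _lipid_term(p, _BC_F_NL, _BC_F_NP) / x)
        ka_ap = ka_ap * x / (_BC_AP * (y_bc - 1.0))
        if ka_ap < 0:
            ka_ap = 0.0

    kp: dict[str, float] = {}
    for tissue in (tissues if tissues is not None else comp.tissues()):
        row = comp[tissue]
        kpu = row.f_ew + (y / x) * row.f_iw + _lipid_term(p, row.f_nl, row.f_np) / x
        if use_ap_branch:
            kpu += ka_ap * row.ap_mg_g * (y - 1.0) / x
        else:
            residual = 1.0 / fu - 1.0 - plasma_lipid
            if residual < 0:           # can occur only near fu = 1
                residual = 0.0
            kpu += residual * row.ra_albumin
        kp[tissue] = kpu * fu

    bp = blood_plasma_ratio(fu, hct=0.45, kp_rbc=drug.kp_rbc)
    return PartitionSet(kp=kp, blood_plasma=bp)


def blood_plasma_ratio(fu: float, hct: float, kp_rbc: float) -> float:
    """Blood:plasma concentration ratio, B:P = (1 - hct) + hct * kp_rbc * fu.

    ``kp_rbc`` is the blood-cell-to-unbound-plasma partition; 0 confines the
    drug to plasma within blood.
    """
    if not (0.0 <= hct < 1.0):
        raise RangeError("hematocrit", hct, "must lie in [0,1)")
    if kp_rbc < 0:
        raise RangeError("kp_rbc", kp_rbc, "must be >= 0")
    return (1.0 - hct) + hct * kp_rbc * fu


def scaled_fu(fu: float, protein_scale: float) -> float:
    """Unbound fraction after scaling the binding-protein concentration.

    fu' = 1 / (1 + protein_scale * (1 - fu) / fu): the scale multiplies the
    binding-protein concentration at constant affinity.  scale 1 is the
    identity; scale 0 removes all binding protein (fu' = 1).
    """
    fu = _require_fraction("fu_plasma", fu)
    if protein_scale < 0:
        raise RangeError("protein_scale", protein_scale, "must be >= 0")
    return 1.0 / (1.0 + protein_scale * (1.0 - fu) / fu)
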