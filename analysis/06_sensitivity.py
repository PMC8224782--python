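#!/usr/bin/env python
"""Local sensitivity of exposure to the key model parameters.

Central-difference normalized sensitivities S = (dAUC/AUC)/(dp/p) of the
140 mg capsule AUC_last(0-96 h) with respect to the estimated/influential
parameters.
"""

import dataclasses
from pathlib import Path

import pandas as pd

import cabpbpk as cp
from cabpbpk.params import load_default_formulations
from cabpbpk.scenarios import local_sensitivity, pbpk_output_fn

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

PARAMS = [
    "drug.kcat_cyp3a4",
    "drug.km_cyp3a4",
    "drug.kcat_mrp2",
    "drug.transcellular_permeability",
    "drug.fu_plasma",
    "physiology.cyp3a4_expression.liver",
    "ehc.emptying_half_time",
]


def main():
    drug, phys, ehc, regimen = cp.load_default_config()
    forms = load_default_formulations()
    reg = dataclasses.replace(regimen, dose=140.0,
                              formulation=forms["capsule"])
    opt = cp.SimulationOptions(rtol=1e-6, atol=1e-9, grid_dt=0.25)
    fn = pbpk_output_fn(drug, phys, ehc, reg, t_end=96.0,
                        output="auc_last", options=opt)

    def base_value(path):
        obj = {"drug": drug, "ehc": ehc}.get(path.split(".")[0])
        if obj is not None:
            return getattr(obj, path.split(".", 1)[1])
        return phys.cyp3a4_expression["liver"]

    rows = []
    for name in PARAMS:
        s = local_sensitivity(fn, {name: base_value(name)}, name, delta=0.2)
        rows.append({"parameter": name, "sensitivity": s})
        print(f"S(AUC_96h; {name}) = {s:+.3f}")
    pd.DataFrame(rows).to_csv(OUT / "sensitivity.csv", index=False)
    print(f"wrote {OUT/'sensitivity.csv'}")


if __name__ == "__main__":
    main()
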