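#!/usr/bin/env python
"""Plasma exposure with and without enterohepatic recirculation.

Simulates the 140 mg tablet with the full bile loop and with biliary
excretion routed directly to feces (no recirculation).  Removing
recirculation collapses the post-meal secondary peaks and lowers exposure.
"""

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

import cabpbpk as cp
from cabpbpk.metrics import auc_last

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main():
    drug, phys, ehc, regimen = cp.load_default_config()
    opt = cp.SimulationOptions(rtol=1e-7, atol=1e-10)
    res_on = cp.PBPKSystem(drug, phys, ehc, opt).simulate(regimen, 144.0)
    opt_off = dataclasses.replace(opt, ehc_enabled=False)
    res_off = cp.PBPKSystem(drug, phys, ehc, opt_off).simulate(regimen, 144.0)

    auc_on = auc_last(res_on.times, res_on.conc_plasma_ng_ml)
    auc_off = auc_last(res_off.times, res_off.conc_plasma_ng_ml)
    print(f"AUC_last(0-144 h) with EHC:    {auc_on:9.0f} ng*h/mL")
    print(f"AUC_last(0-144 h) without EHC: {auc_off:9.0f} ng*h/mL")
    print(f"exposure ratio with/without:   {auc_on/auc_off:.2f}")

    df = pd.DataFrame({
        "time_h": res_on.times,
        "conc_ng_ml_with_ehc": res_on.conc_plasma_ng_ml,
        "conc_ng_ml_without_ehc": np.interp(res_on.times, res_off.times,
                                            res_off.conc_plasma_ng_ml)})
    df.iloc[::5].to_csv(OUT / "ehc_contrast.csv", index=False,
                        float_format="%.5g")
    res_on.event_log_dataframe().to_csv(OUT / "ehc_event_log.csv", index=False)
    print(f"wrote {OUT/'ehc_contrast.csv'} and ehc_event_log.csv")


if __name__ == "__main__":
    main()
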