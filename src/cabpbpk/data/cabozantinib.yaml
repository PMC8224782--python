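# Default cabozantinib profile for the whole-body PBPK model.
#
# fu_plasma: cabozantinib is 99.7% bound to human plasma proteins; the fraction
# unbound is therefore stored as 0.0024 (= 0.24%).  If you prefer a different
# protein-binding reading, override this field — everything downstream scales
# consistently.
#
# Rate constants are on their in-vitro scale (1/min); the engine converts to
# 1/h once at assembly.  Permeability is the transcellular intestinal
# permeability in cm/min.
drug:
  molecular_weight: 501.50        # g/mol
  pka_base: 6.32                  # monoprotic base
  fu_plasma: 0.0024               # fraction unbound (0.24%)
  logp: 4.40
  solubility_ref: 0.00772         # mg/mL at pH 6.5 (7.72e-3)
  solubility_ref_ph: 6.5
  km_cyp3a4: 0.97                 # umol/L
  kcat_cyp3a4: 0.67               # 1/min
  km_mrp2: 10.0                   # umol/L
  kcat_mrp2: 2111.11              # 1/min
  mrp2_ref_conc: 0.09             # umol transporter / L liver
  transcellular_permeability: 0.000170  # cm/min (1.70e-4)
  partition_method: rodgers-rowland
  permeability_method: perfusion-limited
  kp_rbc: 0.0                     # plasma-restricted in blood (99.7% bound)

formulations:
  tablet:
    weibull_t50: 36.00            # min, 50% dissolved, fasted state
    weibull_shape: 1.29
  capsule:
    weibull_t50: 45.00
    weibull_shape: 5.00
  solution:
    # administered "solution" likely behaved as a suspension; luminal
    # solubility is scaled down for this arm (value unprinted -> default 0.5)
    solution_solubility_scale: 0.5

physiology: default
ehc: default

regimen:
  dose: 140.0                     # mg
  formulation: tablet
  route: oral
  interval: 24.0                  # h
  n_doses: 1
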