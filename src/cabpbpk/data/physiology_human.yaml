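# Baseline adult human physiology for the whole-body PBPK model.
#
# Organ volumes and blood flows are standard ICRP-type reference values for a
# ~73 kg adult male (volumes in L, flows in L/h; cardiac output = sum of the
# systemic flows = 390 L/h).  They are deliberately round reference numbers,
# not a bit-exact copy of any proprietary software database.
#
# liver.flow_l_h is the hepatic ARTERIAL flow; the portal inflow is the sum of
# the splanchnic outflows (gut, spleen, pancreas, stomach).  lung.flow_l_h is
# ignored: the lung carries total cardiac output.
#
# GI geometry: effective absorptive areas are mucosal areas including fold/
# villi amplification (hence the large small-intestinal values); pH and
# transit times are standard fasted-state values.
#
# cyp3a4_expression: hepatic CYP3A4 tissue concentration is not an observable
# printed constant; the default below was calibrated once so that the base
# model's oral plasma clearance matches the clinical CL/F implied by the
# published 140 mg exposure (~2.3 L/h).  It is the designated tuning knob for
# metabolic capacity and can be overridden freely.  The small-intestinal
# (gut tissue) concentration is a literature-scale mucosal estimate.
physiology:
  hematocrit: 0.47
  plasma_protein_scale: 1.0
  body_weight_kg: 73.0
  species: human
  volume_venous_l: 3.53
  volume_arterial_l: 1.77
  organs:
    lung:     {volume_l: 0.53,  flow_l_h: 0.0}
    adipose:  {volume_l: 18.20, flow_l_h: 19.50}
    bone:     {volume_l: 10.50, flow_l_h: 19.50}
    brain:    {volume_l: 1.45,  flow_l_h: 46.80}
    heart:    {volume_l: 0.33,  flow_l_h: 15.60}
    kidney:   {volume_l: 0.31,  flow_l_h: 74.10}
    muscle:   {volume_l: 29.00, flow_l_h: 66.30}
    skin:     {volume_l: 3.30,  flow_l_h: 19.50}
    rest:     {volume_l: 4.00,  flow_l_h: 29.25}
    gut:      {volume_l: 1.65,  flow_l_h: 54.60}
    spleen:   {volume_l: 0.15,  flow_l_h: 11.70}
    pancreas: {volume_l: 0.14,  flow_l_h: 3.90}
    stomach:  {volume_l: 0.15,  flow_l_h: 3.90}
    liver:    {volume_l: 1.80,  flow_l_h: 25.35}   # hepatic arterial flow
  gi_segments:
    # absorptive (mucosal) area declines steeply from duodenum to colon, so
    # drug dissolving late reaches poorly absorbing segments — the spatial
    # coupling behind the formulation differences in early absorbed fraction
    - {name: stomach,       volume_l: 0.050, area_cm2: 0.0,     ph: 2.0, transit_h: 0.25}
    - {name: duodenum,      volume_l: 0.030, area_cm2: 3500.0,  ph: 6.0, transit_h: 0.25}
    - {name: upper_jejunum, volume_l: 0.080, area_cm2: 7800.0,  ph: 6.2, transit_h: 0.75}
    - {name: lower_jejunum, volume_l: 0.080, area_cm2: 4700.0,  ph: 6.6, transit_h: 0.75}
    - {name: upper_ileum,   volume_l: 0.080, area_cm2: 2350.0,  ph: 7.0, transit_h: 0.75}
    - {name: lower_ileum,   volume_l: 0.080, area_cm2: 1180.0,  ph: 7.4, transit_h: 0.80}
    - {name: caecum,        volume_l: 0.050, area_cm2: 490.0,   ph: 6.0, transit_h: 4.0}
    - {name: colon,         volume_l: 0.100, area_cm2: 780.0,   ph: 6.8, transit_h: 13.0}
  cyp3a4_expression:            # umol enzyme / L tissue
    liver: 8.5                  # calibrated to clinical oral clearance (see docs)
    gut: 0.60                   # small-intestinal mucosa, literature-scale estimate
  mrp2_expression:              # umol transporter / L tissue
    liver: 0.09                 # reference concentration, tissue of highest expression
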