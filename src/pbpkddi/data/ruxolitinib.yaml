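# Ruxolitinib compound parameter file.
# Provenance classes as in posaconazole.yaml.
name: ruxolitinib
molecular_weight_g_mol: 306.37      # literature
logp: 2.65                          # identified (lit. measurements ~2.1-3.0)
fu_p: 0.033                         # literature (~97% bound)
blood_plasma_ratio: 1.0
pka:
  - {value: 4.3, type: base}        # literature: weak base
solubility:
  reference_value_mg_ml: 1.0        # literature: freely soluble at GI pH
  reference_ph: 7.0
  gain_per_charge: 1.0
partition_method: rodgers_rowland   # main_text
permeability_method: fixed
specific_intestinal_permeability:
  value: 5.2e-4                     # identified (rapid-dissolution, high-permeability tablet)
  unit: cm/min
gfr_fraction: 0.0                   # main_text: renal excretion negligible
clearances:
  # main_text: first-order specific clearances from in vitro intrinsic
  # clearance; elimination fully covered by the two CYP processes
  - {enzyme: CYP3A4, kind: first_order_specific_clearance, value: 0.46}
  - {enzyme: CYP2C9, kind: first_order_specific_clearance, value: 0.65}
formulations:
  tablet:
    kind: weibull
    dissolution_time_t50_min: 15.0  # main_text
    dissolution_shape: 1.10         # main_text
    lag_time_min: 0.0
provenance:
  note: >
    Specific clearances, Weibull dissolution time and shape are main-text
    values.  MW, fu_p and pKa are literature values; logP and the intestinal
    permeability were identified against the reported steady-state exposure
    (the engine's distribution and absorption scaling differ from the
    reference software, so the literature logP overpredicts the
    distribution volume here).
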