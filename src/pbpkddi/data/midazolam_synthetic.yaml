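# SYNTHETIC midazolam compound file.
#
# Stand-in for the published midazolam PBPK model used to estimate the
# posaconazole Ki: that model's parameter file is not redistributed here, so
# this fixture assembles representative public literature values for the
# physicochemistry and calibrates the CYP3A4 specific clearance in-package
# to a typical i.v. midazolam plasma clearance (~25-27 L/h).  It is a
# constructed stand-in, not a transcription.
name: midazolam
molecular_weight_g_mol: 325.77      # literature
logp: 3.13                          # literature
fu_p: 0.03                          # literature (~97% bound)
blood_plasma_ratio: 1.0
pka:
  - {value: 6.0, type: base}        # literature
solubility:
  reference_value_mg_ml: 0.05
  reference_ph: 7.0
  gain_per_charge: 1.0
partition_method: rodgers_rowland
permeability_method: standard_calculated
specific_intestinal_permeability:
  value: 3.0e-4                     # synthetic: high-permeability BCS I compound
  unit: cm/min
gfr_fraction: 0.0
clearances:
  - {enzyme: CYP3A4, kind: first_order_specific_clearance, value: 1.00}  # calibrated
formulations:
  iv:
    kind: iv_infusion
  solution:
    kind: solution
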