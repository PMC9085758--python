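# Well-mixed PKA/AQP2 phosphorylation model (basal conditions).
# Values without a provenance tag are in internal units (uM, s, um).
model: phospho
duration: {value: 5, unit: min}
observe_every: 1.0
seed: 1
params:
  camp_influx: {value: 50, unit: nM/s, provenance: paper}
  k_camp_on_a: {value: 0.07, unit: 1/(uM*s), provenance: paper}
  k_camp_on_b: {value: 0.07, unit: 1/(uM*s), provenance: paper}
  k_camp_off_a: {value: 0.02, unit: 1/s, provenance: placeholder}
  k_camp_off_b: {value: 0.02, unit: 1/s, provenance: placeholder}
  k_pkac_release: {value: 2.0, unit: 1/s, provenance: placeholder}
  k_pkac_bind: {value: 2.0, unit: 1/(uM*s), provenance: placeholder}
  k_pkac_bind_phospho: {value: 0.05, unit: 1/(uM*s), provenance: placeholder}
  k_pkar_phos: {value: 0.3, unit: 1/s, provenance: placeholder}
  k_sub_bind: {value: 1.0, unit: 1/(uM*s), provenance: placeholder}
  k_sub_unbind: {value: 1.0, unit: 1/s, provenance: placeholder}
  k_cat_aqp2: {value: 3.0, unit: 1/s, provenance: placeholder}
  k_cat_pde4: {value: 3.0, unit: 1/s, provenance: placeholder}
  # calibrated once so the basal S256 phospho-ratio sits at 0.46
  k_pp2b_bind: {value: 0.048, unit: 1/(uM*s), provenance: placeholder}
  k_pp2b_unbind: {value: 1.0, unit: 1/s, provenance: placeholder}
  k_dephos: {value: 2.0, unit: 1/s, provenance: placeholder}
  k_pde_camp_on: {value: 2.0, unit: 1/(uM*s), provenance: placeholder}
  k_pde_camp_off: {value: 1.0, unit: 1/s, provenance: placeholder}
  k_hydrolysis: {value: 1.0, unit: 1/s, provenance: placeholder}
  k_hydrolysis_phospho: {value: 3.0, unit: 1/s, provenance: placeholder}
  pkar_total: {value: 2.0, unit: uM, provenance: placeholder}
  pkac_total: {value: 1.0, unit: uM, provenance: placeholder}
  pde4_total: {value: 0.2, unit: uM, provenance: placeholder}
  pp2b_total: {value: 0.5, unit: uM, provenance: placeholder}
  aqp2_total: {value: 2.0, unit: uM, provenance: placeholder}
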