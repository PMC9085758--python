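# Full recycling model, activation variant (scaled-down desk geometry:
# 12x12 um section).  cAMP enters at four basolateral grid points at
# 400 nM/s for the first 5 minutes, 200 nM/s until minute 15, then a
# basal 50 nM/s.  Vesicles depart storage at an AQP2-S256 phospho-ratio
# of 0.75.
model: full_activation
duration: {value: 3, unit: min}
observe_every: 2.0
seed: 1
params:
  n: 12
  D_camp: {value: 32, unit: um^2/s, provenance: paper}
  D_vesicle: {value: 0.13, unit: um^2/s, provenance: paper}
  permeability: {value: 0.01, unit: "", provenance: paper}
  departure_threshold: {value: 0.75, unit: "", provenance: paper}
  basal_ratio: {value: 0.46, unit: "", provenance: paper}
  v_actin: {value: 0.8, unit: um/s, provenance: placeholder}
  v_microtubule: {value: 0.8, unit: um/s, provenance: placeholder}
  k_p: {value: 0.05, unit: 1/(s*um^2), provenance: placeholder}
  k_b: {value: 0.5, unit: 1/s, provenance: placeholder}
  t_cp: {value: 20.0, unit: s, provenance: placeholder}
  c_cp: {value: 2.0, unit: uM*um, provenance: placeholder}
  t_m: {value: 15.0, unit: s, provenance: placeholder}
  permeability_factor: {value: 0.04, unit: "", provenance: placeholder}
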