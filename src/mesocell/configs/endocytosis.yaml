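# Clathrin-mediated endocytosis on a 1 um^2 apical membrane patch with
# the PKA -> CSK -> SRC inhibition cascade regulating cargo collection.
model: endocytosis
duration: {value: 5, unit: min}
observe_every: 5.0
seed: 1
params:
  camp_influx: {value: 50, unit: nM/s, provenance: paper}
  aqp2_density: {value: 5.0, unit: uM*um, provenance: placeholder}
  k_p: {value: 0.2, unit: 1/(s*um^2), provenance: placeholder}
  k_b: {value: 1.0, unit: 1/s, provenance: placeholder}
  t_cp: {value: 30.0, unit: s, provenance: placeholder}
  c_cp: {value: 5.0, unit: uM*um, provenance: placeholder}
  t_m: {value: 30.0, unit: s, provenance: placeholder}
  vesicle_radius: {value: 50, unit: nm, provenance: placeholder}
  clathrin_coat: {value: 2.0, unit: uM*um, provenance: placeholder}
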