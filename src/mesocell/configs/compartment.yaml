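# cAMP compartmentalization: 30x30 grid, restricted storage region with
# the PDE4 sink, influx at four basolateral nodes.
model: compartment
duration: {value: 5, unit: min}
observe_every: 5.0
seed: 1
params:
  n: 30
  ds: {value: 1.0, unit: um, provenance: placeholder}
  D_camp: {value: 32, unit: um^2/s, provenance: paper}
  permeability: {value: 0.01, unit: "", provenance: paper}
  ring: false
  passages: 2
  influx: {value: 400, unit: nM/s, provenance: paper}
  pde4: {value: 0.5, unit: uM, provenance: placeholder}
  kcat_hydrolysis: {value: 6.0, unit: 1/s, provenance: placeholder}
  km_hydrolysis: {value: 2.0, unit: uM, provenance: placeholder}
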