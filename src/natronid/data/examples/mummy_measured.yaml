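# Worked example with the published crocodile-mummy case-study measurements:
# cortical bone mu = 0.274 /cm at bone-mineral density 1.8 g/cm3, inclusion
# average mu = 0.297 /cm and maximum mu = 0.334 /cm.
mode: measured
beamline: body_24um
tolerance: 0.01
reference:
  material: hydroxyapatite
  density: 1.8
  measured_mu: 0.274
measured:
  average_mu: 0.297
  maximum_mu: 0.334
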