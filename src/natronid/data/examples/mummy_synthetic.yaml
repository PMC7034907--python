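# Synthetic demo: mummy-like phantom, end-to-end.
mode: synthetic
seed: 42
beamline: body_24um
energy_keV: 146.1
tolerance: 0.01
reference:
  material: hydroxyapatite
  density: 1.8
  label: 1
segmentation:
  threshold: 0.25
  min_size: 27
phantom:
  shape: [96, 112, 112]
  n_inclusions: 20
  psf_sigma: 0.7
  noise_sigma: 0.01
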