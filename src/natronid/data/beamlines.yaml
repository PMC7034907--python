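# Bending-magnet beamline presets for the four crocodile-mummy acquisition
# configurations (voxel sizes 53.19 / 24.37 / 6.37 / 4.3 um). "10x Al 5" and
# "Al prof 15x5" filter stacks are encoded as their total aluminium thickness.
# The ring/field pair fixes the critical energy (E_c = 0.665 E^2 B ~ 20.6 keV);
# the bending-magnet field is a configurable estimate, so the reported average
# detected energies (~101 / ~139 / ~114 / ~120 keV) are band checks, not
# calibration constants.
head_53um:
  source: {ring_energy_GeV: 6.03, field_T: 0.85}
  filters:
    - {material: aluminium, thickness_mm: 50.0}
    - {material: molybdenum, thickness_mm: 0.35}
  scintillator: {material: luag, thickness_um: 2000}
  nominal_average_keV: 101
body_24um:
  source: {ring_energy_GeV: 6.03, field_T: 0.85}
  filters:
    - {material: molybdenum, thickness_mm: 0.3}
    - {material: copper, thickness_mm: 12.0}
  scintillator: {material: luag, thickness_um: 2000}
  nominal_average_keV: 139
detail_6um:
  source: {ring_energy_GeV: 6.03, field_T: 0.85}
  filters:
    - {material: copper, thickness_mm: 6.0}
    - {material: molybdenum, thickness_mm: 0.4}
  scintillator: {material: ggg, thickness_um: 500}
  nominal_average_keV: 114
plants_4um:
  source: {ring_energy_GeV: 6.03, field_T: 0.85}
  filters:
    - {material: aluminium, thickness_mm: 75.0}
    - {material: molybdenum, thickness_mm: 0.35}
  scintillator: {material: luag, thickness_um: 200}
  nominal_average_keV: 120
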