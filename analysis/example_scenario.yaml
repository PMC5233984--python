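# Example scenario document for tchannel.load_scenario.
# Every key is optional; omitted sections fall back to the study defaults.
# Unknown sections or keys are rejected.
grid:
  spacing: 0.5            # mm, isotropic voxel size
head:
  scalp: 5.0              # layer thicknesses, mm
  skull: 7.0
  dura: 0.5
  csf: 2.0                # at the gyral crown
  gm: 2.5
  fold_amplitude: 3.0
  fold_wavelength: 20.0
channel:
  shape: T                # T, I, or NONE
  shaft_diameter: 7.0     # mm; hat diameter defaults to shaft + 1
  hat_side: outer
montage:
  ring_radius: 35.0       # center-to-return distance, mm
  current_mA: 1.0
  displacement: [0.0, 0.0]
conductivity:             # S/m, overrides only
  skull: 0.01
solver:
  rtol: 1.0e-9
roi:
  radius: 5.0             # mm
  spacing: 0.84           # lattice pitch -> ~112 neurons
membrane:
  r_m: 30000.0            # Ohm cm^2
  r_a: 150.0              # Ohm cm
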