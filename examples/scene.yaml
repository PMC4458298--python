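# Two dye-filled tube inclusions in an absorbing rectangular phantom.
# Optics are liver-like soft tissue (mm^-1); six-frame dynamic study.
scene:
  geometry: {width_mm: 25, height_mm: 30, edge_mm: 1.0}
  optics:
    mu_a_x: 0.16
    mu_s_prime_x: 0.578
    mu_a_m: 0.124
    mu_s_prime_m: 0.542
    refractive_index: 1.0
  n_excitation_sources: 4
  detector_every: 2
  inclusions:
    - label: tube 1
      center: [4.0, 15.0]
      radius: 2.0
      course:
        times: [5, 10, 15, 30, 60, 120]
        values: [1.0, 0.85, 0.7, 0.45, 0.2, 0.05]
    - label: tube 2
      center: [21.0, 15.0]
      radius: 2.0
      course:
        times: [5, 10, 15, 30, 60, 120]
        values: [0.43, 0.61, 0.78, 0.99, 1.0, 0.21]
noise:
  psnr_db: 40
  seed: 0
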