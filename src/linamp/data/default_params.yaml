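# Default calibration of the negative-feedback (linearizer) circuit model.
# Units: hours, molecule counts per cell; Dox in ng/mL enters through f.
# These values are a documented calibration: they are chosen so that the
# wild-type dose response is monotone and approximately linear over the
# induction range below, and so that a 1..15 copy-number sweep at
# 0.05 ng/mL Dox shows rising expression together with a rising fraction
# of repressed promoters (leak-dominated transcription).
parameters:
  m: 30.0          # max transcription rate per unbound promoter copy (1/h)
  leak_r1: 0.10    # leak fraction, singly bound promoter
  leak_r2: 0.02    # leak fraction, doubly bound promoter
  r: 5.0           # TetR->operator association (1/(molecule h))
  k_off: 50.0      # TetR-operator dissociation (1/h); fast promoter flicker, Kd = 10
  f: 100.0         # Dox influx constant (molecules/h per ng/mL)
  g_dox: 0.1       # intracellular Dox clearance (1/h)
  k_seq_on: 5.0    # TetR-Dox association (1/(molecule h))
  k_seq_off: 0.01  # TetR-Dox dissociation (1/h); near-irreversible capture
  k_tl_tetr: 2.0   # TetR translation per mRNA (1/h)
  k_tl_gfp: 2.0    # eGFP translation per mRNA (1/h)
  d_m: 1.0         # mRNA decay (1/h)
  d_tetr: 0.2      # free TetR decay (1/h)
  d_gfp: 0.2       # eGFP decay (1/h)
  d_complex: 0.2   # TetR:Dox complex decay (1/h)
  copy_number: 1
  dox_ext: 0.05    # ng/mL; the maintenance dose used throughout

calibration:
  # Dox range (ng/mL) over which the default dose response is designed to
  # be approximately linear, and the grid used for linearity checks.
  dox_linear_min: 0.0
  dox_linear_max: 0.1
  dox_grid_points: 6
  # Copy-number sweep conditions.
  sweep_n_min: 1
  sweep_n_max: 15
  sweep_dox: 0.05
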