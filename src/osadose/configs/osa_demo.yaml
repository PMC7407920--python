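# Demonstration configuration: applicator with a 3-mm phantom above and a
# 15-mm backscatter phantom below, 532-nm light, two 2-cm diffusers 3 cm
# apart delivering a total of 200 mW/cm for 278 s, plate prediction at 10 uM.
scene:
  wavelength: 532
  top_phantom_mm: 3.0
  backscatter_mm: 15.0
  voxel_size_mm: 1.0
source:
  linear_power_mw_per_cm: 200.0   # total across both fibers, split equally
  duration_s: 278.0
  per_fiber: false
transport:
  n_packets: 100000
  seed: 1
kill_model:
  concentration_um: 10.0
  f50_j_cm2: 5.0
  f_kill_j_cm2: 20.0
  kill_floor: 0.01
plate:
  overhang_cols: 1
  noise_sd: 0.05
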