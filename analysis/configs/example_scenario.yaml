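# Example custom scenario for `depotflow simulate --config <this file>`:
# 500 uL at 50 uL/min into mildly anisotropic tissue, 1% frame drift,
# smooth-front rim and default detector noise.
protocol:
  flow_rate_ul_min: 50.0
  total_volume_ul: 500.0
  mode: continuous
  needle_tip: [128, 128]
  frame_interval_s: 30.0
tissue:
  epsilon: 1.0
  anisotropy: 0.85
  crack_width_um: 800.0
  youngs_modulus_kpa: 1.01
  fracture_threshold_kj_m2: 4.1
  lag_volume_ul: 50.0
  mu_abs_per_mm: 0.15
detector:
  gain_level: 30000.0
  offset_level: 1000.0
  gain_pattern_rel: 0.03
  offset_pattern_abs: 20.0
  photons_per_pixel: 10000.0
  read_noise: 30.0
frame_times_s: [0, 30, 60, 90, 120, 150, 180, 210, 240, 270, 300, 330, 360,
                390, 420, 450, 480, 510, 540, 570, 600]
frame_shape: [256, 256]
pixel_size_um: 40.0
seed: 0
noiseless: false
drift_schedule:
  - [0.0, 0.0, 0.0]
  - [600.0, 2.0, 1.0]
dr_relax_exponent: 0.0
dr_relax_scale: 0.02
rim_taper_mm: 0.0
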