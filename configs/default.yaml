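# Full study-scale configuration: 91 rats recorded for 3 hours at 1 kHz
# during a single-step hypoglycemic clamp, delineated and clustered over the
# complete senator x cluster x timepoint grid. Every parameter the pipeline
# accepts is spelled out here; values not overridden elsewhere are these.
outdir: run_output
seed: 0

sim:
  n_rats: 91
  frac_diabetic: 0.40659340659340659   # 37 of 91
  frac_died: 0.26373626373626374       # 24 of 91
  duration_min: 180.0
  fs_hz: 1000.0
  hr_bpm: [300.0, 450.0]
  glucose_draw_min: 15.0
  glucose_plateau_mgdl: 12.5
  glucose_noise_sd: 0.8
  clamp_descent_min: 60.0
  wander_amp_mv: 0.1
  wander_freq_hz: 0.3
  powerline_freq_hz: 60.0
  powerline_amp_mv: 0.05
  white_noise_sd_mv: 0.015
  pvc_prob_severe: 0.05
  pvc_prob_severe_died_diabetic: 0.15
  truncate_at_death: false
  seed: 0

filter_params:
  low_cut_hz: 0.5
  high_cut_hz: 100.0
  order: 3
  notch_hz: 60.0
  quality_factor: 30.0

delineation:
  min_prominence: null        # null -> 6 x MAD of the segment
  mad_factor: 6.0
  min_width_ms: 1.0
  min_relative_height: 0.4
  refractory_ms: 90.0
  p_window_ms: [110.0, 15.0]
  p_floor_mv: 0.06
  t_window_ms: [10.0, 90.0]
  s_search_ms: 35.0
  pre_ms: 50.0
  post_ms: 100.0

senator_list: [100, 150, 200, 250, 300, 350, 400, 450, 500]
cluster_list: [10, 15, 20, 25, 30, 35, 40, 45, 50]
time_list: [100, 200, 250, none]
max_iter: 100
write_signals: false
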