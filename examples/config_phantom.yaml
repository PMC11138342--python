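# Example configuration covering every tunable of the chain.
# Use with:  difc simulate --config examples/config_phantom.yaml -o scan.csv
#            difc detect scan.csv --config examples/config_phantom.yaml -o cands.csv

simulate:
  duration_s: 600
  sampling_rate: 2000          # samples/s
  probe_separation_mm: 3
  flow_rate_ul_min: 25         # syringe-pump flow through the phantom tube
  concentration_per_ml: {green: 1000, orange: 1000}
  cluster_size_mean: 1         # 1 = single-cell suspension
  two_fp_mixing: 0.0           # probability a >=2-cell cluster mixes colors
  speed_mean_mm_s: 30
  speed_gsd: 1.15
  sensing_length_mm: 1         # transit FWHM = sensing_length / speed
  cell_amp_median_mv: {green: 80, orange: 80}
  cell_amp_gsd: 2.0
  tr_true: {green: 0.04, orange: 0.06}   # generative bleed ratios
  noise_sigma_mv: 2.0
  background_mv: 50
  drift_amp_mv: 10
  drift_period_s: 120
  direction_forward_frac: 1.0
  artifact_rate_per_min: 0.0
  saturation_limit_mv: 1500    # detector rail

detect:
  bg_window_s: 5               # moving-median background window
  noise_window_s: 60           # moving-std noise window
  k: 5                         # detection threshold in local-noise sigmas
  mask_peaks_for_noise: true   # recommended at phantom event rates

match:
  speed_min_mm_s: 5
  speed_max_mm_s: 150
  amp_ratio_tol: 2
  width_ratio_tol: 2
  artifact_window_s: 0.010

classify:
  coincidence_window_s: null   # null = half the mean peak width, >= 5 ms
  saturation_limit_mv: 1500
  ref_green_mv: null           # null = median single-color amplitude
  ref_orange_mv: null
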