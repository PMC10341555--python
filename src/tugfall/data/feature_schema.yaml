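- number: 1
  name: mse_mean_ML
  block: full_tug
  axis: ML
- number: 2
  name: mse_mean_V
  block: full_tug
  axis: V
- number: 3
  name: mse_mean_AP
  block: full_tug
  axis: AP
- number: 4
  name: mse_sd_ML
  block: full_tug
  axis: ML
- number: 5
  name: mse_sd_V
  block: full_tug
  axis: V
- number: 6
  name: mse_sd_AP
  block: full_tug
  axis: AP
- number: 7
  name: mse_ci_ML
  block: full_tug
  axis: ML
- number: 8
  name: mse_ci_V
  block: full_tug
  axis: V
- number: 9
  name: mse_ci_AP
  block: full_tug
  axis: AP
- number: 10
  name: pe_ML
  block: full_tug
  axis: ML
- number: 11
  name: pe_V
  block: full_tug
  axis: V
- number: 12
  name: pe_AP
  block: full_tug
  axis: AP
- number: 13
  name: stand_duration
  block: sist
  axis: null
- number: 14
  name: sist_range_ML
  block: sist
  axis: ML
- number: 15
  name: sist_range_V
  block: sist
  axis: V
- number: 16
  name: sist_range_AP
  block: sist
  axis: AP
- number: 17
  name: sist_max_ML
  block: sist
  axis: ML
- number: 18
  name: sist_max_V
  block: sist
  axis: V
- number: 19
  name: sist_max_AP
  block: sist
  axis: AP
- number: 20
  name: sist_rms_ML
  block: sist
  axis: ML
- number: 21
  name: sist_rms_V
  block: sist
  axis: V
- number: 22
  name: sist_rms_AP
  block: sist
  axis: AP
- number: 23
  name: sist_max_jerk_ML
  block: sist
  axis: ML
- number: 24
  name: sist_max_jerk_V
  block: sist
  axis: V
- number: 25
  name: sist_max_jerk_AP
  block: sist
  axis: AP
- number: 26
  name: sist_min_ML
  block: sist
  axis: ML
- number: 27
  name: sist_min_V
  block: sist
  axis: V
- number: 28
  name: sist_min_AP
  block: sist
  axis: AP
- number: 29
  name: sist_mean_jerk_ML
  block: sist
  axis: ML
- number: 30
  name: sist_mean_jerk_V
  block: sist
  axis: V
- number: 31
  name: sist_mean_jerk_AP
  block: sist
  axis: AP
- number: 32
  name: sist_sd_ML
  block: sist
  axis: ML
- number: 33
  name: sist_sd_V
  block: sist
  axis: V
- number: 34
  name: sist_sd_AP
  block: sist
  axis: AP
- number: 35
  name: walk_duration
  block: walk
  axis: null
- number: 36
  name: cadence
  block: walk
  axis: null
- number: 37
  name: step_length
  block: walk
  axis: null
- number: 38
  name: gait_speed
  block: walk
  axis: null
- number: 39
  name: step_time
  block: walk
  axis: null
- number: 40
  name: stride_time
  block: walk
  axis: null
- number: 41
  name: cv_step_time
  block: walk
  axis: null
- number: 42
  name: cv_stride_time
  block: walk
  axis: null
- number: 43
  name: walk_rms_ML
  block: walk
  axis: ML
- number: 44
  name: walk_rms_V
  block: walk
  axis: V
- number: 45
  name: walk_rms_AP
  block: walk
  axis: AP
- number: 46
  name: turn_cv_ML
  block: turn
  axis: ML
- number: 47
  name: turn_cv_V
  block: turn
  axis: V
- number: 48
  name: turn_cv_AP
  block: turn
  axis: AP
- number: 49
  name: turn_median_ML
  block: turn
  axis: ML
- number: 50
  name: turn_median_V
  block: turn
  axis: V
- number: 51
  name: turn_median_AP
  block: turn
  axis: AP
- number: 52
  name: turn_range_ML
  block: turn
  axis: ML
- number: 53
  name: turn_range_V
  block: turn
  axis: V
- number: 54
  name: turn_range_AP
  block: turn
  axis: AP
- number: 55
  name: turn_rms_ML
  block: turn
  axis: ML
- number: 56
  name: turn_rms_V
  block: turn
  axis: V
- number: 57
  name: turn_rms_AP
  block: turn
  axis: AP
- number: 58
  name: sit_duration
  block: stsi
  axis: null
- number: 59
  name: stsi_range_ML
  block: stsi
  axis: ML
- number: 60
  name: stsi_range_V
  block: stsi
  axis: V
- number: 61
  name: stsi_range_AP
  block: stsi
  axis: AP
- number: 62
  name: stsi_rms_ML
  block: stsi
  axis: ML
- number: 63
  name: stsi_rms_V
  block: stsi
  axis: V
- number: 64
  name: stsi_rms_AP
  block: stsi
  axis: AP
- number: 65
  name: stsi_min_ML
  block: stsi
  axis: ML
- number: 66
  name: stsi_min_V
  block: stsi
  axis: V
- number: 67
  name: stsi_min_AP
  block: stsi
  axis: AP
- number: 68
  name: stsi_max_ML
  block: stsi
  axis: ML
- number: 69
  name: stsi_max_V
  block: stsi
  axis: V
- number: 70
  name: stsi_max_AP
  block: stsi
  axis: AP
- number: 71
  name: stsi_max_jerk_ML
  block: stsi
  axis: ML
- number: 72
  name: stsi_max_jerk_V
  block: stsi
  axis: V
- number: 73
  name: stsi_max_jerk_AP
  block: stsi
  axis: AP
- number: 74
  name: stsi_mean_jerk_ML
  block: stsi
  axis: ML
- number: 75
  name: stsi_mean_jerk_V
  block: stsi
  axis: V
- number: 76
  name: stsi_mean_jerk_AP
  block: stsi
  axis: AP
- number: 77
  name: stsi_sd_ML
  block: stsi
  axis: ML
- number: 78
  name: stsi_sd_V
  block: stsi
  axis: V
- number: 79
  name: stsi_sd_AP
  block: stsi
  axis: AP
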