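# Demo run configuration: the full default study conditions.
# Every key is optional; unknown keys are rejected.
seed: 17

# cohort
n_subjects: 28          # QC-passing subjects
n_qc_fail: 4            # extra heavy movers excluded at QC

# resting-state simulation and scrubbing
n_volumes: 256
tr_s: 1.7
fd_thresh_mm: 0.5
max_scrubbed: 108
n_networks: 12
rois_per_network: 6
within_r: 0.35
between_r: 0.12
seg_within_slope: 0.04
between_mode: pooled    # or pair_means

# writing simulation and kinematics
duration_s: 27.0
fs_hz: 200.0
target_cm: 1.0
strokes_per_s: 1.5
base_speed_cm_s: 2.0
cutoff_hz: 7.0
filter_order: 4
prominence_frac: 0.05

# composite scores
var_threshold: 0.80

# inference
n_boot: 1000
ci_level: 0.95
p_retain: 0.1
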