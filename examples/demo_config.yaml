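# Demonstration cohort: 20 ROIs, 15 + 15 subjects, one injected
# connectivity effect on ROI 5 (group B's intensity distribution in that
# region is shifted by +0.15), pain scores tracking ROI 5's mean intensity.
cohort:
  n_rois: 20
  grid_shape: [12, 12, 12]
  voxel_size: [1.0, 1.0, 1.0]
  n_per_group: [15, 15]
  seed: 42
  mc_effect_rois:
    5: {mean_delta: 0.15}
  pain_score_model:
    intercept: 7.5
    slope: 0.9
    noise_sd: 1.0
    feature_roi: 5

analysis:
  bandwidth_method: silverman
  grid_points: 512
  sweep: {s_min: 0.05, s_max: 0.40, step: 0.02}
  n_nulls: 10
  null_seed: 0
  q: 0.05
  ttest_variant: student
  degree_report_fraction: 0.5
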