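# Demo pipeline configuration: every key shown with its default-ish demo
# value. Run with:  climmed run --config examples/demo_config.yaml
data: null                      # path to a cohort CSV; null -> simulate
generator:                      # any GeneratorConfig field, plus:
  n_individuals: 5000
  seed: 20180401
  calibrate: true               # calibrate intercepts to the survey margins
outcome: overweight             # or obesity
covariates: [sex, age, education]
covariates_in_mediators: true
quadrature_points: 7            # adaptive Gauss-Hermite nodes (outcome eq.)
temperature_column: mean_temp_c # sensitivity switch: e.g. median_temp_c
bootstrap:
  n_reps: 200                   # published analysis uses 5000
  resample_size: 2000           # published analysis uses 10000
  seed: 20180402
  quadrature_points: 7          # 0 -> replicate fits without random intercept
decimals: 4
output_dir: climmed_run
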