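# End-to-end demo: simulate a four-occasion achievement cohort at the
# canonical generating regime, preprocess, and fit the simplex model.
models: [simplex]
output_dir: demo_output
seed: 42
n_restarts: 4
simulate:
  model: simplex
  n_mz: 2000
  n_dz: 2000
  params:
    a:
      init_sd: 0.8544
      betas: [0.86, 0.84, 0.86]
      innov_sd: [0.4001, 0.3689, 0.3377]
      spec_sd: [0.0, 0.0, 0.0, 0.0]
    c:
      init_sd: 0.4472
      betas: [0.9, 0.9, 0.9]
      innov_sd: [0.1949, 0.1949, 0.1949]
      spec_sd: [0.0, 0.0, 0.0, 0.0]
    e:
      init_sd: 0.2646
      betas: [0.0, 0.0, 0.0]
      innov_sd: [0.3162, 0.4123, 0.4690]
      spec_sd: [0.0, 0.0, 0.0, 0.0]
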