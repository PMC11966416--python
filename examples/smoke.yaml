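# Smoke-scale end-to-end run: simulate -> train -> evaluate in well under a
# minute on one CPU.  Remove the generator/model blocks to run at the full
# default scale (915 fields, d_model 256).
output_dir: vmatqa_out
seed: 5
split_seed: 5
model_name: informer_cnn
generator:
  n_plans: 7
  n_fields: 10
  span_days: 120
  window_days: 8
model:
  d_model: 32
  ffn_dim: 64
  window: 8
  conv_channels: [4, 4, 4]
  head_hidden: 16
  max_epochs: 3
  patience: 5
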