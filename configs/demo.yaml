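# Desk-scale demo: three-subtype planted-signal repertoire, tiny encoder.
seed: 7
out_dir: runs/demo
data:
  n_records: 300
  subtype_labels: [naive, switched_memory, plasma]
  motif_strength: 1.0
  heavy_fraction: 1.0
  mode: hcdr3
  max_len: 32
model:
  n_layers: 2
  n_heads: 2
  hidden_dim: 32
  ffn_dim: 64
training:
  w_cl: 0.5
  total_steps: 300
  batch_size: 24
  peak_lr: 0.001
  eval_interval: 75
eval:
  probe_steps: 300
explain:
  ig_steps: 50
  n_records: 2
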