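# Desk-scale end-to-end demo: all stages on synthetic fixtures.
seed: 1
out_dir: pleioscan_out
simulate:
  n_snps: 5000
  planted_loci: [[10, 6.0, 6.0], [500, 6.5, 6.0]]
  n_pos: 600
  n_neg: 600
  seq_length: 80
cnn:
  max_epochs: 18
  conv_filters: [16, 8]
  filter_sizes: [9, 5]
  pool_widths: [1, 1]
  fc_units: [16]
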