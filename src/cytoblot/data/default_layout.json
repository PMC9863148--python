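{
  "name": "synthetic-2x2x10x10",
  "n_block_rows": 2,
  "n_block_cols": 2,
  "rows_per_block": 10,
  "cols_per_block": 10,
  "pitch": 18.0,
  "alley_row": 1.0,
  "alley_col": 1.0,
  "spot_radius": 6.0
}
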