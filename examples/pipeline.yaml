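# Full pipeline configuration: synth -> features -> train -> reconstruct.
# Thresholds default to the recording-protocol values used throughout
# the package (5 kHz, 8000-sample windows, 90 dB S/N cut, 0.5 mV amplitude).
seed: 7
synth:
  n_pairs: 200
  fs: 5000.0
  apd90_range: [0.2, 1.2]
  amplitude_range_mv: [0.5, 10.0]
  snr_db_range: [80.0, 110.0]
network:
  input_len: 2000
  epochs: 20
  batch_size: 16
  lr: 0.0015
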