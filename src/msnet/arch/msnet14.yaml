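input:
  height: 256
  width: 256
  channels: 1
pooling_mode: stochastic
batch_norm: true
layers:
- type: conv
  kernel:
  - 3
  - 3
  in_channels: 1
  filters: 8
  stride: 2
  padding: same
- type: pool
  kernel: 3
  stride: 2
- type: conv
  kernel:
  - 3
  - 3
  in_channels: 8
  filters: 8
  stride: 2
  padding: same
- type: pool
  kernel: 3
  stride: 2
- type: conv
  kernel:
  - 3
  - 3
  in_channels: 8
  filters: 16
  stride: 1
  padding: same
- type: conv
  kernel:
  - 3
  - 3
  in_channels: 16
  filters: 16
  stride: 1
  padding: same
- type: conv
  kernel:
  - 3
  - 3
  in_channels: 16
  filters: 16
  stride: 1
  padding: same
- type: pool
  kernel: 3
  stride: 2
- type: conv
  kernel:
  - 3
  - 3
  in_channels: 16
  filters: 32
  stride: 1
  padding: same
- type: conv
  kernel:
  - 3
  - 3
  in_channels: 32
  filters: 32
  stride: 1
  padding: same
- type: conv
  kernel:
  - 3
  - 3
  in_channels: 32
  filters: 32
  stride: 1
  padding: same
- type: conv
  kernel:
  - 3
  - 3
  in_channels: 32
  filters: 64
  stride: 1
  padding: same
- type: conv
  kernel:
  - 3
  - 3
  in_channels: 64
  filters: 64
  stride: 1
  padding: same
- type: conv
  kernel:
  - 3
  - 3
  in_channels: 64
  filters: 64
  stride: 1
  padding: same
- type: pool
  kernel: 3
  stride: 2
- type: fc
  out_features: 20
- type: dropout
  probability: 0.5
- type: fc
  out_features: 10
- type: dropout
  probability: 0.5
- type: fc
  out_features: 2
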