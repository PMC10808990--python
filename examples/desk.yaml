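# Desk-scale recipe: 64x64 scenes, 20-epoch schedule with the lr drop
# scaled from the full-scale 90-of-100 epochs.
scene:
  width: 64
  height: 64
train:
  initial_lr: 0.002
  epochs: 20
  lr_drop_epoch: 18
  eval_every: 0
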