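# Demo run: synthetic genome + all libraries at moderate depth,
# then every analysis stage.  Completes in well under 10 minutes on one CPU.
seed: 0
depth: 50000
outdir: demo_run
mappability:
  read_length: 36
hic:
  resolution: 5000
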