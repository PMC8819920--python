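# Example end-to-end configuration.
#
# Generate the matching input first:
#   sclrtools simulate --cells 10 --molecules-per-cell 30 \
#       --splint-dup-rate 0.3 --tenx-dup-rate 0.3 --seed 1 \
#       --out-prefix examples/run/sim
# then:
#   sclrtools run examples/config.yaml
reads: examples/run/sim.fastq
out_dir: examples/run/out
seed: 1
log_level: INFO
chemistry: {}
whitelist:
  expected_cells: 10
umi:
  umi_max_edits: 1
merge: {}
diff: {}
vfilter: {}
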