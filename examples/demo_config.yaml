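# All-synthetic demo: generates every input, then runs every stage.
# Run from the repository root:
#   atdqc run --config examples/demo_config.yaml
seed: 7
outdir: atdqc_demo_out
stages:
  simulate: {enabled: true}
  structure: {enabled: true}
  classify: {enabled: true}
  wobble: {enabled: true}
  kinetics: {enabled: true}
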