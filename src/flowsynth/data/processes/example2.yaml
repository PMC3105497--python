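# Random protein sequences in, sequence-feature display out.
initial: start
nodes:
  start: makeprotseq
  end: showfeat
edges:
  - {src: start, dst: end, loose: true}
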