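# Loosely specified workflow: random nucleotide sequences in, pretty-printed
# alignment out; the loose branch is the synthesis problem.
initial: start
nodes:
  start: makenucseq
  end: showalign
edges:
  - {src: start, dst: end, loose: true}
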