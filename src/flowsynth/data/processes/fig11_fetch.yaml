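# Variant that fetches the HMM from a database instead of building it.
initial: n_fetch
nodes:
  n_fetch: ehmmfetch
  n_emit: ehmmemit
  n_show: showseq
edges:
  - {src: n_fetch, dst: n_emit}
  - {src: n_emit, dst: n_show}
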