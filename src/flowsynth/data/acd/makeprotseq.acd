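# Synthetic ACD descriptor fixture (authored for the flowsynth test domain;
# not an original EMBOSS distribution file).
application: makeprotseq [
  documentation: "Create random protein sequences."
  groups: "Edit"
]

section: output [
  information: "Output section"
  type: "page"
]

  seqoutall: outseq [
    parameter: "Y"
    relation: "EDAM: 0000004 ! protein_sequence_record"
  ]

endsection: output
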