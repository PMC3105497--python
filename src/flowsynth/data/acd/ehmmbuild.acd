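# Synthetic ACD descriptor fixture (authored for the flowsynth test domain;
# not an original EMBOSS distribution file).
application: ehmmbuild [
  documentation: "Build a profile HMM from an alignment."
  groups: "Hmm"
]

section: input [
  information: "Input section"
  type: "page"
]

  seqset: alignfile [
    parameter: "Y"
    relation: "EDAM: 0009101 ! protein_sequence_alignment_data"
  ]

endsection: input

section: output [
  information: "Output section"
  type: "page"
]

  outfile: outfile [
    parameter: "Y"
    relation: "EDAM: 0009105 ! hmm"
  ]

endsection: output
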