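# Synthetic ACD descriptor fixture (authored for the flowsynth test domain;
# not an original EMBOSS distribution file).
application: edialign [
  documentation: "Local multiple alignment of sequences."
  groups: "Alignment:Multiple"
  relation: "EDAM: 0000021 ! sequence_alignment"
]

section: input [
  information: "Input section"
  type: "page"
]

  seqset: sequences [
    parameter: "Y"
    type: "gapany"
    relation: "EDAM: 0000003 ! sequence_record"
  ]

endsection: input

section: output [
  information: "Output section"
  type: "page"
]

  outfile: outfile [
    parameter: "Y"
    knowntype: "edialign output"
  ]

  seqoutall: outseq [
    parameter: "Y"
    relation: "EDAM: 0000003 ! sequence_record"
  ]

endsection: output
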