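# Synthetic ACD descriptor fixture (authored for the flowsynth test domain;
# not an original EMBOSS distribution file).
application: showpep [
  documentation: "Displays protein sequences with features in pretty format."
  groups: "Display"
]

section: input [
  information: "Input section"
  type: "page"
]

  seqall: sequence [
    parameter: "Y"
    relation: "EDAM: 0000004 ! protein_sequence_record"
  ]

endsection: input

section: output [
  information: "Output section"
  type: "page"
]

  outfile: outfile [
    parameter: "Y"
    knowntype: "showpep output"
  ]

endsection: output
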