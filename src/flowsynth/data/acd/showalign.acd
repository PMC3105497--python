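# Synthetic ACD descriptor fixture (authored for the flowsynth test domain;
# not an original EMBOSS distribution file).
application: showalign [
  documentation: "Display a multiple sequence alignment in pretty format."
  groups: "Display"
  relation: "EDAM: 0000022 ! sequence_visualisation"
]

section: input [
  information: "Input section"
  type: "page"
]

  infile: file [
    parameter: "Y"
    relation: "EDAM: 0009107 ! sequence_alignment_data"
  ]

endsection: input

section: output [
  information: "Output section"
  type: "page"
]

  outfile: outfile [
    parameter: "Y"
    knowntype: "showalign output"
  ]

endsection: output
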