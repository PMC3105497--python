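# Synthetic ACD descriptor fixture (authored for the flowsynth test domain;
# not an original EMBOSS distribution file).
application: ehmmemit [
  documentation: "Generate sequences from a profile HMM."
  groups: "Hmm"
]

section: input [
  information: "Input section"
  type: "page"
]

  infile: hmmfile [
    parameter: "Y"
    relation: "EDAM: 0009102 ! hmmer_hidden_markov_model"
  ]

endsection: input

section: output [
  information: "Output section"
  type: "page"
]

  outfile: outfile [
    parameter: "Y"
    knowntype: "hmmemit output"
  ]

endsection: output
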