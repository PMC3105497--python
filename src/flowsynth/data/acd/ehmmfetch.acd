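# Synthetic ACD descriptor fixture (authored for the flowsynth test domain;
# not an original EMBOSS distribution file).
application: ehmmfetch [
  documentation: "Retrieve an HMM from an HMM database."
  groups: "Hmm"
]

section: input [
  information: "Input section"
  type: "page"
]

  string: name [
    parameter: "Y"
    relation: "EDAM: 0009103 ! hmmer_hidden_markov_model_identifier"
  ]

  infile: database [
    parameter: "Y"
    relation: "EDAM: 0009104 ! hmmer_hidden_markov_model_database"
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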