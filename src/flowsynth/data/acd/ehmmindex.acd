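# Synthetic ACD descriptor fixture (authored for the flowsynth test domain;
# not an original EMBOSS distribution file).
application: ehmmindex [
  documentation: "Create a binary SSI index for an HMM database."
  groups: "Hmm"
]

section: input [
  information: "Input section"
  type: "page"
]

  infile: database [
    parameter: "Y"
    relation: "EDAM: 0009104 ! hmmer_hidden_markov_model_database"
  ]

endsection: input
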