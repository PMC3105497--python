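"""Hand-transcribed reference: input/output types of the generated
HMMER-subset domain, used to pin the importer's naming rules."""

TABLE3 = {
    "edialign": ({"sequence_record"}, {"edialign_seqoutall_output", "edialign_output"}),
    "ehmmalign": ({"protein_sequence_record", "hmmer_hidden_markov_model"},
                  {"ehmmalign_align_output"}),
    "ehmmbuild": ({"protein_sequence_alignment_data"}, {"hmm"}),
    "ehmmcalibrate": ({"hmmer_hidden_markov_model"},
                      {"hmmer_histogram", "hmmcalibrate_output"}),
    "ehmmconvert": ({"hmmer_hidden_markov_model"}, {"hmm"}),
    "ehmmemit": ({"hmmer_hidden_markov_model"}, {"hmmemit_output"}),
    "ehmmfetch": ({"hmmer_hidden_markov_model_identifier",
                   "hmmer_hidden_markov_model_database"}, {"hmm"}),
    "ehmmindex": ({"hmmer_hidden_markov_model_database"}, set()),
    "ehmmpfam": ({"protein_sequence_record", "hmmer_hidden_markov_model"},
                 {"hmmpfam_output"}),
    "ehmmsearch": ({"protein_sequence_record", "hmmer_hidden_markov_model"},
                   {"hmmsearch_output"}),
    "emma": ({"sequence_record"}, {"emma_seqoutset_output", "dendrogram"}),
    "makenucseq": (set(), {"makenucseq_seqoutall_output"}),
    "makeprotseq": (set(), {"makeprotseq_seqoutall_output"}),
    "showalign": ({"sequence_alignment_data"}, {"showalign_output"}),
    "showfeat": ({"sequence_record"}, {"showfeat_output"}),
    "showpep": ({"protein_sequence_record"}, {"showpep_output"}),
    "showseq": ({"dna_sequence_record"}, {"showseq_output"}),
}
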