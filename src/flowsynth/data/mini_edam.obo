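format-version: 1.2
ontology: mini-edam
remark: Compact EDAM-style ontology covering the data and operation terms used by the bundled HMMER-subset ACD descriptors. Synthetic fixture modelled on the EDAM data/operation branches; term ids are local to this file.

[Term]
id: EDAM:0000001
name: data

[Term]
id: EDAM:0000002
name: identifier
is_a: EDAM:0000001 ! data

[Term]
id: EDAM:0000003
name: sequence_record
is_a: EDAM:0000001 ! data

[Term]
id: EDAM:0000004
name: protein_sequence_record
is_a: EDAM:0000003 ! sequence_record

[Term]
id: EDAM:0000005
name: dna_sequence_record
is_a: EDAM:0000003 ! sequence_record

[Term]
id: EDAM:0000006
name: sequence_report
is_a: EDAM:0000001 ! data

[Term]
id: EDAM:0000007
name: sequence_signature
is_a: EDAM:0000001 ! data

[Term]
id: EDAM:0000008
name: sequence_profile_alignment
is_a: EDAM:0000001 ! data

[Term]
id: EDAM:0000020
name: operation

[Term]
id: EDAM:0000021
name: sequence_alignment
is_a: EDAM:0000020 ! operation

[Term]
id: EDAM:0000022
name: sequence_visualisation
is_a: EDAM:0000020 ! operation

[Term]
id: EDAM:0000099
name: alignment_format
is_obsolete: true
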