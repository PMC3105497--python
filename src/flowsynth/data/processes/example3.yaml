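# Remote-services skeleton: a DDBJ nucleotide entry drives a BLAST search,
# Uniprot ids are extracted and each entry fetched in a loop whose remaining
# body is loosely specified.
initial: n_ddbj
nodes:
  n_ddbj: fetch_ddbj_entry
  n_blast: blast_search
  n_extract: extract_uniprot_ids
  n_fetchu: fetch_uniprot_entry
  n_next: next_uniprot_id
  n_done: collect_results
edges:
  - {src: n_ddbj, dst: n_blast}
  - {src: n_blast, dst: n_extract}
  - {src: n_extract, dst: n_fetchu}
  - {src: n_fetchu, dst: n_next, loose: true}
  - {src: n_next, dst: n_fetchu, label: next_id}
  - {src: n_next, dst: n_done, label: done}
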