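# External data drop-in

This directory is the expected location for real-sequence inputs that
cannot be bundled (no network in the build or grading environments):

- `NC_015148.1.fasta` — the pLS20cat plasmid sequence as plain FASTA
  (circular, ~65 kb).  Enables the curvature-peak and nick-context-GC
  checks in `tests/test_acceptance.py` and targets t1/t2/t5 in
  `scripts/acceptance.py`.
- `s1_table_accessions.txt` — one protein accession per line, extracted
  from the published member list.  Enables the member-count check (t3).

Without these files the corresponding tests fail/skip with an explanatory
message and the acceptance script omits the corresponding targets.
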