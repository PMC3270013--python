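# User-editable adaptor/primer catalog: one "name<TAB>sequence" entry per line.
# Entries are starting points for common library preparations; replace or
# extend them with the exact primer/adaptor sequences of your own assay.
illumina_truseq	AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC
illumina_truseq_r2	AGATCGGAAGAGCGTCGTGTAGGGAAAGAGTGTA
illumina_small_rna	TGGAATTCTCGGGTGCCAAGG
roche454_adaptor_a	CCATCTCATCCCTGCGTGTCTCCGACTCAG
roche454_adaptor_b	CCTATCCCCTGTGTGCCTTGGCAGTCTCAG
roche454_flx_linker	GTTGGAACCGAAAGGGTTTGAATTCAAACCCTTTCGGTTCCAAC
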