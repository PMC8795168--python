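missense_variant	exonic
synonymous_variant	exonic
stop_gained	exonic
stop_lost	exonic
start_lost	exonic
start_retained_variant	exonic
stop_retained_variant	exonic
frameshift_variant	exonic
inframe_insertion	exonic
inframe_deletion	exonic
protein_altering_variant	exonic
coding_sequence_variant	exonic
incomplete_terminal_codon_variant	exonic
splice_donor_variant	splicing
splice_acceptor_variant	splicing
splice_region_variant	splicing
splice_donor_region_variant	splicing
splice_donor_5th_base_variant	splicing
splice_polypyrimidine_tract_variant	splicing
5_prime_UTR_variant	utr5
3_prime_UTR_variant	utr3
non_coding_transcript_exon_variant	ncRNA
non_coding_transcript_variant	ncRNA
mature_miRNA_variant	ncRNA
intron_variant	intronic
upstream_gene_variant	upstream
downstream_gene_variant	downstream
intergenic_variant	intergenic
regulatory_region_variant	intergenic
TF_binding_site_variant	intergenic
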