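key	value
completeness_complete	776
completeness_complete_pseudogene	289
completeness_partial	188
completeness_partial_pseudogene	67
class_CNL	618
class_NL	98
class_CN	3
class_N	1
class_NLR-ID	52
polymorphic_primer_pairs	105
total_primer_pairs	757
contigs_assembled	1509
contigs_nonredundant	1456
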