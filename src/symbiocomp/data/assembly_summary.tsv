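key	value
total_reads	83828866
clean_reads	82818787
mean_read_length_bp	101
n_scaffolds	1324517
n_contigs	34428
n_singletons	38288
n_unitigs	72716
longest_unitig_bp	12135
smallest_unitig_bp	150
mean_unitig_bp	591.9
annotated_unitigs	21129
meam1_mapped	44425
meam1_total	57741
asia_ii3_mapped	37365
asia_ii3_total	45831
med_mapped	21309
med_total	27288
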