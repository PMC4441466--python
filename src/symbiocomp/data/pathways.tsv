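amino_acid	kegg_map	essential	step_index	ecs
glycine	260	no	0	1.4.3.3
glycine	260	no	1	2.6.1.44
glycine	260	no	2	2.1.2.1
glycine	260	no	3	1.4.4.2
glycine	260	no	4	2.1.2.10
serine	260	no	0	1.1.1.29
serine	260	no	1	2.7.1.31
serine	260	no	2	1.1.1.95
serine	260	no	3	2.6.1.52
serine	260	no	4	3.1.3.3
cysteine	270	no	0	4.2.1.22
cysteine	270	no	1	4.4.1.1
aspartate	250	no	0	2.6.1.1
asparagine	250	no	0	6.3.5.4
glutamate	250	no	0	1.4.1.13,1.4.1.14
glutamine	250	no	0	6.3.1.2
alanine	250	no	0	2.6.1.2
proline	330	no	0	2.7.2.11
proline	330	no	1	1.2.1.41
proline	330	no	2	4.3.1.12
tyrosine	400	no	0	1.14.16.1
phenylalanine	400	yes	0	5.4.99.5
phenylalanine	400	yes	1	4.2.1.51
phenylalanine	400	yes	2	2.6.1.1
tryptophan	400	yes	0	4.1.3.27
tryptophan	400	yes	1	2.4.2.18
tryptophan	400	yes	2	4.2.1.20
arginine	330	yes	0	1.2.1.38
arginine	330	yes	1	2.6.1.11
arginine	330	yes	2	2.1.3.3
arginine	330	yes	3	6.3.4.5
arginine	330	yes	4	4.3.2.1
valine_leucine_isoleucine	290	yes	0	2.2.1.6
valine_leucine_isoleucine	290	yes	1	1.1.1.86
valine_leucine_isoleucine	290	yes	2	4.2.1.9
valine_leucine_isoleucine	290	yes	3	2.3.3.13
valine_leucine_isoleucine	290	yes	4	4.2.1.33
valine_leucine_isoleucine	290	yes	5	1.1.1.85
valine_leucine_isoleucine	290	yes	6	2.6.1.42
histidine	340	yes	0	3.5.4.19
histidine	340	yes	1	5.3.1.16
histidine	340	yes	2	4.2.1.19
histidine	340	yes	3	2.6.1.9
methionine	270	yes	0	2.1.1.10,2.1.1.14
methionine	270	yes	1	2.6.1.57
lysine	300	yes	0	1.2.1.11
lysine	300	yes	1	4.3.3.7
lysine	300	yes	2	1.17.1.8
lysine	300	yes	3	2.3.1.117
lysine	300	yes	4	2.6.1.17
lysine	300	yes	5	3.5.1.18
lysine	300	yes	6	5.1.1.7
threonine	260	yes	0	4.3.1.19
threonine	260	yes	1	1.2.1.11
threonine	260	yes	2	1.1.1.3
threonine	260	yes	3	4.2.3.1
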