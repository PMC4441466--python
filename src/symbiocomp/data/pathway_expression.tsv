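essential	amino_acid	kegg_map	enzyme	ec	unitig	symbiont_rpkm	insect_rpkm
no	glycine	260	D-amino-acid oxidase	1.4.3.3	Unitig_2664	-	10.9
no	glycine	260	Glyoxylate aminotransferase	2.6.1.44	Unitig_6058	-	147.4
no	glycine	260	Serine/glycine hydroxylmethyltransferase	2.1.2.1	Unitig_2506	-	62.2
no	glycine	260	Glycine dehydrogenase (decarboxylating)	1.4.4.2	Unitig_61534	-	13.2
no	glycine	260	Aminomethyltransferase	2.1.2.10	Unitig_51378	-	37.7
no	serine	260	Glyoxylate hydroxypyruvate reductase	1.1.1.29	Unitig_35285	-	6.7
no	serine	260	Glycerate kinase	2.7.1.31	Unitig_1084	-	8.3
no	serine	260	Phosphoglycerate dehydrogenase	1.1.1.95	Unitig_69094	-	213.2
no	serine	260	Phosphoserine aminotransferase	2.6.1.52	Unitig_5520	-	161.5
no	serine	260	Phosphoserine phosphatase	3.1.3.3	Unitig_15230	-	6.9
no	cysteine	270	Cysteine synthase	4.2.1.22	Unitig_22283	-	23.3
no	cysteine	270	Cystathionase	4.4.1.1	Unitig_21860	-	99.6
no	aspartate	250	Aspartate aminotransferase	2.6.1.1	Unitig_64	-	35
no	asparagine	250	Asparagine synthetase	6.3.5.4	Unitig_19156	-	34.6
no	glutamate	250	Glutamate synthase	1.4.1.13	Unitig_47533	-	19.6
no	glutamate	250	Glutamate synthase	1.4.1.14	Unitig_17057	-	16.1
no	glutamine	250	Glutamine synthetase	6.3.1.2	Unitig_40789	-	96.9
no	alanine	250	Alanine aminotransferase	2.6.1.2	Unitig_16275	-	18.9
no	proline	330	Glutamyl kinase	2.7.2.11	Unitig_19760	-	30.7
no	proline	330	Glutamylphosphate reductase	1.2.1.41	Unitig_69676	-	94.4
no	proline	330	Ornithine cyclodeaminase	4.3.1.12	Unitig_61585	-	27.2
no	tyrosine	400	Monooxygenase	1.14.16.1	Unitig_52178	-	183.7
yes	phenylalanine	400	hydroxyphenylpyruvate synthase	5.4.99.5	Unitig_56082	12.6	-
yes	phenylalanine	400	prephenate dehydratase	4.2.1.51	Unitig_56082	12.6	-
yes	phenylalanine	400	Aminotransferase	2.6.1.1	Unitig_21129	-	8.3
yes	tryptophan	400	Anthranilate synthase aminase	4.1.3.27	Unitig_42109	14.4	-
yes	tryptophan	400	Anthranilate phosphoribosyltransferase	2.4.2.18	Unitig_54016	23.6	-
yes	tryptophan	400	Tryptophan synthase	4.2.1.20	Unitig_25708	16.4	-
yes	tryptophan	400	Tryptophan synthase	4.2.1.20	Unitig_52877	25.6	-
yes	arginine	330	Glutamate-semialdehyde dehydrogenase	1.2.1.38	Unitig_9438	21.8	-
yes	arginine	330	Acetylornithine succinylornithine aminotransferase	2.6.1.11	Unitig_40277	23.2	-
yes	arginine	330	Ornithine carbamoyltransferase	2.1.3.3	Unitig_23876	14.3	-
yes	arginine	330	Argininosuccinate synthase	6.3.4.5	Unitig_24038	15.4	-
yes	arginine	330	Argininosuccinate lyase	4.3.2.1	Unitig_44282	26.3	-
yes	valine_leucine_isoleucine	290	Acetolactate synthase	2.2.1.6	Unitig_9069	15.1	-
yes	valine_leucine_isoleucine	290	Ketol-acid reductoisomerase	1.1.1.86	Unitig_16373	18.3	-
yes	valine_leucine_isoleucine	290	Dihydroxy-acid dehydratase	4.2.1.9	Unitig_23925	11.6	-
yes	valine_leucine_isoleucine	290	2-isopropylmalate synthase	2.3.3.13	Unitig_6685	29.4	-
yes	valine_leucine_isoleucine	290	3-isopropylmalate dehydratase	4.2.1.33	Unitig_6246	29.1	-
yes	valine_leucine_isoleucine	290	3-isopropylmalate dehydrogenase	1.1.1.85	Unitig_6259	28.4	-
yes	valine_leucine_isoleucine	290	Branched-chain-amino-acid aminotransferase	2.6.1.42	Unitig_62909	-	86.7
yes	histidine	340	Phosphoribosyl-amp cyclohydrolase	3.5.4.19	Unitig_47211	12.3	-
yes	histidine	340	Phosphoribosylformimino-5-aminoimidazole carboxamide ribotide isomerase	5.3.1.16	Unitig_23937	13.9	-
yes	histidine	340	Imidazoleglycerol-phosphate dehydratase	4.2.1.19	Unitig_55053	24.2	-
yes	histidine	340	Histidinol-phosphate aminotransferase	2.6.1.9	Unitig_27079	15.4	-
yes	methionine	270	Homocysteine s-methyltransferase	2.1.1.10	Unitig_15630	-	30.1
yes	methionine	270	Homocysteine s-methyltransferase	2.1.1.14	Unitig_10347	16.2	-
yes	methionine	270	Histidinol-phosphate aminotransferase	2.6.1.57	Unitig_27079	15.4	-
yes	lysine	300	Aspartate-semialdehyde dehydrogenase	1.2.1.11	Unitig_11956	25.2	-
yes	lysine	300	Dihydrodipicolinate synthase	4.3.3.7	Unitig_56490	23.6	-
yes	lysine	300	Dihydrodipicolinate reductase	1.17.1.8	Unitig_23804	24.6	-
yes	lysine	300	Tetrahydrodipicolinate n-succinyltransferase	2.3.1.117	Unitig_11565	18.4	-
yes	lysine	300	Acetylornithine/succinylornithine aminotransferase	2.6.1.17	Unitig_30242	14.4	-
yes	lysine	300	Succinyl-diaminopimelate desuccinylase	3.5.1.18	Unitig_11696	24.6	-
yes	lysine	300	Diaminopimelate epimerase	5.1.1.7	Unitig_39459	18.3	-
yes	threonine	260	Threonine dehydratase deaminase	4.3.1.19	Unitig_20690	-	40.9
yes	threonine	260	Aspartate-semialdehyde dehydrogenase	1.2.1.11	Unitig_11956	25.2	-
yes	threonine	260	Homoserine dehydrogenase	1.1.1.3	Unitig_9316	24.6	-
yes	threonine	260	Threonine synthase	4.2.3.1	Unitig_11908	14.8	-
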