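aphid_transporter	aphid_locus	unitig	rpkm
ACYPI000536	LOC100159138	Unitig_36850	48
ACYPI000550	LOC100159152	Unitig_68785	253
ACYPI000550	LOC100159152	Unitig_21655	57
ACYPI000550	LOC100159152	Unitig_40249	36
ACYPI001018	LOC100159667	Unitig_47082	172
ACYPI001018	LOC100159667	Unitig_49482	126
ACYPI008904	LOC100168178	Unitig_52040	95
ACYPI008904	LOC100168178	Unitig_52329	98
ACYPI008971	LOC100168251	Unitig_36271	78
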