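species	accession	source	phylum_path	n_p25_domains	rossmann_flags	other_domains	is_est	questionable
Drosophila melanogaster	NP_648370	RefSeq	Metazoa;Arthropoda;Hexapoda;Insecta;Endopterygota	1	-	-	0	0
Drosophila sechellia	XP_002029959	RefSeq	Metazoa;Arthropoda;Hexapoda;Insecta;Endopterygota	1	-	-	0	0
Drosophila simulans	XP_002084342	RefSeq	Metazoa;Arthropoda;Hexapoda;Insecta;Endopterygota	1	-	-	0	0
Drosophila erecta	XP_001972246	RefSeq	Metazoa;Arthropoda;Hexapoda;Insecta;Endopterygota	1	-	-	0	0
Drosophila yakuba	XP_002094265	RefSeq	Metazoa;Arthropoda;Hexapoda;Insecta;Endopterygota	1	-	-	0	0
Drosophila ananassae	XP_001957775	RefSeq	Metazoa;Arthropoda;Hexapoda;Insecta;Endopterygota	1	-	-	0	0
Drosophila willistoni	XP_002062203	RefSeq	Metazoa;Arthropoda;Hexapoda;Insecta;Endopterygota	1	-	-	0	0
Drosophila persimilis	XP_002025402	RefSeq	Metazoa;Arthropoda;Hexapoda;Insecta;Endopterygota	1	-	-	0	0
Drosophila pseudoobscura	XP_001353716	RefSeq	Metazoa;Arthropoda;Hexapoda;Insecta;Endopterygota	1	-	-	0	0
Drosophila mojavensis	XP_002007566	RefSeq	Metazoa;Arthropoda;Hexapoda;Insecta;Endopterygota	1	-	-	0	0
Drosophila virilis	XP_002047114	RefSeq	Metazoa;Arthropoda;Hexapoda;Insecta;Endopterygota	1	-	-	0	0
Drosophila grimshawi	XP_001983728	RefSeq	Metazoa;Arthropoda;Hexapoda;Insecta;Endopterygota	1	-	-	0	0
Anopheles gambiae	XP_556944	RefSeq	Metazoa;Arthropoda;Hexapoda;Insecta;Endopterygota	1	-	-	0	0
Culex quinquefasciatus	XP_001862283	RefSeq	Metazoa;Arthropoda;Hexapoda;Insecta;Endopterygota	1	-	-	0	0
Camponotus floridanus	EFN74475	GenBank	Metazoa;Arthropoda;Hexapoda;Insecta;Endopterygota	1	-	-	0	0
Solenopsis invicta	EFZ11240	GenBank	Metazoa;Arthropoda;Hexapoda;Insecta;Endopterygota	1	-	-	0	1
Danaus plexippus	EHJ66593	GenBank	Metazoa;Arthropoda;Hexapoda;Insecta;Endopterygota	1	-	-	0	0
Tribolium castaneum	EFA09619	GenBank	Metazoa;Arthropoda;Hexapoda;Insecta;Endopterygota	1	-	-	0	0
Tribolium castaneum	EEZ98749	GenBank	Metazoa;Arthropoda;Hexapoda;Insecta;Endopterygota	1	-	-	0	0
Ixodes scapularis	XP_002404704	RefSeq	Metazoa;Arthropoda;Chelicerata;Arachnida;Acari	1	-	-	0	0
Metaseiulus occidentalis	XP_003742023	RefSeq	Metazoa;Arthropoda;Chelicerata;Arachnida;Acari	1	-	-	0	0
Clonorchis sinensis	GAA47940	RefSeq	Metazoa;Platyhelminthes;Trematoda	1	-	-	0	1
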