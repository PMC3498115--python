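species	accession	source	phylum_path	n_p25_domains	rossmann_flags	other_domains	is_est	questionable
Monosiga brevicollis	XP_001750206	RefSeq	Choanomonada	1	yes	-	0	0
Salpigoeca rosetta	EGD82798	GenBank	Choanomonada	1	yes	-	0	0
Batrachochytrium dendrobatidis	EGF79566	GenBank	Fungi;Chytridiomycota	2	yes;no	-	0	0
Spizellomyces punctatus	SPPG_08463	Broad	Fungi;Chytridiomycota	2	yes;yes	-	0	0
Hyperamoeba dachnaya	EC854006	GenBank	Mycetozoa	3	yes;yes;yes	-	1	0
Thecamonas trahens	AMSG_02233	Broad	Apusomonadida	4	yes;yes;yes;yes	-	0	0
Chlamydomonas reinhardtii	XP_001690551	RefSeq	Chloroplastida;Chlorophyta	1	yes	-	0	0
Volvox carteri	XP_002946586	RefSeq	Chloroplastida;Chlorophyta	2	yes;yes	-	0	0
Lolium perenne	GR509039	GenBank	Chloroplastida;Charophyta	1	yes	-	1	0
Aureococcus anophagefferens	EGB10333	GenBank	Stramenopiles	1	yes	WD40	0	0
Ectocarpus siliculosus	CBN76131	GenBank	Stramenopiles	1	no	-	0	0
Phytophthora infestans	XP_002907772	RefSeq	Stramenopiles	1	no	-	0	0
Phytophthora ramorum	phyra80518	JGI	Stramenopiles	1	no	-	0	0
Phytophthora sojae	EGZ29591	GenBank	Stramenopiles	1	no	-	0	0
Giardia lamblia	XP_001705540	RefSeq	Fornicata	2	no;yes	-	0	0
Giardia lamblia	GL50581_3979	GiardiaDB	Fornicata	2	no;yes	-	0	0
Jakoba libera	EC691986	GenBank	Jakobida	3	no;no;no	-	1	0
Seculamonas ecuadoriensis	EC817264	GenBank	Jakobida	3	no;no;no	-	1	0
Trimastix pyriformis	EC840067	GenBank	Preaxostyla	3	yes;yes;yes	-	1	0
Naegleria gruberi	D2VER9_NAEGR	UniProt	Heterolobosea	2	no;no	-	0	0
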