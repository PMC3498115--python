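species	accession	source	phylum_path	n_p25_domains	rossmann_flags	other_domains	is_est	questionable
Chlamydomonas reinhardtii	XP_001691800	RefSeq	Chloroplastida;Chlorophyta	2	-	EFh	0	0
Volvox carteri	XP_002948912	RefSeq	Chloroplastida;Chlorophyta	2	-	EFh	0	0
Micromonas pusilla	XP_003058058	RefSeq	Chloroplastida;Chlorophyta	3	-	EFh;COG4942	0	0
Micromonas pusilla	XP_003063447	RefSeq	Chloroplastida;Chlorophyta	1	-	EFh	0	0
Micromonas pusilla	XP_002506378	RefSeq	Chloroplastida;Chlorophyta	2	-	EFh	0	0
Micromonas pusilla	XP_002507907	RefSeq	Chloroplastida;Chlorophyta	2	-	EFh	0	0
Micromonas pusilla	XP_003061031	RefSeq	Chloroplastida;Chlorophyta	2	-	-	0	0
Chlorella variabilis	EFN57882	GenBank	Chloroplastida;Chlorophyta	2	-	-	0	0
Coccomyxa subellipsoidea	EIE25016	GenBank	Chloroplastida;Chlorophyta	2	-	EFh	0	0
Ostreococcus lucimarinus	XP_001421186	RefSeq	Chloroplastida;Chlorophyta	2	-	-	0	0
Albugo laibachii	CCA17632	GenBank	Stramenopiles	1	-	P-loopNTPase;DEXDc;HELICc	0	0
Ectocarpus siliculosus	CBN75312	GenBank	Stramenopiles	1	-	Znf_BBOX;IQ	0	0
Ectocarpus siliculosus	CBJ49059	GenBank	Stramenopiles	1	-	zf-SNAP50_C;Znf_BBOX;IQ;WW	0	0
Phytophthora infestans	XP_002905233	RefSeq	Stramenopiles	1	-	Znf_BBOX;IQ;COG5022	0	0
Phytophthora infestans	XP_002907084	RefSeq	Stramenopiles	1	-	Mcp5_PH	0	0
Phytophthora sojae	EGZ26181	GenBank	Stramenopiles	1	-	Znf_BBOX;IQ;COG5022	0	0
Naegleria gruberi	XP_002683090	RefSeq	Heterolobosea	1	-	Kelch	0	0
Naegleria gruberi	XP_002682916	RefSeq	Heterolobosea	1	-	PLN02919;PTPc	0	0
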