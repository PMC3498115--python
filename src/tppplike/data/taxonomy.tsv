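species	supergroup	megagroup	path
Homo sapiens	Opisthokonta	unikonts	Metazoa;Vertebrata
Tetraodon nigroviridis	Opisthokonta	unikonts	Metazoa;Vertebrata
Caenorhabditis elegans	Opisthokonta	unikonts	Metazoa;Nematoda
Suberites domuncula	Opisthokonta	unikonts	Metazoa;Porifera
Trichoplax adhaerens	Opisthokonta	unikonts	Metazoa;Placozoa
Drosophila melanogaster	Opisthokonta	unikonts	Metazoa;Arthropoda;Hexapoda;Insecta;Endopterygota
Drosophila sechellia	Opisthokonta	unikonts	Metazoa;Arthropoda;Hexapoda;Insecta;Endopterygota
Drosophila simulans	Opisthokonta	unikonts	Metazoa;Arthropoda;Hexapoda;Insecta;Endopterygota
Drosophila erecta	Opisthokonta	unikonts	Metazoa;Arthropoda;Hexapoda;Insecta;Endopterygota
Drosophila yakuba	Opisthokonta	unikonts	Metazoa;Arthropoda;Hexapoda;Insecta;Endopterygota
Drosophila ananassae	Opisthokonta	unikonts	Metazoa;Arthropoda;Hexapoda;Insecta;Endopterygota
Drosophila willistoni	Opisthokonta	unikonts	Metazoa;Arthropoda;Hexapoda;Insecta;Endopterygota
Drosophila persimilis	Opisthokonta	unikonts	Metazoa;Arthropoda;Hexapoda;Insecta;Endopterygota
Drosophila pseudoobscura	Opisthokonta	unikonts	Metazoa;Arthropoda;Hexapoda;Insecta;Endopterygota
Drosophila mojavensis	Opisthokonta	unikonts	Metazoa;Arthropoda;Hexapoda;Insecta;Endopterygota
Drosophila virilis	Opisthokonta	unikonts	Metazoa;Arthropoda;Hexapoda;Insecta;Endopterygota
Drosophila grimshawi	Opisthokonta	unikonts	Metazoa;Arthropoda;Hexapoda;Insecta;Endopterygota
Anopheles gambiae	Opisthokonta	unikonts	Metazoa;Arthropoda;Hexapoda;Insecta;Endopterygota
Culex quinquefasciatus	Opisthokonta	unikonts	Metazoa;Arthropoda;Hexapoda;Insecta;Endopterygota
Camponotus floridanus	Opisthokonta	unikonts	Metazoa;Arthropoda;Hexapoda;Insecta;Endopterygota
Solenopsis invicta	Opisthokonta	unikonts	Metazoa;Arthropoda;Hexapoda;Insecta;Endopterygota
Danaus plexippus	Opisthokonta	unikonts	Metazoa;Arthropoda;Hexapoda;Insecta;Endopterygota
Tribolium castaneum	Opisthokonta	unikonts	Metazoa;Arthropoda;Hexapoda;Insecta;Endopterygota
Ixodes scapularis	Opisthokonta	unikonts	Metazoa;Arthropoda;Chelicerata;Arachnida;Acari
Metaseiulus occidentalis	Opisthokonta	unikonts	Metazoa;Arthropoda;Chelicerata;Arachnida;Acari
Clonorchis sinensis	Opisthokonta	unikonts	Metazoa;Platyhelminthes;Trematoda
Monosiga brevicollis	Opisthokonta	unikonts	Choanomonada
Salpigoeca rosetta	Opisthokonta	unikonts	Choanomonada
Batrachochytrium dendrobatidis	Opisthokonta	unikonts	Fungi;Chytridiomycota
Spizellomyces punctatus	Opisthokonta	unikonts	Fungi;Chytridiomycota
Hyperamoeba dachnaya	Amoebozoa	unikonts	Mycetozoa
Thecamonas trahens	Apusozoa	unikonts	Apusomonadida
Cyanophora paradoxa	Archaeplastida	photosynthetic	Glaucophyta
Chlamydomonas reinhardtii	Archaeplastida	photosynthetic	Chloroplastida;Chlorophyta;Chlorophyceae
Volvox carteri	Archaeplastida	photosynthetic	Chloroplastida;Chlorophyta;Chlorophyceae
Micromonas pusilla	Archaeplastida	photosynthetic	Chloroplastida;Chlorophyta;Prasinophyceae
Ostreococcus lucimarinus	Archaeplastida	photosynthetic	Chloroplastida;Chlorophyta;Prasinophyceae
Ostreococcus tauri	Archaeplastida	photosynthetic	Chloroplastida;Chlorophyta;Prasinophyceae
Chlorella variabilis	Archaeplastida	photosynthetic	Chloroplastida;Chlorophyta;Trebouxiophyceae
Coccomyxa subellipsoidea	Archaeplastida	photosynthetic	Chloroplastida;Chlorophyta;Trebouxiophyceae
Lolium perenne	Archaeplastida	photosynthetic	Chloroplastida;Charophyta
Oryza sativa	Archaeplastida	photosynthetic	Chloroplastida;Charophyta
Triticum aestivum	Archaeplastida	photosynthetic	Chloroplastida;Charophyta
Hordeum vulgare	Archaeplastida	photosynthetic	Chloroplastida;Charophyta
Albugo laibachii	Chromalveolata	photosynthetic	Stramenopiles
Ectocarpus siliculosus	Chromalveolata	photosynthetic	Stramenopiles
Aureococcus anophagefferens	Chromalveolata	photosynthetic	Stramenopiles
Phytophthora infestans	Chromalveolata	photosynthetic	Stramenopiles
Phytophthora ramorum	Chromalveolata	photosynthetic	Stramenopiles
Phytophthora sojae	Chromalveolata	photosynthetic	Stramenopiles
Babesia bovis	Chromalveolata	photosynthetic	Alveolata;Apicomplexa
Toxoplasma gondii	Chromalveolata	photosynthetic	Alveolata;Apicomplexa
Plasmodium falciparum	Chromalveolata	photosynthetic	Alveolata;Apicomplexa
Cryptosporidium muris	Chromalveolata	photosynthetic	Alveolata;Apicomplexa
Tetrahymena thermophila	Chromalveolata	photosynthetic	Alveolata;Ciliophora
Paramecium tetraurelia	Chromalveolata	photosynthetic	Alveolata;Ciliophora
Paracercomonas marina	Rhizaria	photosynthetic	Cercozoa
Giardia lamblia	Excavata	Excavata	Fornicata
Jakoba libera	Excavata	Excavata	Jakobida
Seculamonas ecuadoriensis	Excavata	Excavata	Jakobida
Malawimonas californiana	Excavata	Excavata	Malawimonas
Trimastix pyriformis	Excavata	Excavata	Preaxostyla
Naegleria gruberi	Excavata	Excavata	Heterolobosea
Trypanosoma brucei	Excavata	Excavata	Euglenozoa;Kinetoplastea
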