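higher_taxon	species	copy_number	family_number	pat_family_count	min_family_size	max_family_size
Actinopterygii	Danio rerio	2091	14	0	1	1157
Actinopterygii	Gasterosteus aculeatus	21	4	0	1	12
Actinopterygii	Oryzias latipes	6	1	0		
Actinopterygii	Takifugu rubripes	7	1	0		
Actinopterygii	Tetraodon nigroviridis	8	2	0	1	7
Amoebozoa	Dictyostelium discoideum	16	1	0		
Amoebozoa	Acantheamoeba sp.	1	1	0		
Amphibia	Xenopus tropicalis	692	81	0	1	38
Annelida	Capitella sp. I	5	2	0	1	4
Blastocladiomycota	Allomyces macrogynus	21	6	0	1	10
Cephalochordata	Branchiostoma floridae	15	11	0	1	3
Chlorophyta	Chlamydomonas reinhardtii	11	5	3	1	4
Chlorophyta	Volvox carteri	36	6	4	2	13
Cnidaria	Nematostella vectensis	60	21	1	1	7
Crustacea	Daphnia pulex	100	39	0	1	5
Echinodermata	Strongylocentrotus purpuratus	4	4	0		
Haptophytes	Emiliana huxleyi	1	1	0		
Hemichordata	Saccoglossus kowalevskii	240	8	1	1	175
Heterolobosea	Naegleria gruberi	7	6	0	1	2
Hexapoda	Bombyx mori	6	2	0	3	3
Hexapoda	Nasonia vitripennis	37	18	0	1	4
Hexapoda	Tribolium castaneum	1	1	0		
Mucoromycotina	Mucor circinelloides	3	2	0	1	2
Mucoromycotina	Phycomyces blakesleeanus	28	13	0	1	5
Mucoromycotina	Rhizopus oryzae	24	11	0	1	4
Mollusca	Aplysia californica	39	7	0	2	10
Mollusca	Lottia gigantea	44	22	1	1	5
Nematoda	Caenorhabditis briggsae	1	1	1		
Nematoda	Pristionchus pacificus	4	3	3	1	2
Petromyzontida	Petromyzon marinus	2	2	0		
Sauropsida	Anolis carolinensis	775	42	0	1	319
Urochordata	Oikopleura dioica	4	2	0	1	3
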