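element	host	taxon	size	start	end	circular_junction	long_orf_overlap	lE	divergent_itr	conserved_itr	rE	icr_sizes
AcDIRS1	A. carolinensis	Sauropsida	5938	CTT	CAT	AAG	No	-	26	140	26	40-58
AcDIRS2	A. carolinensis	Sauropsida	5997	TTT	TGT	AAA	Yes	-	26	136	28	39-60
AcaDIRS1	A. californica	Mollusca	5222	ATT	ATT	AAT	No	-	36	32	48	45-88
AcaDIRS2	A. californica	Mollusca	5808	ATT	ATT	AAT	No	-	34	36	48	44-88
AcasDIRS1	A. castellanii	Amoebozoa	3974	GTT	CTT	AAG	No	12	22	84	-	52-36
AmDIRS1	A. macrogynus	Blastocladiomycota	4801	CGG	GCG	CG	Yes	64	33	123	-	110-39
AmDIRS2	A. macrogynus	Blastocladiomycota	5713	ATT	AAT	AAT	Yes	14	9	193	75	24-86
BfDIRS1	B. floridae	Cephalochordata	4949	TTG	TTG	CAA	Yes	-	23	118	45	60-83
BfDIRS2	B. floridae	Cephalochordata	5269	TTA	TTT	AA	Yes	-	19	103	40	33-71
BmDIRS1	B. mori	Hexapoda	4870	ATT	ATA	AAT	Yes	-	16	155	30	40-62
CaspDIRS1	Capitella sp.	Annelida	4994	ATT	ATT	AAT	Yes	nd	nd	nd	nd	nd
DIRS1-2	D. discoideum	Amoebozoa	3793	TTA	TTA	TAA	Yes	-	12	304	24	26-59
DpuDIRS3	D. pulex	Crustacea	5195	ATT	ATT	AAT	No	-	24	170	50	38-89
GaDIRS1	G. aculeatus	Actinopterygii	5322	GTT	GTT	AAC	Yes	-	19	148	27	46-56
GaDIRS2	G. aculeatus	Actinopterygii	5782	GTT	GTT	AAC	Yes	-	21	144	26	38-57
LgDIRS1	L. gigantea	Mollusca	4680	ATT	ATT	AAT	No	-	35	31	48	39-86
LgDIRS2	L. gigantea	Mollusca	5036	AAT	AAT	ATT	No	-	34	141	46	46-67
LgDIRS3	L. gigantea	Mollusca	5133	ATT	ATT	AAT	No	-	30	36	49	42-86
MciDIRS1	M. circinelloides	Mucoromycotina	4402	ATT	ATT	AAT	Yes	38	8	107	11	75-42
NvDIRS2	N. vitripennis	Hexapoda	4849	TAA	TAA	TTA	No	-	25	62	35	41-73
NveDIRS6b	N. vectensis	Cnidaria	4142	ATT	AAT	AAT	No	-	30	118	49	40-82
PblDIRS1	P. blakesleeanus	Mucoromycotina	4315	ATT	ATT	AAT	Yes	28	20	94	9	58-39
RoDIRS1	R. oryzae	Mucoromycotina	4274	ATT	ATT	AAT	Yes	28	14	102	9	59-44
SkoDIRS1	S. kowalevskii	Hemichordata	6052	ATT	ATT	AAT	No	-	16	202	30	67-63
SkoDIRS2	S. kowalevskii	Hemichordata	6283	GTT	GTT	AAC	No	-	15	142	27	63-65
TnDIRS1a	T. nigroviridis	Actinopterygii	5931	GTT	GAT	AAC	Yes	-	21	146	27	36-57
XtDIRS2	X. tropicalis	Amphibia	5571	TTT	TAT	AAA	Yes	-	20	102	30	43-61
XtDIRS3	X. tropicalis	Amphibia	6196	TTT	TTT	AAA	Yes	-	11	123	34	41-65
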