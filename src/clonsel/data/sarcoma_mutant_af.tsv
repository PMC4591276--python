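cell_line	gene	transcript	af_sensitive	af_resistant
IB111	HSPG2	NM_005529:exon42:c.A5239C:p.T1747P	0.03	0.39
IB111	MACF1	NM_012090:exon91:c.A15886C:p.T5296P	0.01	0.23
IB111	P4HTM	NM_177938:exon6:c.C933G:p.S311R	0.09	0.26
IB111	ECT2	NM_001258315:exon4:c.T245C:p.I82T	0.01	0.18
IB111	HLA-A	NM_001242758:exon6:c.A1033T:p.T345S	0.3	0.95
IB111	HLA-C	NM_002117:exon2:c.G97T:p.D33Y	0.21	0.88
IB111	SUPV3L1	NM_003171:exon5:c.G680C:p.G227A	0.29	0.63
IB111	PHLDB1	NM_001144759:exon17:c.C3418T:p.R1140C	0.34	0.66
IB111	ATP5B	NM_001686:exon8:c.A1123G:p.T375A	0.5	0.63
IB111	GPN3	NM_016301:exon5:c.A512C:p.N171T	0.5	0.77
IB111	POLG	NM_001126131:exon14:c.G2323A:p.E775K	0.01	0.24
IB111	PKD1	NM_001009944:exon28:c.T9583C:p.W3195R	0.07	0.19
IB111	ZNF205	NM_001042428:exon7:c.A1204C:p.T402P	0	0.17
IB111	PSMB10	NM_002801:exon3:c.C172G:p.R58G	0.07	0.28
IB111	SF3B3	NM_012426:exon3:c.C382G:p.R128G	0.09	0.31
IB111	SLC38A10	NM_001037984:exon4:c.G349T:p.G117W	0.04	0.19
IB111	NR2F6	NM_005234:exon1:c.A271C:p.T91P	0.13	0.35
IB111	AP1B1	NM_001127:exon5:c.C369G:p.C123W	0.04	0.28
IB115	CKAP2L	NM_152515:exon3:c.C119A:p.S40Y	0	0.32
IB115	PDLIM4	NM_001131027:exon6:c.C674T:p.A225V	0.42	0.53
IB115	FAM45A	NM_207009:exon8:c.G810A:p.M270I	0	0.21
IB115	TP53	NM_001276698:exon4:c.G347C:p.C116S	0	0.35
IB115	EMC10	NM_175063:exon5:c.G529T:p.D177Y	0.02	0.31
IB128	UBE4B	NM_001105562:exon4:c.G367C:p.D123H	0	0.18
IB128	NRAS	NM_002524:exon3:c.A182G:p.Q61R	0	0.15
IB128	ENAH	NM_001008493:exon6:c.C836T:p.S279F	0	0.11
IB128	SYNJ2	NM_003898:exon4:c.A487G:p.N163D	0.11	0.31
IB128	HPD	NM_001171993:exon16:c.G967A:p.G323S	0	0.34
IB128	TP53	NM_001276698:exon3:c.G266C:p.R89P	0	0.21
IB128	TP53	NM_001276698:exon2:c.G119A:p.G40E	0	0.17
IB128	TP53	NM_001126112:exon4:c.C374G:p.T125R	0	0.4
IB128	C17orf89	NM_001086521:exon1:c.C68G:p.A23G	0.02	0.34
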