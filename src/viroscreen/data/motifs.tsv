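name	pattern	consensus	note
WALKER_A	G....GK[ST]	GPPGSGKS	P-loop NTPase Walker A (GxxxxGKS/T)
WALKER_B	[ILMFV][ILMFV][ILMFV][ILMFV]DE	ILVFDE	Walker B hydrophobic strand + DE
INTEGRASE_DDE	D..[GA]D.{30,40}[ST]E	DGAGDQNAQNAQNAQNAQNAQNAQNAQNAQNAQNAQNSE	retroviral-type integrase DDE triad spacing
ADENAIN_TRIAD	H[GSA].{15,35}E[GSA].{20,45}[GQ]C[LIVMF]	HGQNAQNAQNAQNAQNAQNAQNEGQNAQNAQNAQNAQNAQNAQNAQNAQNAQNGCL	adenoviral cysteine endoprotease His-Glu-Cys triad
PLA2_CATALYTIC	Y.G.G.{10,30}HD.{2}Y	YLGKGQNAQNAQNAQNAQNAQNHDLNY	phospholipase A2 Ca-loop + HD catalytic dyad
POLB_CORE	YGDTDS	YGDTDS	family-B DNA polymerase motif C (YGDTDS)
RT_CORE	LPQG.{15,40}[FY].DD	LPQGQNAQNAQNAQNAQNAQNAQNAQNAYVDD	reverse transcriptase LPQG + YxDD
SF1_HELICASE	G.{3}GK[ST].{20,80}[DE]E..Q.{30,150}GR[LIVMA]GR	GSGSGKTQNAQNAQNAQNAQNAQNAQNAQNAQNAQNAQNAQNAQNADEAHQQNAQNAQNAQNAQNAQNAQNAQNAQNAQNAQNAQNAQNAQNAQNAQNAQNAQNAQNAGRAGR	superfamily-1 helicase motifs I / II / VI
CHROMO	[EQ]Y[LIVM][LIVM]KW.{10,30}[WF]	EYLLKWQNAQNAQNAQNAQNAW	chromo domain aromatic cage surrogate
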