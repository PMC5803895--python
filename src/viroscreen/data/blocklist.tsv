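name	pattern	consensus	note
POLYMERASE	NADFDGD	NADFDGD	multisubunit RNA polymerase catalytic loop
KINASE	HRD[LIVMF]K..N	HRDLKPEN	protein kinase catalytic loop (HRDxKxxN)
PHOSPHATASE	HC[SA]AG.GR	HCSAGIGR	protein tyrosine phosphatase CX5R active site
APOPTOSIS_INHIBITOR	C..C.{14,20}H.{6,10}C	CGGCQNAQNAQNAQNAQNHQNAQNAQC	BIR-domain zinc coordination spacing
SUPEROXIDE_DISMUTASE	[GA][FILM]H[FILV]H..[GP][SD]	GFHVHEFGD	Cu/Zn superoxide dismutase signature
PROTEASE	GDSGG	GDSGG	trypsin-family serine protease active site
NUCLEASE	[LIVM]PD.{8,20}[DE][LIVM]K	LPDQNAQNAQNADLK	PD-(D/E)xK restriction-like nuclease core
UBIQUITIN_LIGASE	C..C.{9,20}C.H..C..C	CGGCQNAQNAQNACAHGGCGGC	RING-type E3 ligase cross-brace
ZINC_FINGER	C..C.{10,14}H...H	CKACGGSGSGSGSGHQRTH	C2H2 zinc finger
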