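trait	gene	Ds	Dn	Ps	Pn	ni_printed	p_printed
Bill size	ALX1	4	0	1	0	Undefined	1
Bill size	CCDC149	9/2	7/2	1	4	5.143	0.565
Bill size	DLK1	3	1	9	2	0.667	1
Bill size	HMGA2	NA	NA	NA	NA	NA	NA
Bill size	LGI2	NA	NA	NA	NA	NA	NA
Body size	AFAP1	5	2	5	3	1.5	1
Body size	LAP3	8	0	4	5	Undefined	0.029
Body size	LCORL	NA	NA	NA	NA	NA	NA
Body size	QDPR	7/3	17/3	2	8	1.647	1
Body size	SLIT2	10	1	12	2	1.667	1
Body size	WAPL	23/3	1/3	18	11	14.056	0.076
Dispersal	KCTD21	NA	NA	NA	NA	NA	NA
Dispersal	SLC2A1	4	0	10	0	Undefined	1
Dispersal	TGFB2	2	0	3	1	Undefined	1
Migration	CLOCK	2	3	3	1	0.222	0.524
Migration	CREB1	NA	NA	NA	NA	NA	NA
Migration	CRY1	4	0	3	0	Undefined	1
Migration	CRY2	1	0	3	1	Undefined	1
Migration	NPAS3	1	0	3	0	Undefined	1
Migration	PER2	15	4	9	0	0	0.273
Migration	PER3	7	2	15	4	0.933	1
Migration	YPEL1	1	0	1	0	Undefined	1
Plumage color - carotenoid	APOD1	2	0	5	0	Undefined	1
Plumage color - carotenoid	BCO1	5	3	2	0	0	1
Plumage color - carotenoid	BCO2	2	3	14	10	0.476	0.632
Plumage color - carotenoid	CD36	3	0	7/2	29/2	Undefined	0.026
Plumage color - carotenoid	HPS5	7	1	39/2	29/2	5.205	0.222
Plumage color - carotenoid	STARD3	4	1	4	0	0	1
Plumage color - melanin	AGRP	0	3	2	0	0	0.1
Plumage color - melanin	ASIP	NA	NA	NA	NA	NA	NA
Plumage color - melanin	MC1R	3	1	2	2	3	1
Plumage color - melanin	MITF	1	0	10	1	Undefined	1
Plumage color - melanin	PCSK2	2	0	3	0	Undefined	1
Plumage color - melanin	TYR	3	2	6	3	0.750	1
Salt tolerance	MMP17	1	1	9	2	0.222	0.423
Salt tolerance	MYOF	13	2	12	4	2.167	0.654
Salt tolerance	WNK2	41/2	27/2	23	11	0.726	0.615
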