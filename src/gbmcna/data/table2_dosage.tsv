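# The 46 genes whose mRNA expression tracked DNA copy number across 23 paired
# tumor samples (Pearson R^2 > 0.70, two-sided p < 5e-7). IMMP1L (11p13) and
# XIST (Xq13.2) were neither amplified nor deleted in the cohort.
gene_name	symbol	cytoband	r_squared
Cold shock domain containing E1, RNA-binding	CSDE1	1p22	0.93
Transcription termination factor, RNA polymerase II	TTF2	1p22	0.75
Breast carcinoma amplified sequence 2	BCAS2	1p21-p13.3	0.90
Amylase, alpha 2B (pancreatic)	AMY2B	1p21	0.71
Tryptophanyl tRNA synthetase 2, mitochondrial	WARS2	1p13.3-p13.1	0.85
Synaptotagmin VI	SYT6	1p13.2	0.78
Mannosidase, alpha, class 1A, member 2	MAN1A2	1p13	0.89
Adenosine monophosphate deaminase 1 (isoform M)	AMPD1	1p13	0.83
Immunoglobulin superfamily, member 3	IGSF3	1p13	0.76
Zinc finger protein 697	ZNF697	1p12	0.82
Signal recognition particle 72kDa	SRP72	4q11	0.77
Transmembrane protein 165	TMEM165	4q12	0.92
FIP1 like 1 (S. cerevisiae)	FIP1L1	4q12	0.92
Exocyst complex component 1	EXOC1	4q12	0.90
Clock homolog (mouse)	CLOCK	4q12	0.88
Polymerase (RNA) II (DNA directed) polypeptide B	POLR2B	4q12	0.87
Steroid 5 alpha-reductase 3	SRD5A3	4q12	0.77
DCN1, defective in cullin neddylation 1, domain containing 4	DCUN1D4	4q12	0.75
Chromosome 4 open reading frame 14	C4orf14	4q12	0.74
Sec1 family domain containing 2	SCFD2	4q12	0.71
Transmembrane protein 106B	TMEM106B	7p21.3	0.84
Epidermal growth factor receptor	EGFR	7p12	0.85
Peroxisome biogenesis factor 1	PEX1	7q21.2	0.79
GATA zinc finger domain containing 1	GATAD1	7q21-q22	0.78
Methylthioadenosine phosphorylase	MTAP	9p21	0.73
Eukaryotic translation initiation factor 3, subunit M	EIF3M	11p13	0.78
IMP1 inner mitochondrial membrane peptidase-like	IMMP1L	11p13	0.75
Amplified in osteosarcoma	OS9	12q13	0.86
Methyltransferase like 1	METTL1	12q13	0.82
Solute carrier family 16, member 7	SLC16A7	12q13	0.78
Cytochrome P450, family 27, subfamily B, polypeptide 1	CYP27B1	12q13.1-q13.3	0.87
Phosphatidylinositol-5-phosphate 4-kinase, type II, gamma	PIP4K2C	12q13.3	0.90
Deltex 3 homolog (Drosophila)	DTX3	12q13.3	0.75
Beta-1,4-N-acetyl-galactosaminyl transferase 1	B4GALNT1	12q13.3	0.72
Methyl-CpG binding domain protein 6	MBD6	12q13.3	0.75
Ts translation elongation factor, mitochondrial	TSFM	12q13-q14	0.87
Carboxy-terminal domain small phosphatase 2	CTDSP2	12q13-q15	0.91
RAP1B, member of RAS oncogene family	RAP1B	12q14	0.97
Cyclin-dependent kinase 4	CDK4	12q14	0.81
Family with sequence similarity 119, member B	FAM119B	12q14.1	0.80
Advillin	AVIL	12q14.1	0.78
Glutamate receptor interacting protein 1	GRIP1	12q14.3	0.95
Mdm2, transformed 3T3 cell double minute 2	MDM2	12q14.3-q15	0.96
Nucleoporin 107kDa	NUP107	12q15	0.85
Solute carrier family 35, member E3	SLC35E3	12q15	0.79
X (inactive)-specific transcript	XIST	Xq13.2	0.96
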