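entrez_id	symbol	name
8811	GALR2	Galanin receptor 2
10653	SPINT2	Serine peptidase inhibitor, Kunitz type 2
29097	CNIH4	Cornichon family AMPA receptor auxiliary protein 4
8332	HIST1H2AL	Histone cluster 1 H2A family member l
3131	HLF	HLF, PAR bZIP transcription factor
2898	GRIK2	Glutamate ionotropic receptor kainate type subunit 2
79586	CHPF	Chondroitin polymerizing factor
51738	GHRL	Ghrelin and obestatin prepropeptide
6857	SYT1	Synaptotagmin 1
2776	GNAQ	G protein subunit alpha q
6804	STX1A	Syntaxin 1A
84988	PPP1R16A	Protein phosphatase 1 regulatory subunit 16A
8115	TCL1A	T‐cell leukemia
79849	PDZD3	PDZ domain containing 3
57698	SHTN1	Shootin 1
1742	DLG4	Disks large MAGUK scaffold protein 4
5520	PPP2R2A	Protein phosphatase 2 regulatory subunit Balpha
4208	MEF2C	Myocyte enhancer factor 2C
5578	PRKCA	Protein kinase C alpha
8764	TNFRSF14	TNF receptor superfamily member 14
9737	GPRASP1	G protein‐coupled receptor‐associated sorting protein 1
5781	PTPN11	Protein tyrosine phosphatase, nonreceptor type 11
5566	PRKACA	Protein kinase cAMP‐activated catalytic subunit alpha
5621	PRNP	Prion protein
213	ALB	Albumin
6667	SP1	Sp1 transcription factor
5499	PPP1CA	Protein phosphatase 1 catalytic subunit alpha
4093	SMAD9	SMAD family member 9
3326	HSP90AB1	Heat‐shock protein 90 alpha family class B member 1
6925	TCF4	Transcription factor 4
4149	MAX	MYC‐associated factor X
7046	TGFBR1	Transforming growth factor beta receptor 1
2885	GRB2	Growth factor receptor‐bound protein 2
6696	SPP1	Secreted phosphoprotein 1
351	APP	Amyloid beta precursor protein
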