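gene	refseq	fold_change	fdr	stat3_prior	stat1_prior
SPOCK3	NM_001251967.1	-5.1	0.0	Pos	None
SFRP1	NM_003012.4	-2.6	0.0	Pos	None
UPK1B	NM_006952	-1.9	0.0	Pos	None
SCARA3	NM_182826.1	-1.8	0.0	Pos	None
CALML3	NM_005185.2	-1.7	0.0	Pos	None
MMP10	NM_002425	-1.7	0.0	Pos	None
SLPI	NM_003064	-1.6	0.0	Pos	None
CCND3	NM_001081636	-1.6	0.0	Pos	None
IFIT1	NM_001548	-2.5	0.0	Pos	Pos
ISG15	NM_005101	-2.3	0.0	Pos	Pos
NNMT	NM_006169	-2.3	0.0	Pos	Pos
OAS1	NM_002534	-2.1	0.0	Pos	Pos
IFI6	NM_022873	-2.1	0.0	Pos	Pos
USP18	NM_017414	-1.9	0.0	Pos	Pos
MX1	NM_002462	-1.9	0.0	Pos	Pos
OAS2	NM_016817	-1.8	0.0	Pos	Pos
IFI27	NM_005532	-1.7	0.0	Pos	Pos
DDX58	NM_014314	-1.7	0.0	Pos	Pos
CLU	NM_001171138	-1.7	0.0	Pos	Pos
SERPINB3	NM_006919	-1.6	0.0	Pos	Pos
IFITM1	NM_003641	-1.5	0.0	Pos	Pos
IFI35	NM_005533	-1.9	0.0	Pos	Pos
PSMB9	NM_002800	-1.6	0.0	Pos	Pos
IFITM3	NM_021034	-1.5	0.0	Pos	Pos
OASL	NM_003733	-2.6	0.0	Neg	Pos
IFIT3	NM_001549	-2.5	0.0	Neg	Pos
IFI44L	NM_006820	-2.3	0.0	Neg	Pos
PLSCR1	NM_021105	-1.8	0.0	Neg	Pos
MX2	NM_002463	-1.8	0.0	Neg	Pos
HERC5	NM_016323	-1.7	0.0	Neg	Pos
IRF7	NM_004029	-1.7	0.0	Neg	Pos
IFI44	NM_006417	-1.7	0.0	Neg	Pos
TRIM22	NM_006074	-1.7	0.0	Neg	Pos
SAMD9	NM_017654	-1.7	0.0	Neg	Pos
SP110	NM_004509	-1.6	0.0	Neg	Pos
HERC6	NM_017912	-1.6	0.0	Neg	Pos
IFIT5	NM_012420	-1.6	0.0	Neg	Pos
UBE2L6	NM_004223	-1.5	0.0	Neg	Pos
PCDH17	NM_001040429	-3.7	0.0	None	Pos
CCNA1	NM_001111046	-2.3	0.0	None	Pos
IFIT2	NM_001547	-2.2	0.0	None	Pos
EPSTI1	NM_033255	-2.2	0.0	None	Pos
BATF2	NM_138456	-2.1	0.0	None	Pos
CMPK2	NM_207315	-2.1	0.0	None	Pos
GBP1	NM_002053	-1.7	0.0	None	Pos
TYMP	NM_001953	-1.7	0.0	None	Pos
LY6E	NM_002346	-1.5	0.0	None	Pos
KRT15	NM_002275	-2.1	0.0	None	Pos
NPTX2	NM_002523	6.5	0.0	Neg	None
SLC2A3	NM_006931	5.9	0.0	Neg	None
CCL2	NM_002982	5.1	0.0	Neg	None
PTGS2	NM_000963	4.4	0.0	Neg	None
ANPEP	NM_001150	3.7	0.0	Neg	None
IGFBP3	NM_000598	3.3	0.0	Neg	None
CXCL3	NM_002090	2.6	0.0	Neg	None
TNC	NM_011607	2.9	0.0	Neg	None
AKAP12	NM_005100	2.9	0.0	Neg	None
CXCL2	NM_009140	2.9	0.0	Neg	None
SMAD9	NM_019483	2.7	0.0	Neg	None
THBS1	NM_003246	2.2	0.0	Neg	None
CCL20	NM_004591.2	2.1	0.0	Neg	None
IER3	NM_003897	2.0	0.0	Neg	None
FOS	NM_005252	2.0	0.0	Neg	None
VEGFA	NM_001171623	2.0	0.0	Neg	None
EGR1	NM_001964	2.0	0.0	Neg	None
NEDD9	NM_001142393	1.9	0.0	Neg	None
ATF3	NM_001674	1.9	0.0	Neg	None
FOSB	NM_006732	1.9	0.0	Neg	None
PHLDA1	NM_007350	1.8	0.0	Neg	None
EREG	NM_001432	1.8	0.0	Neg	None
NOTCH4	NM_010929	1.8	0.0	Neg	None
NR4A2	NM_006186	1.8	0.0	Neg	None
STC1	NM_003155	1.8	0.0	Neg	None
SLC4A7	NM_001258379	1.8	0.0	Neg	None
ADM	NM_001124	1.8	0.0	Neg	None
COL5A1	NM_000093	1.7	0.0	Neg	None
SLC2A1	NM_006516	1.7	0.0	Neg	None
VLDLR	NM_003383	1.7	0.0	Neg	None
PDK1	NM_002610	1.7	0.0	Neg	None
SERTAD2	NM_014755	1.6	0.0	Neg	None
HK2	NM_000189	1.6	0.0	Neg	None
NAV1	NM_173437	1.6	0.0	Neg	None
SLC7A11	NM_014331	1.6	0.0	Neg	None
HSPG2	NM_005529.5	1.5	0.0	Neg	None
TGFBR3	NM_011578	1.5	0.0	Neg	Neg
ALDH3A1	NM_000691	2.6	0.0	Pos	None
NRP2	NM_201266	1.9	0.0	None	Pos
COL16A1	NM_001856	1.8	0.0	None	Pos
CYP1B1	NM_000104	2.0	0.0	None	Pos
DYNC1H1	NM_001376	1.5	0.0	None	Pos
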