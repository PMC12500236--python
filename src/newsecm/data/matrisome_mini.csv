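# Miniature matrisome annotation for tests and examples: ~60 well-known human
# ECM accessions mapped to matrisome division and category.
accession,division,category
COL1A1_HUMAN,core matrisome,collagens
COL1A2_HUMAN,core matrisome,collagens
COL2A1_HUMAN,core matrisome,collagens
COL3A1_HUMAN,core matrisome,collagens
COL4A1_HUMAN,core matrisome,collagens
COL4A2_HUMAN,core matrisome,collagens
COL5A1_HUMAN,core matrisome,collagens
COL6A1_HUMAN,core matrisome,collagens
COL6A2_HUMAN,core matrisome,collagens
COL7A1_HUMAN,core matrisome,collagens
COL11A1_HUMAN,core matrisome,collagens
COL17A1_HUMAN,core matrisome,collagens
COL18A1_HUMAN,core matrisome,collagens
FINC_HUMAN,core matrisome,ecm_glycoproteins
LAMA1_HUMAN,core matrisome,ecm_glycoproteins
LAMA3_HUMAN,core matrisome,ecm_glycoproteins
LAMB1_HUMAN,core matrisome,ecm_glycoproteins
LAMB3_HUMAN,core matrisome,ecm_glycoproteins
LAMC1_HUMAN,core matrisome,ecm_glycoproteins
LAMC2_HUMAN,core matrisome,ecm_glycoproteins
TENA_HUMAN,core matrisome,ecm_glycoproteins
FBN1_HUMAN,core matrisome,ecm_glycoproteins
FBLN1_HUMAN,core matrisome,ecm_glycoproteins
FBLN2_HUMAN,core matrisome,ecm_glycoproteins
NID1_HUMAN,core matrisome,ecm_glycoproteins
NID2_HUMAN,core matrisome,ecm_glycoproteins
EMIL1_HUMAN,core matrisome,ecm_glycoproteins
TSP1_HUMAN,core matrisome,ecm_glycoproteins
SPRC_HUMAN,core matrisome,ecm_glycoproteins
VTNC_HUMAN,core matrisome,ecm_glycoproteins
PGBM_HUMAN,core matrisome,proteoglycans
PGS1_HUMAN,core matrisome,proteoglycans
PGS2_HUMAN,core matrisome,proteoglycans
LUM_HUMAN,core matrisome,proteoglycans
VCAN_HUMAN,core matrisome,proteoglycans
AGRIN_HUMAN,core matrisome,proteoglycans
MMP2_HUMAN,matrisome-associated,ecm_regulators
MMP9_HUMAN,matrisome-associated,ecm_regulators
MMP14_HUMAN,matrisome-associated,ecm_regulators
TIMP1_HUMAN,matrisome-associated,ecm_regulators
TIMP2_HUMAN,matrisome-associated,ecm_regulators
PCOC2_HUMAN,matrisome-associated,ecm_regulators
LOXL2_HUMAN,matrisome-associated,ecm_regulators
TGM2_HUMAN,matrisome-associated,ecm_regulators
PLOD1_HUMAN,matrisome-associated,ecm_regulators
SERPH_HUMAN,matrisome-associated,ecm_regulators
ANXA1_HUMAN,matrisome-associated,ecm_affiliated
ANXA2_HUMAN,matrisome-associated,ecm_affiliated
ANXA5_HUMAN,matrisome-associated,ecm_affiliated
LEG1_HUMAN,matrisome-associated,ecm_affiliated
LEG3_HUMAN,matrisome-associated,ecm_affiliated
PLOD2_HUMAN,matrisome-associated,ecm_regulators
SEM3C_HUMAN,matrisome-associated,ecm_affiliated
GPC1_HUMAN,matrisome-associated,ecm_affiliated
TGFB1_HUMAN,matrisome-associated,secreted_factors
TGFB2_HUMAN,matrisome-associated,secreted_factors
VEGFA_HUMAN,matrisome-associated,secreted_factors
CTGF_HUMAN,matrisome-associated,secreted_factors
S10A4_HUMAN,matrisome-associated,secreted_factors
IBP3_HUMAN,matrisome-associated,secreted_factors
IBP5_HUMAN,matrisome-associated,secreted_factors
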