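# Static hotspot-style variant templates used to style synthetic truth sets.
# Columns: label, vtype, ref, alt, classification
label	vtype	ref	alt	classification
HS_KRAS_G12D	SNV	G	A	pathogenic
HS_KRAS_G12V	SNV	G	T	pathogenic
HS_BRAF_V600E	SNV	T	A	pathogenic
HS_EGFR_L858R	SNV	T	G	pathogenic
HS_PIK3CA_H1047R	SNV	A	G	pathogenic
HS_PIK3CA_E545K	SNV	G	A	pathogenic
HS_TP53_R175H	SNV	G	A	pathogenic
HS_TP53_R273C	SNV	C	T	pathogenic
HS_TP53_G112D	SNV	G	A	benign
HS_IDH1_R132H	SNV	G	A	pathogenic
HS_NRAS_Q61K	SNV	C	A	pathogenic
HS_KIT_D816V	SNV	A	T	pathogenic
HS_AKT1_E17K	SNV	G	A	pathogenic
HS_ERBB2_V842I	SNV	G	A	pathogenic
HS_CTNNB1_S45F	SNV	C	T	pathogenic
HS_FBXW7_R465C	SNV	C	T	pathogenic
HS_SMAD4_R361H	SNV	G	A	pathogenic
HS_PTEN_R130Q	SNV	G	A	pathogenic
HS_APC_R1450X	SNV	C	T	pathogenic
HS_VHL_S65L	SNV	C	T	VUS
HS_EGFR_E746del	DEL	-	-	pathogenic
HS_ERBB2_A775ins	INS	-	-	pathogenic
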