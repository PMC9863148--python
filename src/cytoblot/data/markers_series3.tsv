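cytokine	CKD_mean_M_F_ExpSeries3	CKD_M_ExpSeries3	CKD_F_ExpSeries3
APOA1	up	up	up
ANG		up
ANGPT1		up
ANGPT2	up	up	up
C5	up	up	up
CD3	down		down
CHI3L1	up		up
CFD	up	up	up
CRP	down		down
FLT3LG	down	down	down
CSF2	down		down
GH1	up	up	up
ICAM1	up	up	up
IFNG	up		up
IGFBP2	up	up	up
IL3		up
IL8	up	up	up
IL22		up
KLK4	up	up	up
CCL2		down
CSF1	down	down	down
MMP9	up	up	up
MPO	up		up
SPP1	up	up	up
PDGFA	down	down	down
PTX3	up		up
RETN	down	down	down
SERPINE1	up		up
VEGFA	down	down	down
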