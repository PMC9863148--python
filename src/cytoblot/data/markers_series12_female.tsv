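cytokine	CKD_F_ExpSeries1	CKD_F_ExpSeries2
ADIPOQ		down
AG		up
AGER	down	down
AHSG		up
ANPEP	up	down
ANXA5	up	down
B2M	up
CCL2	up	down
CCN1	up	down
CLU	up	up
CST3	up
CXCL16	up
DPP4	up
EGF	up
EGFR	down	down
FABP1	down
IL1RN		up
IL6	up	down
IL10	up
HAVCR1	up
KLK3	up
LCN2	up
MME		up
MMP9	up	down
PLAU	up	down
RETN	up	up
SERPINA3	up
SKP1	up
TNFA	up
TNFSF12		up
TNFRSF1A	up
TTF3	up
VCAM1		up
VEGF	down	down
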