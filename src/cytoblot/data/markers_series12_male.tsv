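cytokine	CKD_M_ExpSeries1	CKD_M_ExpSeries2
ADIPOQ		up
AG		up
AGER		down
AHSG		down
ANPEP		down
ANXA5		up
CCN1		up
CLU	up	down
CXCL1	up
CXCL16		down
DPP4	down
EGFR	down
FABP1		up
IL1RN	up
IL10	up	up
LCN2		up
MME	down	down
MMP9	down	up
RBP4	up	down
RETN		up
SERPINA3		up
SKP1	up
TNFA		up
TNFSF12		up
VEGF	down	up
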