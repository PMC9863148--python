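block_row	block_col	row	col	analyte	role
0	0	0	0	REF	reference
0	0	0	1		empty
0	0	0	2	A01	analyte
0	0	0	3	A01	analyte
0	0	0	4	A05	analyte
0	0	0	5	A05	analyte
0	0	0	6	A09	analyte
0	0	0	7	A09	analyte
0	0	0	8	A13	analyte
0	0	0	9	A13	analyte
0	0	1	0	A17	analyte
0	0	1	1	A17	analyte
0	0	1	2	A21	analyte
0	0	1	3	A21	analyte
0	0	1	4	A25	analyte
0	0	1	5	A25	analyte
0	0	1	6	A29	analyte
0	0	1	7	A29	analyte
0	0	1	8	A33	analyte
0	0	1	9	A33	analyte
0	0	2	0	A37	analyte
0	0	2	1	A37	analyte
0	0	2	2	A41	analyte
0	0	2	3	A41	analyte
0	0	2	4	A45	analyte
0	0	2	5	A45	analyte
0	0	2	6	A49	analyte
0	0	2	7	A49	analyte
0	0	2	8	NEG	negative
0	0	2	9	NEG	negative
0	0	3	0	NEG	negative
0	0	3	1	NEG	negative
0	0	3	2		empty
0	0	3	3		empty
0	0	3	4		empty
0	0	3	5		empty
0	0	3	6		empty
0	0	3	7		empty
0	0	3	8		empty
0	0	3	9		empty
0	0	4	0		empty
0	0	4	1		empty
0	0	4	2		empty
0	0	4	3		empty
0	0	4	4		empty
0	0	4	5		empty
0	0	4	6		empty
0	0	4	7		empty
0	0	4	8		empty
0	0	4	9		empty
0	0	5	0		empty
0	0	5	1		empty
0	0	5	2		empty
0	0	5	3		empty
0	0	5	4		empty
0	0	5	5		empty
0	0	5	6		empty
0	0	5	7		empty
0	0	5	8		empty
0	0	5	9		empty
0	0	6	0		empty
0	0	6	1		empty
0	0	6	2		empty
0	0	6	3		empty
0	0	6	4		empty
0	0	6	5		empty
0	0	6	6		empty
0	0	6	7		empty
0	0	6	8		empty
0	0	6	9		empty
0	0	7	0		empty
0	0	7	1		empty
0	0	7	2		empty
0	0	7	3		empty
0	0	7	4		empty
0	0	7	5		empty
0	0	7	6		empty
0	0	7	7		empty
0	0	7	8		empty
0	0	7	9		empty
0	0	8	0		empty
0	0	8	1		empty
0	0	8	2		empty
0	0	8	3		empty
0	0	8	4		empty
0	0	8	5		empty
0	0	8	6		empty
0	0	8	7		empty
0	0	8	8		empty
0	0	8	9		empty
0	0	9	0		empty
0	0	9	1		empty
0	0	9	2		empty
0	0	9	3		empty
0	0	9	4		empty
0	0	9	5		empty
0	0	9	6		empty
0	0	9	7		empty
0	0	9	8		empty
0	0	9	9		empty
0	1	0	0	A02	analyte
0	1	0	1	A02	analyte
0	1	0	2	A06	analyte
0	1	0	3	A06	analyte
0	1	0	4	A10	analyte
0	1	0	5	A10	analyte
0	1	0	6	A14	analyte
0	1	0	7	A14	analyte
0	1	0	8		empty
0	1	0	9	REF	reference
0	1	1	0	A18	analyte
0	1	1	1	A18	analyte
0	1	1	2	A22	analyte
0	1	1	3	A22	analyte
0	1	1	4	A26	analyte
0	1	1	5	A26	analyte
0	1	1	6	A30	analyte
0	1	1	7	A30	analyte
0	1	1	8	A34	analyte
0	1	1	9	A34	analyte
0	1	2	0	A38	analyte
0	1	2	1	A38	analyte
0	1	2	2	A42	analyte
0	1	2	3	A42	analyte
0	1	2	4	A46	analyte
0	1	2	5	A46	analyte
0	1	2	6	A50	analyte
0	1	2	7	A50	analyte
0	1	2	8	NEG	negative
0	1	2	9	NEG	negative
0	1	3	0	NEG	negative
0	1	3	1	NEG	negative
0	1	3	2		empty
0	1	3	3		empty
0	1	3	4		empty
0	1	3	5		empty
0	1	3	6		empty
0	1	3	7		empty
0	1	3	8		empty
0	1	3	9		empty
0	1	4	0		empty
0	1	4	1		empty
0	1	4	2		empty
0	1	4	3		empty
0	1	4	4		empty
0	1	4	5		empty
0	1	4	6		empty
0	1	4	7		empty
0	1	4	8		empty
0	1	4	9		empty
0	1	5	0		empty
0	1	5	1		empty
0	1	5	2		empty
0	1	5	3		empty
0	1	5	4		empty
0	1	5	5		empty
0	1	5	6		empty
0	1	5	7		empty
0	1	5	8		empty
0	1	5	9		empty
0	1	6	0		empty
0	1	6	1		empty
0	1	6	2		empty
0	1	6	3		empty
0	1	6	4		empty
0	1	6	5		empty
0	1	6	6		empty
0	1	6	7		empty
0	1	6	8		empty
0	1	6	9		empty
0	1	7	0		empty
0	1	7	1		empty
0	1	7	2		empty
0	1	7	3		empty
0	1	7	4		empty
0	1	7	5		empty
0	1	7	6		empty
0	1	7	7		empty
0	1	7	8		empty
0	1	7	9		empty
0	1	8	0		empty
0	1	8	1		empty
0	1	8	2		empty
0	1	8	3		empty
0	1	8	4		empty
0	1	8	5		empty
0	1	8	6		empty
0	1	8	7		empty
0	1	8	8		empty
0	1	8	9		empty
0	1	9	0		empty
0	1	9	1		empty
0	1	9	2		empty
0	1	9	3		empty
0	1	9	4		empty
0	1	9	5		empty
0	1	9	6		empty
0	1	9	7		empty
0	1	9	8		empty
0	1	9	9		empty
1	0	0	0	A03	analyte
1	0	0	1	A03	analyte
1	0	0	2	A07	analyte
1	0	0	3	A07	analyte
1	0	0	4	A11	analyte
1	0	0	5	A11	analyte
1	0	0	6	A15	analyte
1	0	0	7	A15	analyte
1	0	0	8	A19	analyte
1	0	0	9	A19	analyte
1	0	1	0	A23	analyte
1	0	1	1	A23	analyte
1	0	1	2	A27	analyte
1	0	1	3	A27	analyte
1	0	1	4	A31	analyte
1	0	1	5	A31	analyte
1	0	1	6	A35	analyte
1	0	1	7	A35	analyte
1	0	1	8	A39	analyte
1	0	1	9	A39	analyte
1	0	2	0	A43	analyte
1	0	2	1	A43	analyte
1	0	2	2	A47	analyte
1	0	2	3	A47	analyte
1	0	2	4	NEG	negative
1	0	2	5	NEG	negative
1	0	2	6	NEG	negative
1	0	2	7	NEG	negative
1	0	2	8		empty
1	0	2	9		empty
1	0	3	0		empty
1	0	3	1		empty
1	0	3	2		empty
1	0	3	3		empty
1	0	3	4		empty
1	0	3	5		empty
1	0	3	6		empty
1	0	3	7		empty
1	0	3	8		empty
1	0	3	9		empty
1	0	4	0		empty
1	0	4	1		empty
1	0	4	2		empty
1	0	4	3		empty
1	0	4	4		empty
1	0	4	5		empty
1	0	4	6		empty
1	0	4	7		empty
1	0	4	8		empty
1	0	4	9		empty
1	0	5	0		empty
1	0	5	1		empty
1	0	5	2		empty
1	0	5	3		empty
1	0	5	4		empty
1	0	5	5		empty
1	0	5	6		empty
1	0	5	7		empty
1	0	5	8		empty
1	0	5	9		empty
1	0	6	0		empty
1	0	6	1		empty
1	0	6	2		empty
1	0	6	3		empty
1	0	6	4		empty
1	0	6	5		empty
1	0	6	6		empty
1	0	6	7		empty
1	0	6	8		empty
1	0	6	9		empty
1	0	7	0		empty
1	0	7	1		empty
1	0	7	2		empty
1	0	7	3		empty
1	0	7	4		empty
1	0	7	5		empty
1	0	7	6		empty
1	0	7	7		empty
1	0	7	8		empty
1	0	7	9		empty
1	0	8	0		empty
1	0	8	1		empty
1	0	8	2		empty
1	0	8	3		empty
1	0	8	4		empty
1	0	8	5		empty
1	0	8	6		empty
1	0	8	7		empty
1	0	8	8		empty
1	0	8	9		empty
1	0	9	0	REF	reference
1	0	9	1		empty
1	0	9	2		empty
1	0	9	3		empty
1	0	9	4		empty
1	0	9	5		empty
1	0	9	6		empty
1	0	9	7		empty
1	0	9	8		empty
1	0	9	9		empty
1	1	0	0	A04	analyte
1	1	0	1	A04	analyte
1	1	0	2	A08	analyte
1	1	0	3	A08	analyte
1	1	0	4	A12	analyte
1	1	0	5	A12	analyte
1	1	0	6	A16	analyte
1	1	0	7	A16	analyte
1	1	0	8	A20	analyte
1	1	0	9	A20	analyte
1	1	1	0	A24	analyte
1	1	1	1	A24	analyte
1	1	1	2	A28	analyte
1	1	1	3	A28	analyte
1	1	1	4	A32	analyte
1	1	1	5	A32	analyte
1	1	1	6	A36	analyte
1	1	1	7	A36	analyte
1	1	1	8	A40	analyte
1	1	1	9	A40	analyte
1	1	2	0	A44	analyte
1	1	2	1	A44	analyte
1	1	2	2	A48	analyte
1	1	2	3	A48	analyte
1	1	2	4	NEG	negative
1	1	2	5	NEG	negative
1	1	2	6	NEG	negative
1	1	2	7	NEG	negative
1	1	2	8		empty
1	1	2	9		empty
1	1	3	0		empty
1	1	3	1		empty
1	1	3	2		empty
1	1	3	3		empty
1	1	3	4		empty
1	1	3	5		empty
1	1	3	6		empty
1	1	3	7		empty
1	1	3	8		empty
1	1	3	9		empty
1	1	4	0		empty
1	1	4	1		empty
1	1	4	2		empty
1	1	4	3		empty
1	1	4	4		empty
1	1	4	5		empty
1	1	4	6		empty
1	1	4	7		empty
1	1	4	8		empty
1	1	4	9		empty
1	1	5	0		empty
1	1	5	1		empty
1	1	5	2		empty
1	1	5	3		empty
1	1	5	4		empty
1	1	5	5		empty
1	1	5	6		empty
1	1	5	7		empty
1	1	5	8		empty
1	1	5	9		empty
1	1	6	0		empty
1	1	6	1		empty
1	1	6	2		empty
1	1	6	3		empty
1	1	6	4		empty
1	1	6	5		empty
1	1	6	6		empty
1	1	6	7		empty
1	1	6	8		empty
1	1	6	9		empty
1	1	7	0		empty
1	1	7	1		empty
1	1	7	2		empty
1	1	7	3		empty
1	1	7	4		empty
1	1	7	5		empty
1	1	7	6		empty
1	1	7	7		empty
1	1	7	8		empty
1	1	7	9		empty
1	1	8	0		empty
1	1	8	1		empty
1	1	8	2		empty
1	1	8	3		empty
1	1	8	4		empty
1	1	8	5		empty
1	1	8	6		empty
1	1	8	7		empty
1	1	8	8		empty
1	1	8	9		empty
1	1	9	0		empty
1	1	9	1		empty
1	1	9	2		empty
1	1	9	3		empty
1	1	9	4		empty
1	1	9	5		empty
1	1	9	6		empty
1	1	9	7		empty
1	1	9	8		empty
1	1	9	9	REF	reference
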