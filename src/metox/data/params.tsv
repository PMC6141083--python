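residue_name	atom_name	radius_A	charge_e	lj_epsilon	lj_rmin_half
*	N	1.55	-0.47	0.20	1.85
*	H	1.10	0.31	0.046	0.225
*	CA	1.70	0.07	0.07	2.00
*	HA	1.10	0.09	0.022	1.32
*	C	1.70	0.51	0.11	2.00
*	O	1.52	-0.51	0.12	1.70
MET	CB	1.70	-0.18	0.055	2.175
MET	HB1	1.10	0.09	0.022	1.32
MET	HB2	1.10	0.09	0.022	1.32
MET	HB3	1.10	0.09	0.022	1.32
MET	CG	1.70	-0.14	0.055	2.175
MET	HG1	1.10	0.09	0.022	1.32
MET	HG2	1.10	0.09	0.022	1.32
MET	SD	1.80	-0.09	0.45	2.00
MET	CE	1.70	-0.22	0.078	2.04
MET	HE1	1.10	0.09	0.022	1.32
MET	HE2	1.10	0.09	0.022	1.32
MET	HE3	1.10	0.09	0.022	1.32
MSX	CB	1.70	-0.18	0.055	2.175
MSX	HB1	1.10	0.09	0.022	1.32
MSX	HB2	1.10	0.09	0.022	1.32
MSX	HB3	1.10	0.09	0.022	1.32
MSX	CG	1.70	-0.14	0.055	2.175
MSX	HG1	1.10	0.09	0.022	1.32
MSX	HG2	1.10	0.09	0.022	1.32
MSX	SD	1.80	0.36	0.35	2.00
MSX	OD	1.52	-0.45	0.12	1.70
MSX	CE	1.70	-0.22	0.078	2.04
MSX	HE1	1.10	0.09	0.022	1.32
MSX	HE2	1.10	0.09	0.022	1.32
MSX	HE3	1.10	0.09	0.022	1.32
ALA	CB	1.70	-0.27	0.078	2.04
ALA	HB1	1.10	0.09	0.022	1.32
ALA	HB2	1.10	0.09	0.022	1.32
ALA	HB3	1.10	0.09	0.022	1.32
HOH	O	1.52	-0.834	0.1521	1.7682
HOH	OH2	1.52	-0.834	0.1521	1.7682
HOH	H1	1.10	0.417	0.046	0.225
HOH	H2	1.10	0.417	0.046	0.225
TIP3	OH2	1.52	-0.834	0.1521	1.7682
TIP3	H1	1.10	0.417	0.046	0.225
TIP3	H2	1.10	0.417	0.046	0.225
BEA	BD	3.00	0.0	0.10	3.37
*	HN	1.10	0.31	0.046	0.225
*	OXT	1.52	-0.51	0.12	1.70
*	S	1.80	-0.09	0.45	2.00
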