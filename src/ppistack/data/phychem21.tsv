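# 21 physicochemical property scales per residue, curated from standard published
# sources: kd = Kyte-Doolittle hydropathy; hw = Hopp-Woods hydrophilicity;
# scm = side-chain mass (Da); vol = residue volume (A^3, Zamyatnin);
# pol = polarity (Grantham); pi = isoelectric point; pa/pb/pt = Chou-Fasman
# helix/sheet/turn propensities; gc = composition (Grantham); gv = side-chain
# volume (Grantham); sasa = maximum solvent-accessible surface area (A^2, Tien);
# chg = net charge at pH 7; aro = aromatic; ali = aliphatic; polb = polar;
# hbd/hba = side-chain hydrogen-bond donors/acceptors; sul = sulfur-containing;
# eis = Eisenberg consensus hydrophobicity; blk = bulkiness (Zimmerman).
aa	kd	hw	scm	vol	pol	pi	pa	pb	pt	gc	gv	sasa	chg	aro	ali	polb	hbd	hba	sul	eis	blk
A	1.8	-0.5	15.0	88.6	8.1	6.00	1.42	0.83	0.66	0.00	31.0	129	0	0	1	0	0	0	0	0.62	11.50
C	2.5	-1.0	47.0	108.5	5.5	5.07	0.70	1.19	1.19	2.75	55.0	167	0	0	0	1	1	1	1	0.29	13.46
D	-3.5	3.0	59.0	111.1	13.0	2.77	1.01	0.54	1.46	1.38	54.0	193	-1	0	0	1	0	4	0	-0.90	11.68
E	-3.5	3.0	73.0	138.4	12.3	3.22	1.51	0.37	0.74	0.92	83.0	223	-1	0	0	1	0	4	0	-0.74	13.57
F	2.8	-2.5	91.0	189.9	5.2	5.48	1.13	1.38	0.60	0.00	132.0	240	0	1	0	0	0	0	0	1.19	19.80
G	-0.4	0.0	1.0	60.1	9.0	5.97	0.57	0.75	1.56	0.74	3.0	104	0	0	0	0	0	0	0	0.48	3.40
H	-3.2	-0.5	82.0	153.2	10.4	7.59	1.00	0.87	0.95	0.58	96.0	224	0.1	1	0	1	1	1	0	-0.40	13.69
I	4.5	-1.8	57.0	166.7	5.2	6.02	1.08	1.60	0.47	0.00	111.0	197	0	0	1	0	0	0	0	1.38	21.40
K	-3.9	3.0	73.0	168.6	11.3	9.74	1.16	0.74	1.01	0.33	119.0	236	1	0	0	1	3	0	0	-1.50	15.71
L	3.8	-1.8	57.0	166.7	4.9	5.98	1.21	1.30	0.59	0.00	111.0	201	0	0	1	0	0	0	0	1.06	21.40
M	1.9	-1.3	75.0	162.9	5.7	5.74	1.45	1.05	0.60	0.00	105.0	224	0	0	0	0	0	1	1	0.64	16.25
N	-3.5	0.2	58.0	114.1	11.6	5.41	0.67	0.89	1.56	1.33	56.0	195	0	0	0	1	2	2	0	-0.78	12.82
P	-1.6	0.0	42.0	112.7	8.0	6.30	0.57	0.55	1.52	0.39	32.5	159	0	0	0	0	0	0	0	0.12	17.43
Q	-3.5	0.2	72.0	143.8	10.5	5.65	1.11	1.10	0.98	0.89	85.0	225	0	0	0	1	2	2	0	-0.85	14.45
R	-4.5	3.0	101.0	173.4	10.5	10.76	0.98	0.93	0.95	0.65	124.0	274	1	0	0	1	5	0	0	-2.53	14.28
S	-0.8	0.3	31.0	89.0	9.2	5.68	0.77	0.75	1.43	1.42	32.0	155	0	0	0	1	1	2	0	-0.18	9.47
T	-0.7	-0.4	45.0	116.1	8.6	5.60	0.83	1.19	0.96	0.71	61.0	172	0	0	0	1	1	2	0	-0.05	15.77
V	4.2	-1.5	43.0	140.0	5.9	5.96	1.06	1.70	0.50	0.00	84.0	174	0	0	1	0	0	0	0	1.08	21.57
W	-0.9	-3.4	130.0	227.8	5.4	5.89	1.08	1.37	0.96	0.13	170.0	285	0	1	0	0	1	0	0	0.81	21.67
Y	-1.3	-2.3	107.0	193.6	6.2	5.66	0.69	1.47	1.14	0.20	136.0	263	0	1	0	1	1	1	0	0.26	18.03
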