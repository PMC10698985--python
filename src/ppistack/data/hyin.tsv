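# Hydrophilicity / hydrophobicity index pair per residue.
# hydrophilicity: Hopp & Woods; hydropathy: Kyte & Doolittle.
aa	hydrophilicity	hydropathy
A	-0.5	1.8
C	-1.0	2.5
D	3.0	-3.5
E	3.0	-3.5
F	-2.5	2.8
G	0.0	-0.4
H	-0.5	-3.2
I	-1.8	4.5
K	3.0	-3.9
L	-1.8	3.8
M	-1.3	1.9
N	0.2	-3.5
P	0.0	-1.6
Q	0.2	-3.5
R	3.0	-4.5
S	0.3	-0.8
T	-0.4	-0.7
V	-1.5	4.2
W	-3.4	-0.9
Y	-2.3	-1.3
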