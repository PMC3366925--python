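# haplogroup label (prefix) -> major-clade bin
A2	A2
B2	B2
C1	C1
D1	D1
L0	L0
L1	L1
L2	L2
L3	L3
HV	HV
JT	JT
N1'2	N1'2
U	U
G	G
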