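outer5	outer3	inner5	inner3	dG
A	U	A	U	-0.93
A	U	U	A	-1.10
A	U	G	C	-2.08
A	U	C	G	-2.24
A	U	G	U	-1.20
A	U	U	G	-1.20
U	A	A	U	-1.33
U	A	U	A	-0.93
U	A	G	C	-2.11
U	A	C	G	-2.35
U	A	G	U	-1.20
U	A	U	G	-1.20
G	C	A	U	-2.35
G	C	U	A	-2.24
G	C	G	C	-3.26
G	C	C	G	-3.42
G	C	G	U	-1.20
G	C	U	G	-1.20
C	G	A	U	-2.11
C	G	U	A	-2.08
C	G	G	C	-2.36
C	G	C	G	-3.26
C	G	G	U	-1.20
C	G	U	G	-1.20
G	U	A	U	-1.20
G	U	U	A	-1.20
G	U	G	C	-1.20
G	U	C	G	-1.20
G	U	G	U	-0.50
G	U	U	G	-0.50
U	G	A	U	-1.20
U	G	U	A	-1.20
U	G	G	C	-1.20
U	G	C	G	-1.20
U	G	G	U	-0.50
U	G	U	G	-0.50
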