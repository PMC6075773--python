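isoform	S91	T94	C95	W97	L98	F99	F102	S117	R118	F121	L122	V125	A126	V128	P178	L179	V181	S182	I185	T186	I189	M190	F193	L194	A197	Y198	I200	S201	F204	V205	F208	V209	L212
TaAOX1a-2AL.sv1	T	S	L	F	P	T	F	C	R	M	L	V	A	V	Y	E	A	L	A	V	V	F	A	Y	G	Y	I	S	F	A	V	V	L
TaAOX1a-2AL.sv2	T	S	L	F	P	T	F	C	R	M	L	V	A	V	Y	E	A	L	A	V	V	F	A	Y	G	Y	I	S	F	A	V	V	L
TaAOX1a-2BL	T	S	L	F	P	T	F	C	R	M	L	V	A	V	Y	E	A	L	A	V	V	F	A	Y	G	Y	I	S	F	A	V	V	L
TaAOX1a-2DL.sv1	T	S	L	F	P	T	F	C	R	M	L	V	A	V	Y	E	A	L	A	V	V	F	A	Y	G	Y	I	S	F	A	V	V	L
TaAOX1a-2DL.sv2	T	S	L	F	P	T	F	C	R	M	L	V	A	V	Y	E	A	L	A	V	V	F	A	Y	G	Y	I	S	F	A	V	V	L
TaAOX1a-like-2DL	-	-	-	-	-	-	-	-	-	-	-	-	-	-	Y	E	A	L	A	V	V	F	A	Y	G	Y	V	S	F	A	V	V	L
TaAOX1c-6AL	T	S	L	V	P	T	F	C	R	M	L	V	A	V	Y	E	A	L	A	V	V	F	A	Y	G	Y	I	S	F	A	V	V	L
TaAOX1c-6BL.sv1	T	S	L	V	P	T	F	C	R	M	L	V	A	V	Y	E	A	L	A	V	V	F	A	Y	G	Y	V	S	F	A	V	V	L
TaAOX1c-6BL.sv2	T	S	L	V	P	T	F	C	R	M	L	V	A	V	Y	E	A	L	A	V	V	F	A	Y	G	Y	V	S	F	A	V	V	L
TaAOX1c-6BL.sv3	T	S	L	V	P	T	F	C	R	M	L	V	A	V	Y	E	A	L	A	V	V	F	A	Y	G	Y	V	S	F	A	V	V	L
TaAOX1c-6DL	T	S	L	V	P	T	F	C	R	M	L	V	A	V	Y	E	A	L	A	V	V	F	A	Y	G	Y	V	S	F	A	V	V	L
put.TaAOX1e-3DS	T	A	I	W	P	T	F	C	R	M	L	V	A	V	Y	E	A	L	V	V	V	F	A	Y	T	Y	A	S	V	A	M	V	L
TaAOX1d-2AL.1	I	T	L	A	G	S	F	S	H	L	L	V	A	V	W	E	A	L	A	T	V	F	A	Y	G	Y	V	S	F	A	F	V	L
TaAOX1d-2AL.2.sv1	V	S	L	V	P	R	F	S	H	L	L	V	A	V	W	E	A	L	A	A	V	F	A	Y	G	Y	I	S	F	A	F	V	L
TaAOX1d-2AL.2.sv2	V	S	L	V	P	R	F	S	H	L	L	V	A	V	W	E	A	L	A	A	V	F	A	Y	G	Y	I	S	F	A	F	V	L
TaAOX1d-2DL	V	S	L	V	P	R	F	S	H	L	L	V	A	V	W	E	A	L	A	A	V	F	A	Y	G	Y	I	S	F	A	F	V	L
put.TaAOX1d-like-4AS	-	-	-	-	-	-	F	S	H	L	L	V	A	V	C	E	A	L	P	T	V	F	A	Y	G	Y	V	S	F	A	F	V	L
TuAOX1a	T	S	L	F	P	T	F	C	R	M	L	V	A	V	Y	E	A	L	A	V	V	F	A	Y	G	Y	I	S	F	A	V	V	L
TuAOX1c	T	S	L	V	P	T	F	C	R	M	L	V	A	V	Y	E	A	L	A	V	V	F	A	Y	G	Y	V	S	F	A	V	V	L
TuAOX1d.1	V	S	L	V	P	R	F	S	H	L	L	V	A	V	W	E	A	L	A	A	V	F	A	Y	G	Y	I	S	F	A	F	V	L
TuAOX1d.2	I	T	L	K	G	S	F	S	H	L	L	V	A	V	W	E	A	L	A	T	V	F	A	Y	G	Y	V	S	F	A	F	V	L
AetAOX1a	T	S	L	F	P	T	F	C	R	M	L	V	A	V	Y	E	A	L	A	V	V	F	A	Y	G	Y	I	S	F	A	V	V	L
AetAOX1e	T	A	M	W	P	T	F	C	R	M	L	V	A	V	Y	E	A	L	A	V	V	F	A	Y	T	Y	A	S	V	A	M	V	L
AetAOX1d	V	S	L	V	P	R	F	S	H	L	L	V	A	V	W	E	A	L	A	A	V	F	A	Y	G	Y	I	S	F	A	F	V	L
AetAOX1d-like	I	T	L	A	G	S	F	S	H	L	L	V	A	V	-	-	-	-	-	-	V	F	A	Y	G	Y	I	S	L	-	-	-	-
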