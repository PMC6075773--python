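isoform	H138	L142	R143	R163	L166	Q187	M131	M135	L139	S141	M145	R147	D148	L156	A159	M167	R180	I183
TaAOX1a-2AL.sv1	H	L	R	R	L	Q	M	M	L	S	F	Q	S	L	A	M	R	V
TaAOX1a-2AL.sv2	H	L	R	R	L	Q	M	M	L	S	F	Q	S	L	A	M	R	V
TaAOX1a-2BL	H	L	R	R	L	Q	M	M	L	S	F	Q	S	L	A	M	R	V
TaAOX1a-2DL.sv1	H	L	R	R	L	Q	M	M	L	S	F	Q	S	L	A	M	R	V
TaAOX1a-2DL.sv2	H	L	R	R	L	Q	M	M	L	S	F	Q	S	L	A	M	R	V
TaAOX1a-like-2DL	H	L	R	R	L	Q	M	V	L	S	F	H	S	M	A	M	R	V
TaAOX1c-6AL	H	L	R	R	L	Q	M	M	L	S	F	Q	S	L	A	M	R	V
TaAOX1c-6BL.sv1	H	L	R	R	L	Q	M	M	L	S	F	Q	S	L	A	M	R	V
TaAOX1c-6BL.sv2	H	L	R	R	L	Q	M	M	L	S	F	Q	S	L	A	M	R	V
TaAOX1c-6BL.sv3	H	L	R	R	L	Q	M	M	L	S	F	Q	S	L	A	M	R	V
TaAOX1c-6DL	H	L	R	R	L	Q	M	M	L	S	F	Q	S	L	A	M	R	V
put.TaAOX1e-3DS	H	L	R	R	L	Q	M	A	L	S	F	Q	S	L	A	M	R	V
TaAOX1d-2AL.1	H	L	R	R	L	Q	M	V	L	S	F	H	S	M	A	M	R	V
TaAOX1d-2AL.2.sv1	H	L	R	R	L	Q	M	V	L	S	F	H	S	M	A	M	R	V
TaAOX1d-2AL.2.sv2	H	L	R	R	L	Q	M	V	L	S	F	H	S	M	A	M	R	V
TaAOX1d-2DL	H	L	R	R	L	Q	M	V	L	S	F	H	S	M	A	M	R	V
put.TaAOX1d-like-4AS	H	L	R	R	L	Q	M	V	L	S	F	H	N	M	A	M	R	V
TuAOX1a	H	L	R	R	L	Q	M	M	L	S	F	Q	S	L	A	M	R	V
TuAOX1c	H	L	R	R	L	Q	M	M	L	S	F	Q	S	L	A	M	R	V
TuAOX1d.1	H	L	R	R	L	Q	M	V	L	S	F	H	S	M	A	M	R	V
TuAOX1d.2	H	L	R	R	L	Q	M	V	L	S	F	H	S	M	A	M	R	V
AetAOX1a	H	L	R	R	L	Q	M	M	L	S	F	Q	S	L	A	M	R	V
AetAOX1e	H	L	R	R	L	Q	M	A	L	S	F	Q	S	L	A	M	R	V
AetAOX1d	H	L	R	R	L	Q	M	V	L	S	F	H	S	M	A	M	R	V
AetAOX1d-like	H	L	R	R	L	-	M	V	L	S	F	H	S	M	A	M	-	-
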