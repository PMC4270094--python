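cell_id	sub_class	parvalbumin	somatostatin	mGluR1a	SATB1	bouton_targets	ankyrinG	EM
123011c3	C-BC	+	n.t.	n.t.	n.t.	n.t.	n.t.	Soma/proximal dendrite
cvi30	C-BC	+	n.t.	n.t.	n.t.	n.t.	n.t.	Soma/proximal dendrite
cvi33	C-BC	+	n.t.	n.t.	n.t.	n.t.	n.t.	n.t.
cvi35	C-BC	+	n.t.	n.t.	n.t.	n.t.	n.t.	n.t.
cvi55	C-BC	n.t.	n.t.	n.t.	n.t.	n.t.	n.t.	Soma/proximal dendrite
cvi65	C-BC	+	n.t.	n.t.	n.t.	n.t.	n.t.	n.t.
cvi75	C-BC	+	n.t.	n.t.	n.t.	n.t.	n.t.	n.t.
cvi151	C-BC	n.t.	n.t.	n.t.	n.t.	n.t.	n.t.	n.t.
cvi251	C-BC	n.t.	n.t.	n.t.	n.t.	n.t.	n.t.	n.t.
cvi240b	H-BC	+	n.t.	n.t.	n.t.	n.t.	n.t.	Soma/proximal dendrite
042911c5	H-BC	+	n.t.	n.t.	n.t.	n.t.	n.t.	n.t.
gs0920	H-BC	+	n.t.	n.t.	n.t.	n.t.	n.t.	n.t.
gs012913	O-Bistrat	+	+	n.t.	n.t.	n.t.	n.t.	n.t.
gs022713	O-Bistrat	+	+	n.t.	n.t.	n.t.	n.t.	n.t.
cvi017	O-Bistrat	n.t.	+	n.t.	n.t.	n.t.	n.t.	n.t.
cvi255	O-Bistrat	-	+	n.t.	n.t.	n.t.	n.t.	n.t.
cvi312	O-Bistrat	n.t.	+	-	n.t.	n.t.	n.t.	n.t.
cvi270	C-Bistrat	+	+	n.t.	n.t.	n.t.	n.t.	n.t.
imi069	C-Bistrat	n.t.	+	n.t.	n.t.	n.t.	n.t.	n.t.
cvi190	C-Bistrat	-	+	n.t.	n.t.	n.t.	n.t.	n.t.
090311c3	E-AAC	+	n.t.	n.t.	n.t.	n.t.	n.t.	AIS
cvi059	E-AAC	n.t.	n.t.	n.t.	n.t.	n.t.	n.t.	AIS
cvi153	C-AAC	n.t.	n.t.	n.t.	n.t.	n.t.	n.t.	AIS
cvi258	C-AAC	+	n.t.	n.t.	n.t.	n.t.	n.t.	AIS
cvi315	C-AAC	n.t.	n.t.	n.t.	-	n.t.	n.t.	n.t.
imi075	C-AAC	+	n.t.	n.t.	n.t.	AIS	n.t.	n.t.
07082014cs6	C-AAC	n.t.	n.t.	n.t.	n.t.	n.t.	AIS	AIS
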