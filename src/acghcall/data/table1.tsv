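sample_id	age	stage_group	figo_stage	histology	grade	chemo	staging	status	os_months	progression	pfs_months	cluster
T102	70	early	Ic capsule ruptured	C	2	no	optimal	Alive	42	no	42	A
T103	61	early	Ic capsule ruptured	C	3	yes	optimal	Alive	154	no	154	A
T104	61	early	Ia	C	3	yes	optimal	Dead	13	yes	10	A
T105	47	early	Ia	C	3	no	minimal	Alive	136	no	136	A
T106	64	early	Ic capsule ruptured	C	3	no	optimal	Alive	39	no	39	A
T108	41	early	Ic capsule ruptured	E	1	yes	minimal	Alive	73	no	73	A
T109	55	early	Ib	E	1	yes	minimal	Alive	137	no	137	A
T110	64	early	Ic ascites positive	E	1	no	modified	Alive	49	yes	49	A
T111	46	early	Ic ovarian surface	E	2	no	minimal	Alive	146	no	146	A
T112	53	early	Ic capsule ruptured	E	2	yes	minimal	Alive	44	no	44	A
T113	42	early	Ic capsule ruptured	M	1	no	optimal	Alive	69	no	69	A
T114	35	early	Ia	M	2	no	optimal	Alive	152	no	152	A
T115	27	early	Ia	S	1	yes	minimal	Alive	65	no	65	A
T116	62	early	Ia	S	1	no	minimal	Alive	59	no	59	B
T117	50	early	Ic ascites positive	S	1	no	modified	Dead	61	yes	7	B
T118	53	early	Ia ovarian surface	S	3	no	optimal	Alive	175	no	175	A
T302	47	advanced	III	C	2	yes	optimal	Dead	17	yes	17	B
T303	57	advanced	IV	C	3	yes	incomplete	Dead	9	yes	8	B
T304	51	advanced	III	C	3	yes	incomplete	Dead	14	yes	14	A
T305	74	advanced	IIIb	C	3	yes	optimal	Dead	60	yes	47	B
T306	48	advanced	IIIa	C	3	yes	optimal	Alive	104	no	104	B
T308	45	advanced	IV	E	2	yes	optimal	Dead	19	yes	9	B
T309	47	advanced	IIIc	E	2	yes	optimal	Dead	41	yes	21	B
T310	74	advanced	IIIb	E	2	yes	optimal	Dead	57	yes	57	B
T311	67	advanced	IIIc	E	3	yes	minimal	Dead	61	yes	22	B
T312	53	advanced	IIIb	E	3	yes	optimal	Dead	28	yes	28	B
T313	67	advanced	III	M	1	yes	optimal	Dead	22	yes	22	A
T314	76	advanced	IV	M	2	yes	optimal	Dead	15	yes	13	A
T315	70	advanced	IIIc	S	1	yes	optimal	Alive	136	no	136	A
T316	76	advanced	IV	S	1	yes	optimal	Alive	22	yes	22	A
T317	80	advanced	IIIc	S	2	yes	incomplete	Dead	6	yes	5	B
T318	61	advanced	IIIc	S	3	yes	unknown	Dead	5	yes	12	B
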