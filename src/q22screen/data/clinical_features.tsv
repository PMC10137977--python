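patient_id	sex	age	ear_side	microtia_degree	cardiac	other_anomalies	familial_child
1	M	8	B	I	VSD		False
2	M	6	R	I	VSD		False
3	F	20	R	I	TOF		False
4	M	13	L	I	VSD;TI;PI		False
5	M	25	L	I	VSD		False
6	M	9	L	I	TOF		False
7	M	6	R	II	PDA		False
8	M	12	R	II	VSD;PH		False
9	M	11	R	II	VSD	cleft palate	False
10	M	8	R	II	TOF		False
11	M	7	R	II	PFO	bilateral preauricular fistula	False
12	F	13	R	II	ASD		False
13	M	10	R	II	VSD		False
14	M	18	L	II	VSD		False
15	M	15	L	II	ASD		False
16	F	6	L	II	VSD		False
17	M	7	L	II	TOF		False
18	F	35	R	III	ASD	facial cleft;hemifacial dysplasia	False
19	F	8	R	III	ASD	hemifacial dysplasia;facial transversal cleft;left eye cyst	False
20	M	7	B	I	ASD;PDA	polydactyly;epilepsy	True
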