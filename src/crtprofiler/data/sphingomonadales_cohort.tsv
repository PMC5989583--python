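serial	species	strain	status	genotype	group	colour	pgc
1	Sphingopyxis alaskensis	RB2256	complete	E,B,I,Y,Z,G	I	Yellow to beige	0
2	Sphingopyxis macrogoltabida	EY-1	complete	E,B,I,Y,Z,G	I	Unknown	0
3	Sphingopyxis fribergensis	Kp5.2	complete	E,B,I,Y,Z,G	I	Yellow	0
4	Sphingomonas sanxanigenens	DSM 19645	complete	E,B,I,Y,Z,G	I	Colourless/white	1
5	Sphingorhabdus sp.	M41	complete	E,B,I,Y,Z,G	I	Colourless/white	0
6	Sphingopyxis sp.	113P3	complete	E,B,I,Y,Z,G	I	Yellowish brown	0
7	Sphingopyxis terrae	NBRC 15098	complete	E,B,I,Y,Z,G	I	Light or deep-yellow	0
8	Sphingobium sp.	SYK-6	complete	E,B,I,Y,Z,G	I	Yellow	0
9	Sphingomonas hengshuiensis	WHSC-8	complete	E,B,I,Y,Z,G	I	Yellow	1
10	Sphingomonas sp.	Root241	draft	E,B,I,Y,Z,G	I	Unknown	0
11	Sphingomonas sp.	ATCC 31555	draft	E,B,I,Y,Z,G,W	II	Red	0
12	Sphingomonas paucimobilis	NBRC 13935	draft	E,B,I,Y,Z,G	I	Yellow	0
13	Sphingomonas astaxanthinifaciens	DSM 22298	draft	E,B,I,Y,Z,W,X	III	Red	1
14	Sphingobium chlorophenolicum	L-1	complete	E,B,I,Y,Z,G	I	Yellow	0
15	Sphingobium sp.	MI1205	complete	E,B,I,Y,Z,G	I	Brownish-yellow	0
16	Sphingobium sp.	EP60837	complete	E,B,I,Y,Z,G	I	Colourless/white	0
17	Sphingobium sp.	YBL2	complete	E,B,I,Y,Z,G	I	Yellow	0
18	Novosphingobium aromaticivorans	DSM 12444	complete	E,B,I,Y,Z,G	I	Yellow	0
19	Citromicrobium sp.	JL477	complete	E,B,I,Y,Z,G	I	Yellow	1
20	Altererythrobacter dongtanensis	KCTC 22672	complete	E,B,I,Y,Z,G	I	Yellow	0
21	Altererythrobacter namhicola	JCM 16345	complete	E,B,I,Y,Z,G,W	II	Orange	0
22	Altererythrobacter epoxidivorans	CGMCC 1.7731	complete	E,B,I,Y,Z,G	I	Yellow	0
23	Altererythrobacter atlanticus	26DY36	complete	E,B,I,Y,Z,G	I	Yellow	0
24	Altererythrobacter ishigakiensis	NBRC 107699	complete	E,B,I,Y,Z,G,W	II	Orange-red	1
25	Erythrobacter litoralis	HTCC2594	complete	E,B,I,Y,Z,G,W	II	Pink	0
26	Erythrobacter atlanticus	s21-N3	complete	E,B,I,Y,Z,G	I	Yellow-brown	0
27	Sphingobium yanoikuyae	ATCC 51230	draft	E,B,I,Y,Z,G	I	Creamy white	0
28	Novosphingobium sp.	PP1Y	complete	E,B,I,Y,Z,G	I	Yellow	0
29	Novosphingobium pentaromativorans	US6-1	complete	E,B,I,Y,Z,G	I	Yellow	0
30	Porphyrobacter neustonensis	DSM 9434	complete	E,B,I,Y,Z,G,W	II	Orange	1
31	Sphingomonas sp.	NIC1	complete	E,B,I,Y,Z,G	I	Unknown	0
32	Sphingomonas melonis	TY	draft	E,B,I,Y,Z,G	I	Yellow	0
33	Altererythrobacter marensis	KCTC 22370	complete	E,B,I,Y,Z,G	I	Yellow	0
34	Croceicoccus naphthovorans	PQ-2	complete	E,B,I,Y,Z,G	I	Yellow	0
35	Sphingomonas taxi	ATCC 55669	complete	E,B,I,Y,Z,G,W	II	Yellow to orange	0
36	Sphingomonas sp.	RIT328	draft	E,B,I,Y,Z,G,W	II	Unknown	0
37	Sphingobium japonicum	UT26S	complete	E,B,I,Y,Z,G	I	Yellow	0
38	Sphingomonas sp.	MM-1	complete	E,I,Y	IV	Colourless/white	0
39	Sphingobium baderi	DE-13	complete	E,I	IV	Colourless/white	0
40	Sphingomonas wittichii	RW1	complete	E,Y	IV	Greyish-white (faintly yellow)	0
41	Sphingopyxis granuli	TFA	complete	E	IV	Yellowish	0
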