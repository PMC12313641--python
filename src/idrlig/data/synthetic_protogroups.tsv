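# Synthetic stand-in protogroup vocabulary mined from the package's toy ligand
# generator (seed 20260930). It is NOT the reference vocabulary derived from the
# Protein Data Bank chemical component corpus; it exists so downstream modules
# run without external data.
vocab_index	component_id	formula	atom_count	match_frequency	rank	atoms	bonds
1	lig039	C5	5	25	1	C,C,C,C,C	0-1;1-2;2-3;3-4
2	lig049	C5	5	25	2	C,C,C,C,C	0-1;1-2;2-3;3-4
3	lig001	C4S	5	17	3	C,C,C,C,S	0-1;1-2;2-3;1-4
4	lig027	C4S	5	17	4	C,C,C,C,S	0-1;1-2;2-3;1-4
5	lig017	C4O	5	16	5	C,C,C,C,O	0-1;1-2;2-3;3-4
6	lig025	C4O	5	15	6	C,C,C,C,O	0-1;1-2;2-3;1-4
7	lig022	C4N	5	13	7	C,C,C,C,N	0-1;1-2;2-3;3-4
8	lig059	C4N	5	13	8	C,C,C,C,N	0-1;1-2;2-3;1-4
9	lig046	C6	6	12	9	C,C,C,C,C,C	0-1;1-2;2-3;3-4;1-5
10	lig026	C5S	6	9	10	C,C,C,C,C,S	0-1;1-2;2-3;0-4;2-5
11	lig034	C5N	6	8	11	C,C,C,C,C,N	0-1;1-2;2-3;3-4;4-5
12	lig050	C5S	6	8	12	C,C,C,C,C,S	0-1;1-2;2-3;3-4;2-5
13	lig021	C4	4	43	13	C,C,C,C	0-1;1-2;2-3
14	lig002	C3N	4	21	14	C,C,C,N	0-1;0-2;0-3
15	lig043	C3N	4	21	15	C,C,C,N	0-1;0-2;0-3
16	lig029	C2NO	4	8	16	C,C,O,N	0-1;1-2;0-3
17	lig005	C6S	7	7	17	C,C,C,C,C,C,S	0-1;1-2;2-3;3-4;0-5;2-6
18	lig015	C7	7	7	18	C,C,C,C,C,C,C	0-1;1-2;2-3;3-4;4-5;0-5;2-6
19	lig041	C2OS	4	7	19	C,C,O,S	0-1;1-2;0-3
20	lig031	C6N	7	4	20	C,C,C,C,C,C,N	0-1;1-2;2-3;3-4;4-5;0-5;1-6
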