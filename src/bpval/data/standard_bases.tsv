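# Standard nucleobase coordinates in the base reference frame (Tsukuba
# convention): x along the pseudo-dyad toward the major groove, y toward
# the sugar, z normal to the base plane such that the base is viewed
# counter-clockwise from +z.  Units: Angstrom.  v1
# base	atom	x	y	z
A	C1'	-2.479	5.346	0.000
A	N9	-1.291	4.498	0.000
A	C8	0.024	4.897	0.000
A	N7	0.877	3.902	0.000
A	C5	0.071	2.771	0.000
A	C6	0.369	1.398	0.000
A	N6	1.611	0.909	0.000
A	N1	-0.668	0.532	0.000
A	C2	-1.912	1.023	0.000
A	N3	-2.320	2.290	0.000
A	C4	-1.267	3.124	0.000
G	C1'	-2.477	5.399	0.000
G	N9	-1.289	4.551	0.000
G	C8	0.023	4.962	0.000
G	N7	0.870	3.969	0.000
G	C5	0.071	2.833	0.000
G	C6	0.424	1.460	0.000
G	O6	1.554	0.955	0.000
G	N1	-0.700	0.641	0.000
G	C2	-1.999	1.087	0.000
G	N2	-2.949	0.139	-0.001
G	N3	-2.342	2.364	0.001
G	C4	-1.265	3.177	0.000
C	C1'	-2.477	5.402	0.000
C	N1	-1.285	4.542	0.000
C	C2	-1.472	3.158	0.000
C	O2	-2.628	2.709	0.001
C	N3	-0.391	2.344	0.000
C	C4	0.837	2.868	0.000
C	N4	1.875	2.027	0.001
C	C5	1.056	4.275	0.000
C	C6	-0.023	5.068	0.000
T	C1'	-2.481	5.354	0.000
T	N1	-1.284	4.500	0.000
T	C2	-1.462	3.135	0.000
T	O2	-2.562	2.608	0.000
T	N3	-0.298	2.407	0.000
T	C4	0.994	2.897	0.000
T	O4	1.944	2.119	0.000
T	C5	1.106	4.338	0.000
T	C7	2.466	4.961	0.001
T	C6	-0.024	5.057	0.000
U	C1'	-2.481	5.354	0.000
U	N1	-1.284	4.500	0.000
U	C2	-1.462	3.131	0.000
U	O2	-2.563	2.608	0.000
U	N3	-0.302	2.397	0.000
U	C4	0.989	2.884	0.000
U	O4	1.935	2.094	-0.001
U	C5	1.089	4.311	0.000
U	C6	-0.024	5.053	0.000
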