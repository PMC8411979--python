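# Watson-Crick base-pair "simple" parameter targets mined from
# high-quality (RSCC >= 0.95, resolution <= 1.60 A) re-refined crystal
# structures.  Signs follow the purine-first canonical pair order.
# shear/stretch in Angstrom, buckle/propeller in degrees.  v1
# category	pair_type	key	mean	sd	count
DNA-DNA	A-T	stretch	-0.111	0.048	899
DNA-DNA	A-T	shear	0.042	0.095	899
DNA-DNA	A-T	propeller	-10.495	6.315	899
DNA-DNA	A-T	buckle	1.325	7.327	899
DNA-DNA	G-C	stretch	-0.130	0.063	1544
DNA-DNA	G-C	shear	-0.215	0.101	1544
DNA-DNA	G-C	propeller	-6.432	7.498	1544
DNA-DNA	G-C	buckle	-0.385	8.453	1544
RNA-RNA	A-U	stretch	-0.103	0.041	602
RNA-RNA	A-U	shear	0.042	0.107	602
RNA-RNA	A-U	propeller	-11.560	4.560	602
RNA-RNA	A-U	buckle	-0.720	5.951	602
RNA-RNA	G-C	stretch	-0.131	0.056	675
RNA-RNA	G-C	shear	-0.209	0.115	675
RNA-RNA	G-C	propeller	-10.979	5.268	675
RNA-RNA	G-C	buckle	-3.403	5.437	675
DNA-RNA	A-T	stretch	-0.135	0.027	92
DNA-RNA	A-T	shear	0.103	0.060	92
DNA-RNA	A-T	propeller	-9.742	3.033	92
DNA-RNA	A-T	buckle	-5.269	2.679	92
DNA-RNA	G-C	stretch	-0.150	0.037	131
DNA-RNA	G-C	shear	-0.175	0.078	131
DNA-RNA	G-C	propeller	-7.512	4.648	131
DNA-RNA	G-C	buckle	0.838	7.368	131
DNA-RNA	A-U	stretch	-0.133	0.020	43
DNA-RNA	A-U	shear	0.007	0.050	43
DNA-RNA	A-U	propeller	-9.781	2.039	43
DNA-RNA	A-U	buckle	2.380	2.356	43
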