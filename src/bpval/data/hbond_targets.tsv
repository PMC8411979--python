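# Watson-Crick base-pair hydrogen-bond length targets mined from
# high-quality (RSCC >= 0.95, resolution <= 1.60 A) re-refined crystal
# structures.  Atom pairs are purine-first.  Units: Angstrom.  v1
# category	pair_type	key	mean	sd	count
DNA-DNA	A-T	N1-N3	2.825	0.053	899
DNA-DNA	A-T	N6-O4	2.999	0.099	899
DNA-DNA	G-C	O6-N4	2.901	0.095	1544
DNA-DNA	G-C	N1-N3	2.907	0.055	1544
DNA-DNA	G-C	N2-O2	2.830	0.078	1544
RNA-RNA	A-U	N1-N3	2.829	0.051	301
RNA-RNA	A-U	N6-O4	2.974	0.094	301
RNA-RNA	G-C	O6-N4	2.916	0.088	675
RNA-RNA	G-C	N1-N3	2.901	0.049	675
RNA-RNA	G-C	N2-O2	2.819	0.070	675
DNA-RNA	A-T	N1-N3	2.800	0.029	92
DNA-RNA	A-T	N6-O4	2.939	0.058	92
DNA-RNA	G-C	O6-N4	2.889	0.051	131
DNA-RNA	G-C	N1-N3	2.875	0.053	131
DNA-RNA	G-C	N2-O2	2.779	0.098	131
DNA-RNA	A-U	N1-N3	2.799	0.025	43
DNA-RNA	A-U	N6-O4	2.963	0.039	43
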