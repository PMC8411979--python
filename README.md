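# bpval

Geometry validation and restraint generation for Watson–Crick base
pairs in nucleic acid structure models (DNA, RNA and hybrids, from
crystallography or cryo-EM).

Refinement at modest resolution routinely distorts base-pair geometry:
hydrogen bonds stretch past 4 Å, bases buckle, pairs shear apart —
often without the experimental data demanding any of it.  `bpval` is
for crystallographers and model builders who want to (i) *score* how
normal every Watson–Crick pair in a model is against targets mined
from high-quality structures, (ii) *restrain* base-pair hydrogen bonds
and stacking during refinement, and (iii) *re-derive* those targets
from their own structure collections.

## The model in brief

Each base gets an orthonormal reference frame by Kabsch superposition
of the standard (Tsukuba-convention) base geometry onto its ring
atoms.  A pair is described by the six *simple* parameters in a frame
whose y axis follows the C1′–C1′ vector and whose z axis is the mean
base normal: shear, stretch, stagger (Å) and buckle, propeller,
opening (°), with buckle² + propeller² equal to the squared interbase
angle.  Four of them are validated against class-specific mined
targets (7 classes: DNA–DNA, RNA–RNA and DNA–RNA × A–T, A–U, G–C):

    Z_p   = (p − μ_class) / σ_class,   p ∈ {shear, stretch, buckle, propeller}
    Z_bpG = rms(Z_shear, Z_stretch, Z_buckle, Z_propeller)

Pairs with Z_bpG > 3.00 are flagged as outliers.  Model-level quality
is the rmsZ of all hydrogen-bond Z scores, the rmsZ per simple
parameter and rmsZ_bpG, each with a jackknife standard deviation;
two models of one entry compare via
Z_change = ΔM / sqrt(σ₁² + σ₂²) (significant beyond |2.6|).
Hydrogen-bond restraints carry the mined target/σ per bond (weight 2);
stacking restraints hold sequential bases at 3.4 Å (weight 5), and
nothing is restrained at resolutions of 1.70 Å or better.  See
`docs/methods.md` for the full account.

## Worked example

Build a 4-pair B-form duplex with heavily buckled pairs and validate
it.  With `spec.json` as

```json
{"category": "DNA-DNA", "pair_type": "G-C", "n_pairs": 4,
 "buckle": 50.0, "propeller": -25.0}
```

```sh
$ bpval build-fixture spec.json --seed 1 --out duplex.cif
wrote duplex.cif (8 residues)
$ bpval validate duplex.cif --json report.json
duplex: 4 WC pairs, 4 outliers (Z_bpG > 3.00)
hbond rmsZ 4.29 ± 0.87; shear rmsZ 2.13 ± 0.00; stretch rmsZ 2.06 ± 0.00; buckle rmsZ 5.96 ± 0.00; propeller rmsZ 2.48 ± 0.00
rmsZ_bpG 3.55 ± 0.00
  outlier A/1DG-B/4DC: Z_bpG 3.55
  outlier A/2DG-B/3DC: Z_bpG 3.55
  outlier A/3DG-B/2DC: Z_bpG 3.55
  outlier A/4DG-B/1DC: Z_bpG 3.55
```

Every pair scores Z_bpG = 3.55: the 50° buckle alone sits ~6σ from the
DNA G–C mean (−0.385 ± 8.453°), and the rms with the other three Z
scores lands above the 3.00 outlier line.  The stretched hydrogen
bonds that come with this distortion push the bond rmsZ to 4.29 —
against targets like N1–N3 = 2.907 ± 0.055 Å a well-refined model
should sit near 1.  Generating restraints for the same model
(resolution 2.45 Å, so the gate is open):

```sh
$ bpval restrain duplex.cif --out restraints.txt
wrote 18 restraints to restraints.txt
$ head -4 restraints.txt
# bpval external restraints v1
# weights: hbond 2, stacking 5
dist first chain A resi 1 ins . atoms N1 second chain B resi 4 ins . atoms N3 value 2.907 sigma 0.055 weight 2
dist first chain A resi 1 ins . atoms N2 second chain B resi 4 ins . atoms O2 value 2.830 sigma 0.078 weight 2
```

12 hydrogen-bond records (3 per G–C pair) plus 6 stacking records
(3 per strand); the values are the mined table entries verbatim.
`bpval compare before.json after.json` then classifies a refinement's
effect (|Δ rmsZ_bpG| > 0.5 is a meaningful change), and
`bpval mine collection/ --res-max 1.60` rebuilds target tables from
an annotated collection.

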