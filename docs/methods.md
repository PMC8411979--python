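# Methods

## Scope

`bpval` measures, validates and restrains the geometry of canonical
Watson–Crick (WC) base pairs — A–T, A–U and G–C — in nucleic acid
structure models.  It covers base-pair detection, base reference-frame
fitting, the "simple" intra-pair parameters, hydrogen-bond lengths,
Z-score validation with jackknife uncertainties, external restraint
generation for refinement, and re-derivation of target tables from
annotated structure collections.  Non-WC pairing modes (Hoogsteen,
wobble, sheared, …), base-step parameters, torsion restraints and
electron-density handling are out of scope; real-space correlation
coefficients (RSCC) are consumed from sidecar tables, never computed.

## Base frames and simple parameters

Each nucleobase carries a fixed standard reference frame (the Tsukuba
convention): x along the pseudo-dyad toward the major groove, y toward
the attached sugar, z normal to the base plane so that the base appears
counter-clockwise from +z.  The standard coordinates for A, C, G, T and
U ship as a plain-text data file; an observed base's frame is the
standard frame carried through the least-squares (Kabsch) superposition
of the standard ring atoms onto the observed ones.  Purine frames use
all nine ring atoms, pyrimidine frames six; exocyclic atoms never enter
the fit, which keeps frames stable for modified bases that share the
ring.  The fit rmsd is recorded; a missing ring atom is an error and
the residue drops out of pairing.

For a purine-first pair (I = purine, J = pyrimidine) the partner's
frame is anti-parallel: its y and z axes are negated before any
combination.  The pair frame is then

* **z** — unit mean of the two aligned base normals,
* **y** — unit C1′(J)→C1′(I) vector orthogonalized against z,
* **x** — y × z (right-handed),

and the six *simple* parameters are

* shear, stretch, stagger: components of (origin_I − origin_J) along
  x, y, z (Å);
* buckle = γ·(a·x), propeller = γ·(a·y), where γ is the angle between
  the aligned normals and a the unit hinge axis z_J′ × z_I — so
  buckle² + propeller² = γ² by construction (degrees);
* opening: signed angle between the projections of the two (aligned)
  y axes onto the pair plane, measured about +z (degrees).

If γ exceeds 90° after the anti-parallel flip the juxtaposition is not
pairable and is reported as such instead of yielding wild parameters.
Exchanging I and J negates shear and buckle and preserves the other
four; pair detection therefore canonicalizes to purine-first order and
flips signs when the input order was reversed, making reports
independent of residue order.

## Pair detection

Candidate detection is deliberately permissive so that restraint
generation does not miss badly modelled pairs: any two bases whose
frame origins lie within 15 Å and which make at least one inter-base
N/O–N/O contact ≤ 4.5 Å are candidates.  A candidate is classified WC
when the parent bases form {A,T}, {A,U} or {G,C}, the aligned interbase
angle is ≤ 65°, |stagger| ≤ 2.5 Å, and all standard donor/acceptor
atoms are present (A–T/A–U: N1–N3, N6–O4; G–C: O6–N4, N1–N3, N2–O2).
These four thresholds are this tool's own calibration points (exposed
in `PairScreen`); they are chosen wide enough to admit pairs whose
"bonds" stretch past 4 Å.  When two candidates compete for a residue,
the pair with more satisfied hydrogen bonds (distance ≤ 3.5 Å), then
the smaller mean deviation from the target bond lengths, wins; every
residue ends up in at most one WC pair.

Pairs are binned into seven classes: category (DNA–DNA, RNA–RNA,
DNA–RNA) × pair type (A–T, A–U, G–C), where hybrids take their type
from the pyrimidine identity.  Modified nucleotides are mapped to their
parent base via an editable component table with a ring-atom-name
fallback (nucleic class inferred from the presence of O2′); modified
pairs validate against the natural pair's targets, which mining
supports with a Welch-test comparison (see below).

## Targets

The embedded tables hold 17 hydrogen-bond entries and 28
simple-parameter entries (7 classes × shear/stretch/buckle/propeller),
each with mean, standard deviation and observation count, mined from
high-quality re-refined crystal structures (both partners RSCC ≥ 0.95,
resolution ≤ 1.60 Å).  Values are served at 3-decimal precision.  Two
classes (A–U in DNA–DNA, A–T in RNA–RNA) have no targets — too few
observations existed — and lookups for them raise instead of borrowing
another category's numbers; such pairs are reported unvalidated.  The
RNA–RNA A–U observation count differs between the two tables (301 vs
602) in the published source; both are kept as printed.  Stagger and
opening are measured and reported but carry no targets.

## Validation metrics

Every measurement standardizes as Z = (value − mean)/sd against its
class target.  Per pair, the overall geometry score is

    Z_bpG = rms(Z_shear, Z_stretch, Z_buckle, Z_propeller)

with Z_bpG > 3.00 flagging an outlier.  The root-mean-square form is
the shipped default; mean(|Z|) is available as a configuration option
(`zbpg_form="mean_abs"`).  Hydrogen-bond Z scores enter only the
hydrogen-bond rmsZ, never Z_bpG.  Model-level metrics are the rmsZ over
all bond Z scores, the rmsZ per simple parameter, and rmsZ_bpG (the rms
of per-pair Z_bpG values), each with a leave-one-out jackknife standard
deviation sd = sqrt(((n−1)/n)·Σ(θ₍ᵢ₎ − θ̄)²).

Two models of the same entry compare through
Z_change = (M_before − M_after)/sqrt(σ_before² + σ_after²);
|Z_change| > 2.6 is significant, and with no σ available significance
is reported as undetermined rather than guessed.  The combined-σ
denominator is a design choice where a single-σ convention would also
have been defensible.  At whole-model scale a change in rmsZ_bpG of
magnitude ≤ 0.5 is classified "no meaningful change" — the magnitude
expected from re-refinement alone.

A small bond-valence utility implements the Brown–Altermatt sum
V = Σ exp((R_o − d)/B) over ligands within a 3.0 Å coordination cutoff
(the cutoff is this tool's choice, logged).  Typical parameters for a
Cd²⁺ site are R_o = 1.875 Å for O ligands, 1.951 Å for N, B = 0.37 Å;
a divalent cation should sum to ≈ 2.0.

## Restraints

Hydrogen-bond restraints copy the target mean/sigma per bond verbatim
(weight 2); stacking restraints keep sequential bases at a 3.4 Å
interplanar separation (weight 5, sigma 0.2 Å — the sigma is this
tool's choice since published descriptions give only the target and
weight).  Stacking neighbours are consecutive usable nucleotides in a
chain whose frame origins are 2.5–5.0 Å apart along the mean base
normal.  Restraints are generated only when the data resolution is
worse than 1.70 Å; at or better than 1.70 Å the targets still serve
validation but the data needs no help.  Residues with alternate
conformations are excluded from restraints (they still validate), and
the `--nonucrest` flag disables generation entirely.  The file body is
a pure function of the model and the tables — regeneration after
rebuilding changes pair membership, never targets — see
`restraint_format.md`.

## Mining

`extract_observations` runs detection on every structure of a
collection and emits one observation record per WC pair with complete
bonds.  Filtering keeps records with both RSCC ≥ 0.95 (records without
RSCC annotation are dropped — the pipeline exists to select *known*
high-quality data) and resolution ≤ 1.60 Å, both bounds inclusive.
Aggregation canonicalizes shear/buckle signs (detection already
guarantees purine-first order), then reports count, mean and sample
(n−1) standard deviation per class and key; empty cells are absent,
never zero-filled.  Poolability questions use a Welch unequal-variance
two-sided t-test at α = 0.01.  The resolution sweep re-runs the filter
from 2.00 to 1.50 Å in 0.05 Å steps and tabulates per-class counts;
the published procedure picked 1.60 Å where a further 0.05 Å cost 24%
of the data, and that trade-off stays a human decision here.

## Synthetic data

The generator is the exact inverse of the measurement pipeline.
`build_pair` places two full standard bases (ring, WC-edge exocyclic
atoms, C1′) so that the measured simple parameters reproduce a
prescription; because the pair frame depends on the C1′–C1′ direction,
which moves with the bases, placement is solved by fixed-point
iteration (build → measure → correct), converging below 1e-9 for
|buckle|, |propeller| < 45° and refused near 90° where the hinge map
degenerates.  `build_duplex` stacks pairs with a helical rise (default
3.4 Å) and twist (36°), purines on one strand, plus a minimal synthetic
backbone trace; it is the fixture for stacking and neighbour logic, not
a physically refined helix.  Gaussian coordinate noise and rigid
motions are seeded; identical seeds give identical fixtures.

Hydrogen-bond lengths in built pairs are *emergent* from the parameter
placement — prescribing independent per-bond Gaussians is geometrically
impossible because two or three bond lengths share six degrees of
freedom.  Collections for mining-recovery experiments are therefore
drawn at the observation-record level (`synth_records`: bonds and
parameters from the published Gaussians, RSCC ≈ N(0.975, 0.01) with an
optional bad fraction, resolution uniform in 1.2–1.6 Å), while
`synth_structure_collection` exercises the full structural pipeline
with prescribed simple parameters.  Consequently, passing recovery
tests demonstrate that extraction, filtering and aggregation are
unbiased at realistic sample sizes (200 entries × 6 pairs ≈ 1200
observations, matching the published per-class counts in order of
magnitude); they do not probe refinement artefacts, correlated errors
between neighbouring residues, or density-dependent selection effects
present in real crystallographic data.

## Numerical choices and edge cases

* Superposition enforces a proper rotation (det = +1) via SVD sign
  correction and rejects collinear point sets.
* γ = 0 (exactly parallel aligned normals) gives buckle = propeller = 0
  directly; the hinge is undefined there and never evaluated.
* Occupancy-zero atoms are kept but their residues are flagged;
  alternate conformations collapse to the highest-occupancy conformer
  by default, with the residue marked for restraint exclusion.
* Hydrogens are ignored everywhere; hydrogen bonds are heavy-atom
  distances.
* rmsZ of an empty set is reported absent, never 0; jackknife SDs need
  n ≥ 2.
* Tolerances: builder round-trip ≤ 1e-6, rigid-body invariance and
  order-swap antisymmetry ≤ 1e-9 (both hold with ~1e-12 margin in the
  shipped tests).

## Known limitations

* Pairing is restricted to the asymmetric unit as given; pairs across
  crystallographic symmetry copies are not detected.
* Detection thresholds are calibration points, not mined quantities;
  unusually distorted true pairs beyond the 65°/2.5 Å screens are
  rejected rather than scored.
* The worked-example checks against deposited PDB entries require the
  user to supply those coordinate files; the package does not
  redistribute them.
* Standard-base coordinates are transcribed constants; their absolute
  accuracy bounds the absolute (not relative) accuracy of emergent
  hydrogen-bond lengths in synthetic fixtures.
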