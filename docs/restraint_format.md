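# External restraint file format (v1)

`bpval restrain` writes, and `bpval.restraints.read_external_restraints`
parses, a line-oriented text dialect for feeding geometric restraints to a
refinement program as *external restraints*.

## Grammar

```
file      ::= header line*
header    ::= "# bpval external restraints v1" NL
              "# weights: hbond 2, stacking 5" NL
              comment*
comment   ::= "#" text NL
line      ::= dist | plane
dist      ::= "dist"  "first" sel "second" sel
              "value" FLOAT "sigma" FLOAT "weight" FLOAT NL
plane     ::= "plane" "first" sel "second" sel
              "value" FLOAT "sigma" FLOAT "weight" FLOAT NL
sel       ::= "chain" ID "resi" INT "ins" (ICODE | ".")
              "atoms" ATOM ("," ATOM)*
```

* `dist` records reference exactly one atom per selector: a hydrogen-bond
  donor/acceptor heavy-atom pair.  `value`/`sigma` are the mined target
  mean and standard deviation in Å, printed to 3 decimals.
* `plane` records reference the full ring-atom sets of two stacked bases.
  The restraint is a single interplanar-distance term between the two
  least-squares ring planes with target 3.4 Å; an atom-to-plane expansion
  is *not* implied.  (Published descriptions of stacking restraints do not
  pin down the functional form; this is the form this tool defines.)
* `weight` is a per-record scale factor applied by the refinement engine
  on top of `sigma` (hydrogen bonds 2, stacking 5).  Keeping the weight
  separate leaves the mined sigmas inspectable in the file.
* Records are sorted (kind, then selectors) and carry no timestamps, so
  regenerating restraints for an unchanged model is byte-identical.
* A file produced under a closed resolution gate (data at 1.70 Å or
  better) or with `--nonucrest` contains only header comments explaining
  why no records were emitted.
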