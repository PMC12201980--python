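# gipcms

Decision-rule annotation and relative quantification of plant **glycosyl
inositol phospho ceramides (GIPC)** from dual-polarity LC–HRMSⁿ runs.

GIPC are the dominant glycosphingolipids of plant membranes: a ceramide
(sphingoid base + fatty acid) linked through a phosphodiester to
myo-inositol carrying a glycan chain of two (series A) to seven (series F)
saccharides, with series 0 denoting the bare inositol phospho ceramide
(IPC). Because they combine a glycan head with a lipid tail, neither
classical glycomics nor lipidomics workflows resolve them; reversed-phase
LC with multistage fragmentation in both ion polarities does, but the
resulting MS1/MS2/MS3 evidence needs systematic, automated interpretation.
`gipcms` implements that interpretation as a library, for analytical
chemists and plant lipidomics groups working with high-resolution MSⁿ
data.

## What it computes

A candidate species — written in shorthand such as `B-NH-18:0;O3/24:1`
(series B glycan, glucosamine R-group, trihydroxylated 18-carbon sphingoid
base, 24:1 fatty acid) — is annotated only when it meets three criteria:

1. **Fragment evidence.** MS2/MS3 spectra contain characteristic ions for
   both the sugar part and the ceramide part in at least one ion mode.
   Class diagnostics are the inositol phosphate family, m/z 259
   ([IP−H]⁻), 241 ([IP−H₂O−H]⁻) and 261 ([IP+H]⁺); glycan branching at
   the inositol is evidenced by [IP+Hex−H]⁻ at 421 and its water loss at
   403. The ceramide is anchored by Y₀/Z₀ (e.g. Z₀ at 622 for
   18:0;O3/22:0), and the MS3 spectrum of Z₀ yields sphingoid-base (W)
   and fatty-acid (V) chain ions that resolve the *molecular species*
   level; without them the annotation stays at *species* (sum
   composition) level.
2. **Dual-polarity accurate mass.** An MS1 feature within 5 ppm of the
   adduct m/z must exist at the same retention time (±0.1 min) in both
   positive and negative mode.
3. **Retention model.** Within a subclass (series, R-group, total
   hydroxylation), reversed-phase retention is linear in the equivalent
   carbon number, ECN = C − 2·DB; candidates off the fitted line are
   rejected.

Around this core the package provides combinatorial inclusion-list
generation over the series 0–F chain space, in-silico fragment prediction
with Domon–Costello labels (B/C/Y/Z/V/W), mzML reading and XIC
integration, internal-standard + dry-weight normalized relative
quantification with a replicate-agreement rule and row-wise z-scoring,
and a seeded synthetic-run generator (with criteria-violating decoys) so
the whole pipeline is testable end to end without instrument data.

## Worked example

`examples/03_annotate_synthetic_run.py` simulates a dual-polarity run
with ten true B-series species on a linear ECN retention model plus three
decoys, writes it as mzML, reads it back and annotates it:

```
true species recovered: 10/10
decoys accepted: 0 of 3

             name series r_group             level  rt_pos  rt_neg  ppm_pos ...
B-NH-18:0;O3/18:0      B      NH molecular_species 14.6417 14.6417    0.562
B-NH-18:0;O3/20:1      B      NH molecular_species 14.6017 14.6217    0.293
...
rejection log:
  B-NH-35:1;O3           rt= 13.54  c2: feature in one polarity only
  B-NH-36:3;O3           rt= 12.48  c1: characteristic fragments missing
  B-NH-18:0;O3/22:0      rt= 17.96  c3: outside ECN retention model
```

Every accepted record carries both retention times (minutes), the MS1
mass errors in ppm, MS1 peak areas for quantification, and the
branching-evidence flag; each decoy is rejected for exactly the criterion
it was built to violate. The other examples print the inclusion list
(`01`), the predicted fragment tables for the reference compound
`B-NH-18:0;O3/22:0` — IP at 259.0224/261.0370, branching ions at
421.0753/403.0647, Z₀ at 622.6133 (`02`) — and the quantification rules
on the barley growth-stage weights, including the 50% → 0% grain-moisture
trajectory (`04`).

## Layout

```
src/gipcms/
  chem.py       elemental formulas, monoisotopic masses, adducts, ppm math
  model.py      GIPC nomenclature: series, R-groups, ceramides, name parser
  masslist.py   combinatorial target/inclusion-list generation
  fragments.py  in-silico MS2/MS3 fragment prediction (editable chain-ion table)
  spectra.py    mzML reading, spectrum model, XIC extraction
  annotate.py   decision rules, dual-polarity linking, ECN filter, pipeline
  quantify.py   normalization, replicate rule, z-scores, moisture
  simulate.py   seeded synthetic runs with ground truth and decoys; mzML writer
  cli.py        thin `gipcms` command-line front end
```

See `docs/methods.md` for the modelling choices, defaults and known
limitations.
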