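# Methods

This note documents the models, defaults and numerical choices behind
`gipcms`, and what the synthetic validation does and does not establish.

## Mass arithmetic

All masses are monoisotopic, computed from a single hard-coded CODATA/IUPAC
table for C, H, N, O, P (≥ 8 decimals). Charged-species m/z uses the proton
mass 1.007276 Da — i.e. the electron mass is accounted for — because the
annotation operates at 5 ppm, where the electron (0.7 ppm at m/z 780)
is not negligible. Supported ionisation transforms are [M+H]⁺, [M−H]⁻ and
[M−2H]²⁻.

**Nominal m/z** is the integer part (truncation) of the monoisotopic m/z,
matching how diagnostic fragments are conventionally quoted: lipid-derived
ions carry a large positive mass defect (Z₀ of ceramide 18:0;O3/22:0 is
622.6133, quoted as 622), while for low-defect glycan ions truncation and
rounding coincide (259.0224 → 259, 760.1907 → 760).

## Structural model and nomenclature

A GIPC is assembled element-conservingly as

```
ceramide + inositol (C6H12O6) + HPO3 − H2O + Σ glycan residues
```

with anhydro residue compositions Hex C6H10O5, HexA C6H8O6, HexN C6H11NO4,
HexNAc C8H13NO5, Pen C5H8O4. The glycan base sequence per series, proximal
(inositol) to distal, is HexA, then the R-group sugar (OH → Hex, NH → HexN,
NAc → HexNAc), then hexoses, with the series-D fifth residue a pentose;
series E/F append further hexoses. Sugar tags in names (`Hex`, `2Hex-Pen`)
append extra distal residues; the underlying reports are not fully
consistent about residue counts in tagged names, but mass assembly under
this rule is unambiguous and names round-trip through the parser.

Chains: sphingoid base CₙH₂ₙ₊₃₋₂·DB N O_OH, fatty acid CₙH₂ₙ₋₂·DB O₂₊OH,
ceramide = SPB + FA − H₂O. The ceramide's elemental composition depends
only on the totals (C_T H₂T₊₁₋₂DB N O_OH₊₁), so species-level (sum
composition) records have a well-defined formula, and projecting a
molecular species to species level preserves it. `;O` with no digit means
one hydroxyl; no `;O` term means none.

Glycan branching (a hexose attached directly to the inositol, the feature
evidenced by the 421/403 ions) is a boolean flag, not a glycan tree: the
available fragment evidence supports only this binary distinction. It
defaults to set for series B and beyond, unset for 0/A, where branching
was not observed.

## Fragment prediction

Fragments follow Domon–Costello labels. Cleavage sites are numbered from
the ceramide: the phosphodiester gives Y₀ (ceramide) and Z₀ (Y₀ − H₂O);
the k-th glycosidic site gives Yₖ/Zₖ (ceramide side) and the complementary
B/C ions (distal side), satisfying m(B⁺) + m(Y⁺) = m([M+H]⁺) + m(proton)
pair-wise (sign mirrored in negative mode). Head-group ions HGⱼ (inositol
phosphate + j proximal residues; e.g. the C-series ion at nominal 760)
serve as alternative MS3 precursors. The composition-unassigned C-series
branching marker at nominal 535 is matched by a ±0.5 Da window only.

Sphingoid-base (W, with sequential water losses) and fatty-acid (V) ion
compositions are not settled chemistry; they live in an editable CSV
(`data/chain_fragments.csv`: W = dehydrated protonated base; V = a
fatty-acyl vinyl-amide cation) rather than in code, and only ions with
published m/z are pinned by tests. Doubly charged fragments and cross-ring
(A/X) cleavages are not predicted; MS3 pathways are limited to Z₀ → chain
ions and head-group ion → glycan ladder.

## Annotation

* **MS1**: XICs are integrated trapezoidally over contiguous non-zero
  stretches of the ±5 ppm chromatogram; each baseline-separated stretch
  with ≥ 3 points is a feature (apex = max point). No smoothing or
  baseline subtraction by default — inputs are centroided high-resolution
  data; the integration scheme is a documented stand-in for whatever the
  original vendor tools used.
* **Criterion 2**: features are paired across polarities per neutral
  formula by nearest RT within ±0.1 min, ties broken by smaller summed
  ppm error; each feature is used at most once.
* **Criterion 1**: MS2 matching is ppm-based (default 10 ppm, Orbitrap
  detection at 30 000 resolution), MS3 matching absolute (default 0.3 Da,
  ion-trap detection); neither tolerance is published, both are exposed in
  `AnnotateConfig`. A fragment counts when its peak is ≥ 1% of the base
  peak (config). Default decision rules demand at least one
  inositol-phosphate/glycan ion AND at least one ceramide ion, satisfiable
  in different polarities; rules are plain-text editable.
* **Level discipline**: molecular-species level strictly requires MS3
  chain-ion confirmation (≥ 1 W-family and ≥ 1 V-family ion for that chain
  split). Removing MS3 spectra demotes records to species level without
  destroying criterion 1.
* **Isobaric candidates**: inclusion-list rows are deduplicated on
  (formula, adduct) but retain the collapsed chain-split variants, because
  a formula can be shared by different splits and even by different
  series/R-group glycans (B-NAc-34:2;O3 and B-NH-36:3;O4 are elementally
  identical). MS2 evidence is gathered per distinct sum-composition
  projection; when no split is MS3-confirmed, the projection with the most
  matched fragments wins, and unresolved ties are emitted flagged
  `ambiguous` rather than dropped.
* **Criterion 3**: per (series, R-group, total-OH) group — the structural
  drivers of reversed-phase retention — a least-absolute-deviation line
  rt = a + b·ECN is solved exactly as a linear program (deterministic; a
  single outlier fails its own check without dragging the fit). Groups
  with < 4 members or without ECN spread are not fitted; their records
  pass with an explicit `ecn_evaluated=False` marker. Residual tolerance
  defaults to 0.5 min.
* Output is deterministically ordered (series, name, RT); rejected
  candidates are logged with the violated criterion. Cross-replicate
  consolidation keeps species seen in ≥ 2 of 3 replicate runs.

## Quantification

ratio = area / internal-standard area / dry weight (g⁻¹); the internal
standard is C16-lactosyl ceramide (LacCer 18:1;O2/16:0, C46H87NO13,
861.6177 Da). Group means follow the replicate-agreement rule: arithmetic
mean over replicates, forced to 0 when exactly one replicate is non-zero;
missing features count as 0. Z-scores are row-wise with population SD
(the common heatmap-scaling default; sample SD is a switch), applied to
group-mean columns; constant rows are flagged and emitted as zeros rather
than scaled. Moisture = 100·(fresh − dry)/fresh, rounded to the nearest
integer for reporting.

## Synthetic data

The generator emulates the acquisition the annotator expects: Gaussian
MS1 elution profiles (FWHM 0.1 min — plausible for a 30-min reversed-phase
gradient, and chosen so the injected area has the closed form
height·σ·√(2π) for oracle checks) for the [M+H]⁺/[M−H]⁻ precursors of
each species; MS2 at the apex carrying the predicted fragments with class
ions strong and ladder ions weak; positive MS3 of Z₀ with the chain ions;
uniform noise peaks in every spectrum; m/z jitter of 1 ppm (MS1), 2 ppm
(MS2) and 0.05 Da (MS3). Retention times follow one global ECN line
(intercept 2 min, slope 0.35 min per ECN unit, placing the barley-like
chain space in the 13–18 min window) with 0.02 min jitter and a 0.02 min
polarity offset SD (well below a third of the 0.1 min linking tolerance).
The default series mix reproduces the barley inventory proportions
(A-NH 25, A-NAc 13, B-NH 35, B-NAc 12, C-NH 11, D-NH 6).

Decoys each violate exactly one criterion: present in one polarity only,
displaced +2 min off the retention line, or carrying no diagnostic
fragments. Species are drawn deduplicated on *elemental formula*, not just
name — isobaric chain splits co-elute under the ECN model, so a decoy
isobaric with a truth would inherit its MS1 evidence and no longer violate
a single criterion. All randomness comes from one stream keyed by the
seed, drawn in a fixed order, so runs and mzML files are byte-identical
across repeats.

The generator does **not** model isotope envelopes, chemical noise
structure, in-source fragmentation, co-elution of different formulas
within a ppm window, or intensity saturation. Passing the round-trip
properties therefore demonstrates the correctness of the decision logic,
the linking arithmetic and the retention filter — not robustness to real
chromatographic and matrix effects, which must be judged on instrument
data.

## mzML I/O

Reading is an accession-driven XML parser (plain or indexed mzML, 32/64-bit
float arrays, zlib or uncompressed, RT unit conversion to minutes at the
boundary); polarity comes from per-spectrum metadata, never from file
names, so mixed-polarity files and paired single-polarity files both work.
MS3 spectra expose the full ancestor precursor chain. Profile spectra are
centroided by local-maximum picking above a configurable floor. The writer
emits plain mzML 1.1.0 with uncompressed 64-bit float arrays (lossless
round trip).

## Validation scale

The test suite exercises the pipeline on runs of 8–14 species over a
~6 min RT window at a 0.02 min MS1 cycle (a few hundred spectra per
polarity), with the multi-seed recovery property aggregated over 20 seeds;
the full suite completes in a few seconds on one CPU.

## Known limitations

Sugar stereochemistry, anomericity and linkage positions beyond the
branching flag are out of scope (unresolvable by this kind of LC–MS/MS
evidence). No isotope-pattern simulation or scoring; no FDR estimation
(no validated decoy chemistry exists for GIPC); no absolute quantification
(no commercial GIPC standards). Reproducing a full plant-tissue inventory
additionally depends on instrument-specific rule thresholds and raw data
not shipped with this package.
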