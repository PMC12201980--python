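"""Predict the diagnostic fragments of one GIPC in both ion polarities.

The compound is the B-series species whose spectra anchor the method:
nominal 259/241 (inositol phosphate and its water loss) and 421/403
(inositol phosphate + hexose, the glycan-branching evidence) appear in
negative mode, the protonated inositol phosphate at 261 and the ceramide
Y0/Z0 pair in positive mode, and the MS3 spectrum of Z0 carries the
sphingoid-base (W) and fatty-acid (V) chain ions that pin the chain split.
"""

from gipcms.fragments import fragments_table, predict_fragments
from gipcms.model import parse_name

sp = parse_name("B-NH-18:0;O3/22:0")
print(f"{sp.name}: formula {sp.formula}, "
      f"neutral mass {sp.neutral_mass:.4f} Da, ECN {sp.ceramide.ecn}")

for polarity in ("-", "+"):
    frags = predict_fragments(sp, polarity, ms_level=2)
    diag = [f for f in frags if f.diagnostic_class in
            ("inositol_phosphate", "branching", "ceramide")]
    print(f"\nMS2, {polarity} mode (class-diagnostic ions):")
    print(fragments_table(diag).to_string(index=False))

ms3 = predict_fragments(sp, "+", ms_level=3, precursor_label="Z0")
print("\nMS3 of Z0 (chain ions; W = sphingoid base, V = fatty acid):")
print(fragments_table(ms3).to_string(index=False))
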