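"""Build the combinatorial GIPC inclusion list for a barley-like chain space.

The target list enumerates every (series, R-group) x ceramide x adduct
combination, deduplicates isobaric chain splits, and flags entries outside
the MS1 scan range instead of dropping them.  The printed m/z values are
what the instrument would schedule for fragmentation.
"""

from gipcms.masslist import ChainSpace, generate_targets

space = ChainSpace()  # sphingoid base 18C, FA 16-26, total OH capped at 2-4
targets = generate_targets(space)

print(f"{len(targets)} targets "
      f"({sum(t.polarity == '+' for t in targets)} positive, "
      f"{sum(t.polarity == '-' for t in targets)} negative)")
print(f"{sum(not t.in_scan_range for t in targets)} outside the "
      "500-2000 m/z scan range (flagged, not dropped)")
print()
print(f"{'m/z':>10}  {'z':>2}  adduct     name")
for t in targets[:5]:
    print(f"{t.mz:10.4f}  {t.adduct.charge:+2d}  {t.adduct.name:9s}  {t.name}")
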