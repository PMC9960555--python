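"""Formula arithmetic and isotope patterns for screenable ions.

Builds the characteristic in-source fragment of triphenyl phosphate and the
deprotonated 2,4,6-tribromophenol ion, and prints their theoretical m/z and
isotope envelopes.
"""

from maldiscreen import isotope_pattern, parse_formula, parse_species, theoretical_mz

tpp = parse_formula("C18H15O4P")  # triphenyl phosphate
fragment = parse_species("M-C6H5", "negative")  # phenyl loss in the source
print(f"TPhP [{fragment.label}]-  ->  ion {fragment.apply(tpp).hill()}, "
      f"m/z {theoretical_mz(tpp, fragment):.4f}")
# The printed m/z (249.0317) is what a 5 mDa screening window is centred on.

tbp_ion = parse_species("M-H", "negative").apply(parse_formula("C6H3Br3O"))
pattern = isotope_pattern(tbp_ion, resolution=25000)
print(f"\n2,4,6-TBP [M-H]- isotope pattern ({tbp_ion.hill()}, R=25,000):")
for mz, rel in pattern.peaks():
    if rel > 0.01:
        print(f"  m/z {mz:9.4f}   {100 * rel:5.1f} %")
# Three bromines give the ~1:3:3:1 envelope spaced ~2 Da apart; matching this
# shape is what the isotope-fit score quantifies.
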