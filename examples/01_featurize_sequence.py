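"""Validate one expanded target and inspect its 149-feature record.

The 30-mer is 4 nt of upstream context, the 20-nt spacer, the NGG PAM
and 3 nt of downstream context.  Position labels run -4..-1 (upstream),
1..23 (spacer + PAM) and +1..+3 (downstream); there is no position 0.
"""

import crisprboost as cb

seq = "GTCTGCCATCTCTGATGGATGTGATGGGCA"
target = cb.validate_target(seq)
print(f"sequence  : {target.upstream}-{target.spacer}-{target.pam}-{target.downstream}")
print(f"GC content: {cb.gc_content(target):.4f}  (fraction of G/C in the 30-mer)")

n_seg, longest = cb.polyt_features(target)
print(f"poly-T    : {n_seg} segment(s) of >=3 Ts, longest T-run = {longest}")

di = cb.positional_dinucleotides(target)
print(f"di19={di['19']} di18={di['18']} di20={di['20']}  (3'-end dinucleotides, "
      "the strongest positional predictors of cleavage efficiency)")

# thermodynamics: 4 nearest-neighbor melting temperatures over spacer
# sub-regions and 2 RNA-folding minimum free energies
thermo = cb.compute_thermo(target, engine=cb.RNAfoldEngine())
print(f"Tm1..Tm4  : {thermo.Tm1:.2f} {thermo.Tm2:.2f} {thermo.Tm3:.2f} "
      f"{thermo.Tm4:.2f} degC")
print(f"dG        : spacer {thermo.dG_spacer:.2f}, spacer+scaffold "
      f"{thermo.dG_full:.2f} kcal/mol (more negative = more stably folded guide)")

row = cb.featurize(target, thermo)
print(f"feature record width: {len(row)} "
      f"({len(cb.SCHEMA.numeric)} numeric + {len(cb.SCHEMA.categorical)} categorical)")
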