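"""Generate the self-contained synthetic potato-like dataset.

Builds 12 chromosomes carrying a planted 20-member Hsp70-like gene
family at the published coordinates, plus 5 decoy candidates and 30
background genes, and prints what was planted.
"""

import famscan

bundle = famscan.generate(famscan.GeneratorConfig(seed=42))

family = sorted(bundle.truth.family_members, key=lambda s: int(s.split("-")[1]))
print(f"proteome size: {len(bundle.proteins)} proteins")
print(f"planted family: {len(family)} members ({family[0]} .. {family[-1]})")
lengths = [len(bundle.protein(name).sequence) for name in family]
print(f"family protein lengths: {min(lengths)}-{max(lengths)} aa")

decoys = bundle.truth.decoy_kind
print(f"decoys: {sum(1 for k in decoys.values() if k == 'redundant')} redundant, "
      f"{sum(1 for k in decoys.values() if k == 'truncated')} truncated, "
      f"{sum(1 for k in decoys.values() if k == 'background')} background genes")

# The 55 proteins include 25 family-like candidates (20 real + 5 decoys);
# downstream examples show how the filters recover exactly the 20.
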