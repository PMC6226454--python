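"""Call stress/hormone regulation from simulated qRT-PCR CT tables.

dCT = CT_target - CT_reference per biological replicate (technical
replicates averaged first); fold change = 2^-ddCT vs the untreated
control; a gene is up/down when fold >= 2 (or <= 0.5) and a Student's
t-test on replicate dCTs is significant at 0.05.
"""

import famscan
from famscan.qpcr import changed_counts
from famscan.reference import ABIOTIC_TREATMENTS

config = famscan.GeneratorConfig(seed=42)
bundle = famscan.generate(config)
ct = famscan.simulate_ct(bundle, config)

calls = famscan.regulation_calls(ct)
print("genes changed per treatment:")
print(changed_counts(calls).to_string())

up = {}
for c in calls:
    if c.call == "up":
        up.setdefault(c.gene_id, set()).add(c.treatment)
all_four = sorted(g for g, t in up.items() if set(ABIOTIC_TREATMENTS) <= t)
print(f"\nup-regulated under all four abiotic stresses ({len(all_four)}):")
print(", ".join(all_four))

# Five genes respond to every abiotic stress; under the hormone panel
# 6/8/8/4 genes change under IAA/ABA/GA3/SA.
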