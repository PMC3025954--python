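"""Bootstrap: approximate matching of the E. coli seed dif in the seed genus.

Fuzzy matching allows up to 8 substitutions and no indels; per genome
the single best hit becomes initial training material for the profile.
"""

import numpy as np

from difscan import SEED_DIFS, SeedDif, fuzzy_scan
from difscan.genome_io import Chromosome

rng = np.random.default_rng(0)
seed = SeedDif("Escherichia coli", SEED_DIFS["Escherichia coli"])

# a background genome carrying one drifted copy of the seed (3 substitutions)
copy = list(seed.sequence)
for i in (2, 11, 20):
    copy[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[copy[i]]
seq = "".join(rng.choice(list("ACGT"), size=50_000))
seq = seq[:30_000] + "".join(copy) + seq[30_028:]
chrom = Chromosome("demo", "demo", ("P", "C", "Escherichia"), seq)

hits = fuzzy_scan(chrom, seed, max_substitutions=8)
for h in hits[:3]:
    print(f"hit at {h.start} ({h.strand}) with {h.substitutions} substitutions: {h.matched}")
print(f"\n{len(hits)} hit(s) within the 8-substitution budget; the best one")
print("(fewest substitutions) would seed the initial profile.")
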