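"""Per-position conservation of dif motifs: the XerC vs XerD arm contrast.

The conservation quantity at a position is the sample variance of the
four base percentages (2500 when one base carries every sequence, 0 when
all four are equally common), normalized to percent.  Generating a clade
whose XerD-side positions evolve at a quarter of the XerC-arm rate
reproduces the published asymmetry: the XerD arm stays more conserved.
"""

from difscan import CladeSpec, evolve_clade
from difscan.replication_stats import conservation_quantity

spec = CladeSpec(n_genera=8, genomes_per_genus=3, genome_length=10_000,
                 motif_sub_rate=0.08, xerD_arm_rate_factor=0.25, random_seed=5)
_, truth = evolve_clade(spec)
motifs = [t.implant_sequence for t in truth.genomes.values() if t.implanted]

profile = conservation_quantity(motifs, group="synthetic clade")
print("position : conservation (%)")
for j, v in enumerate(profile.values, start=1):
    arm = "XerC arm" if 7 <= j <= 12 else ("XerD arm" if 17 <= j <= 22 else "")
    print(f"{j:>8} : {v:6.1f}  {arm}")

xerc = profile.values[6:12].mean()
xerd = profile.values[16:22].mean()
print(f"\nXerC-arm mean {xerc:.1f}%  vs  XerD-arm mean {xerd:.1f}%")
print("Slower XerD-side evolution leaves its binding arm visibly more")
print("conserved, the same contrast reported for real dif collections.")
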