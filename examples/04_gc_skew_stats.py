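"""Replication-strand statistics: ori/ter calls and the GC skew index.

Generates genomes across a ladder of skew strengths and prints the GCSI
and the error of the ori/ter calls against the programmed positions.
GCSI is calibrated so a perfect square-wave skew scores 1; below 0.05
the skew is considered invisible and ori/ter calls are not trusted.
"""

import numpy as np

from difscan import generate_skewed_genome, skew_report
from difscan.replication_stats import circular_distance

rng = np.random.default_rng(2)
L = 100_000
true_ori = 30_000

print(f"{'skew':>6} {'GCSI':>8} {'visible':>8} {'ori error':>10} {'ter error':>10}")
for strength in (0.0, 0.1, 0.3, 0.6, 1.0):
    chrom = generate_skewed_genome(L, 0.5, strength, ori=true_ori, rng=rng)
    rep = skew_report(chrom)
    ori_err = circular_distance(rep.ori, true_ori, L)
    ter_err = circular_distance(rep.ter, true_ori + L // 2, L)
    print(f"{strength:>6.1f} {rep.gcsi:>8.4f} {str(rep.skew_visible):>8} "
          f"{ori_err:>10} {ter_err:>10}")

print("\nGCSI grows with the programmed skew strength; once the skew is")
print("visible the cumulative-curve extremes localize ori and ter to")
print("within a fraction of a percent of the genome length.")
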