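# Methods

## Model and assumptions

The target is a fixed-length, ungapped 28-bp motif: *dif* sites across
bacteria keep their length and arm architecture, and the bootstrap
explicitly forbids insertions and deletions, so every training set is a
gap-free alignment by construction.  The profile is therefore a
28-match-state position model — per-column emission probabilities with a
shared pseudocount — rather than a profile HMM with insert/delete
states, which would be inert on gap-free training data.  Scoring is
log2-odds against the *scanned chromosome's* mononucleotide frequencies
(strand-symmetrized, so both strands see the same background): an
absolute background would reward base composition rather than motif
match and systematically misbehave in AT-rich genomes.

Statistical significance is exact rather than asymptotic.  The
distribution of the window score under the background is computed by
dynamic programming over per-column scores discretized to a 1/1000-bit
grid; the p-value of a hit is the exact tail mass at its discretized
score and `E = p × 2L` counts both strands of the circular chromosome.
At 28 columns the DP support is small enough that this is cheap, and it
avoids fitting an extreme-value calibration.  Refining the grid 10×
changes p-values by well under 5% (tested); windows containing N are
unscoreable and skipped; zero-emission entries (possible only with
pseudocount 0) score −∞ and their probability mass is absorbed out of
the finite distribution.

## Iteration order and gating

Per-organism distance to the seed is the average of the XerC and XerD
identity distances from global pairwise alignment (BLOSUM62, gap open
10, extend 0.5): `1 − identities / aligned columns`.  A multiple
alignment would change absolute values but only the *ordering* matters
to the algorithm, and pairwise distances are reproducible without an
external aligner; no evolutionary-distance correction is applied for the
same reason.  Groups (genus by default) are visited in ascending order
of their closest member's distance; ties break lexicographically.  The
0.3 protein-distance gap that empirically separates phyla is surfaced as
a warning when a profile is about to be applied across it, not as a hard
failure.

Leave-one-out cross-validation gates every training-set enlargement:
each held-out site must be the top hit on its own chromosome, above both
thresholds, under a profile trained on all the others.  On failure the
offending new additions are evicted from training (first the new sites
that fail their own held-out test; if older sites still fail, the whole
round's additions); evicted sites remain reported as predictions flagged
not-trained-on.  This keeps the profile conservative without discarding
genome-level results.

## Validation rules

* Thresholds: score ≥ 10 bits and E < 1e−4 (configurable).
* Palindrome: ≥ 4 Watson–Crick complementary pairs among positions
  (7,22)…(12,17).  The threshold is *inclusive* at 4 deliberately: the
  experimentally confirmed *B. subtilis* site scores exactly 4, so a
  strict "more than four" rule would reject a published functional site.
* Position: candidates within 10% of the genome length of the GC-skew
  origin are rejected.  No published number quantifies "close to the
  origin"; 10% is chosen to be far outside the observed dispersion of
  real sites around the terminus (about ±1.4% of genome length at 1σ)
  while still excluding the origin region, and it is configurable.
  Chromosomes whose GCSI falls below 0.05 have no trustworthy ori, so
  the position check is skipped for them.
* A candidate failing only the score/E thresholds but passing palindrome
  and position is reported `provisional` (the manual-rescue route);
  failing palindrome or position means `rejected`.

Cross-group prediction accepts a site when at least two foreign profiles
rank the *identical* site (same start and strand) best and it validates,
or when a single profile's best hit reaches full validated status; among
validated candidates the highest bit score wins.

## Replication-strand statistics

Cumulative GC skew assigns +1 to C, −1 to G, 0 to A/T/N and accumulates
at 1-bp resolution.  Before taking extremes the curve is detrended by
subtracting the linear drift `i·(C−G)_total/L`: replichores of unequal
length leave a net trend in the linearized curve, and without detrending
the extreme positions would depend on where the circular sequence is
cut.  Detrending makes ori/ter calls exactly rotation-equivariant (a
property the test suite checks).  Convention: maximum → ori, minimum →
ter, i.e. the forward strand is G-rich (leading) from ori to ter; users
with annotation-based ori calls can override.

GCSI is `sqrt(SA × D)` where SA is the magnitude of the
one-cycle-per-genome Fourier component of the skew series in 4096
windows, normalized by its value for a unit square wave
(`2/sin(π/N)`), and D is half the absolute difference of the aggregate
skew of the two arcs split at (ori, ter).  Both terms are 1 for a
perfect two-replichore square wave and near 0 for i.i.d. sequence, so
the index is self-calibrated to [0, 1].  The published index of the same
name uses unstated normalization constants; this variant is not
numerically identical to it, but reproduces its operational uses — the
0.05 visibility threshold (≥ 95% of i.i.d. 100-kb genomes fall below
it) and monotone growth with skew strength.  The boundary case GCSI
exactly 0.05 counts as visible.

Replichore-relative position maps a coordinate to percent of the
half-genome from the antipode of ori (0% = opposite ori, 100% = at
ori).  Position comparisons exclude chromosomes with GCSI < 0.05 and use
Spearman rank correlation (average ranks on ties); with fewer than three
usable chromosomes, or constant inputs, the correlation is reported NaN.

Per-position conservation of a motif group is the sample variance
(denominator 3) of the four base percentages: 2500 for a monomorphic
position, 0 for a perfectly uniform one — the denominator is fixed by
requiring the worked value 2500 for composition (100, 0, 0, 0).  Values
are normalized to percent of 2500.  For multi-chromosome organisms,
per-strain profiles are averaged before normalization (equivalent
either way, since normalization is linear).

## Synthetic study design

The generator emulates exactly what the method assumes about real data
and records ground truth for everything.

* **Genomes**: i.i.d. bases within each replichore with
  `P(G) − P(C) = skew_strength × GC` on the leading arc, reversed on the
  lagging arc; A/T balanced.  Default 50 kb — far below real chromosomes
  but large enough that the best background window of 2L ≈ 100k scored
  windows sits far below the E-value threshold, which is the regime that
  matters; GC 0.5; skew strength 0.5 (a clearly visible but not extreme
  skew, GCSI ≈ 0.5).
* **Replichore asymmetry**: ter is displaced from the antipode of ori by
  up to ±10% of L per genome.  Real replichores are unequal, and without
  this spread every ter would sit at 0% replichore-relative and the
  dif-vs-ter correlation would be degenerate noise.
* **Implants**: one *dif* per chromosome at ter ± 2% of L (uniform
  jitter, matching the observed ±1σ dispersion of real sites around the
  shift-point), random strand.  Negative-control genomes (optional
  fraction) receive no implant.
* **Divergence**: genera lie on a chain from the root; each branch
  mutates the motif at 0.03 substitutions/site (positions 13–28 slowed
  by the XerD-arm factor 0.5) and the 298-residue proteins at 0.02.
  Branch outcomes that would drop the arm-palindrome count below 4 are
  redrawn: a *dif* whose arms lose complementarity cannot bind the
  recombinases and would be purged by selection, and an unconstrained
  mutation model would manufacture biologically impossible "true" sites
  that the validator rightly rejects.  Protein evolution is i.i.d.
  substitution — enough to make sequence distance track tree distance
  (rank correlation > 0.9), which is all the iteration order uses.

What passing tests on this generator do **not** show: robustness to
repeated elements, mobile DNA and phage pseudo-*dif* sites, to
AT-content extremes, to annotation errors in XerC/XerD, or to indel
variation in real motifs.  The synthetic study validates the machinery,
not the biology of any particular genome.

## Numerical and degenerate-input choices

* Discretization grid 1/1000 bit; integer thresholding by
  `ceil(t/grid − 1e−9)` so grid-exact scores count as passing.
* Ties: best scan hit by lowest start then '+' strand; iteration-order
  ties lexicographic; nearest-genome ties by id.
* All-AT or skew-free chromosomes: ori/ter unstable, flagged via
  `skew_visible`; GCSI 0 when ori = ter.
* Chromosomes shorter than the GCSI window count use one window per
  base.
* Fuzzy matching with multiple best hits at the minimal substitution
  count marks the genome `ambiguous` and keeps it out of training
  rather than resolving silently.
* Determinism: a single integer seed drives the generator; the pipeline
  itself is deterministic, and two runs from the same inputs produce
  byte-identical reports (tested).

## Problem sizes

The standard study is 30 genomes × 50 kb; the test suite and the
reference script run in a few minutes on one CPU.  The pipeline scales
linearly in total genome length (scanning dominates) and has been kept
free of per-genome quadratic steps except the pairwise protein
distances, which are cached.

## Known limitations

* The profile has no insert/delete states, by design; motifs with real
  indels (e.g. the 31-bp single-recombinase variants) are out of scope.
* E-values are per chromosome, not per run; multiply by the number of
  chromosomes for a database-wide expectation.
* The GCSI variant is self-calibrated and not numerically identical to
  the published index (operational behavior validated instead).
* Class-level fallback uses profiles pooled per class rather than a full
  re-run of the recursion inside each class; on data with strong
  within-class structure a full re-run could do better.
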