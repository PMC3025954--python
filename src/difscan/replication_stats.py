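"""Replication-strand statistics: GC skew, ori/ter, GCSI, conservation.

The GC skew (C-G)/(C+G) changes sign at the replication origin and
terminus of a two-replichore circular chromosome, so the cumulative
(C-G) curve at 1-bp resolution has its maximum at the origin and its
minimum at the terminus (the leading strand running ori->ter on the
forward strand is G-rich under this convention).  The GC skew index
(GCSI) quantifies how pronounced the skew is by combining the amplitude
of the one-cycle-per-genome Fourier component of the windowed skew
series with the compositional distance between the two replichores; it
is calibrated so a perfect square-wave skew scores 1, and 0.05 is the
operational visibility threshold below which ori/ter calls are not
trusted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from ._seq import encode
from .genome_io import Chromosome
from .seed_fuzzy import DIF_LENGTH

GCSI_THRESHOLD = 0.05
GCSI_WINDOWS = 4096

#: variance of the position-specific base-percentage vector when one base
#: accounts for all sequences (the maximum): sample variance over the four
#: percentages (100,0,0,0) with denominator 3
MAX_CONSERVATION_VARIANCE = 2500.0


def circular_distance(p: float, q: float, L: float) -> float:
    """Shortest distance between two positions on a circle of size L."""
    d = abs(p - q) % L
    return min(d, L - d)


@dataclass
class SkewReport:
    """Per-chromosome ori/ter/GCSI summary."""

    chromosome: str
    length: int
    ori: int                # 1-based; argmax of cumulative (C-G)
    ter: int                # 1-based; argmin of cumulative (C-G)
    gcsi: float
    skew_visible: bool      # gcsi >= threshold
    cumulative_max: float
    cumulative_min: float


@dataclass
class PositionComparison:
    chromosome: str
    dif_rel: float              # % of replichore from the antipode of ori
    ter_rel: float              # % of replichore from the antipode of ori
    diff_percent_genome: float  # circular dif-ter distance as % of L, in [0, 50]
    gcsi: float


@dataclass
class ConservationProfile:
    group: str
    variances: np.ndarray       # 28 raw variances, squared percentage points
    values: np.ndarray          # 28 percent-normalized values in [0, 100]


def cumulative_skew(chromosome: Chromosome) -> np.ndarray:
    """Cumulative sum of s(C)=+1, s(G)=-1, s(A)=s(T)=s(N)=0 per base.

    Element i-1 holds the sum over the first i bases; the final element is
    count(C) - count(G).
    """
    codes = encode(chromosome.sequence)
    contrib = np.zeros(len(codes))
    contrib[codes == 1] = 1.0      # C
    contrib[codes == 2] = -1.0     # G
    return np.cumsum(contrib)


def find_ori_ter(chromosome: Chromosome) -> tuple[int, int]:
    """(ori, ter) as 1-based positions of the cumulative-skew extremes.

    The cumulative curve is detrended (the linear drift from a nonzero
    total C-G excess is subtracted) before taking the extremes: replichores
    of unequal length leave a net trend in the linearized curve, and
    without detrending the extremes would depend on where the circular
    sequence happens to be cut.  Detrending makes the call exactly
    rotation-equivariant.  Ties break to the smallest coordinate.  For a
    skew-free sequence the result is unstable; check ``skew_visible``
    before trusting it.
    """
    cum = cumulative_skew(chromosome)
    L = len(cum)
    detrended = cum - np.arange(1, L + 1) * (cum[-1] / L)
    ori = int(np.argmax(detrended)) + 1
    ter = int(np.argmin(detrended)) + 1
    return ori, ter


def _windowed_skew(codes: np.ndarray, windows: int) -> np.ndarray:
    """(C-G)/(C+G) in ``windows`` near-equal bins; 0 where no C or G."""
    L = len(codes)
    edges = np.linspace(0, L, windows + 1).astype(int)
    is_c = np.concatenate([[0], np.cumsum(codes == 1)])
    is_g = np.concatenate([[0], np.cumsum(codes == 2)])
    c = is_c[edges[1:]] - is_c[edges[:-1]]
    g = is_g[edges[1:]] - is_g[edges[:-1]]
    denom = c + g
    skew = np.zeros(windows)
    nz = denom > 0
    skew[nz] = (c[nz] - g[nz]) / denom[nz]
    return skew


def gcsi(chromosome: Chromosome, windows: int = GCSI_WINDOWS) -> float:
    """GC skew index: sqrt(spectral amplitude x replichore distance).

    The spectral term is the magnitude of the 1-cycle-per-genome Fourier
    component of the windowed skew series, normalized by its value for a
    unit square wave (2/sin(pi/N)), so a perfect two-replichore skew
    scores 1 and an unskewed sequence scores near 0.  The distance term
    is half the absolute difference of the aggregate skew of the two
    halves split at the cumulative-skew extremes (each aggregate in
    [-1, 1], so the term is in [0, 1]).
    """
    L = len(chromosome)
    if L < windows:
        windows = L
    codes = encode(chromosome.sequence)
    series = _windowed_skew(codes, windows)
    spectrum = np.fft.fft(series)
    sa = abs(spectrum[1]) / (2.0 / np.sin(np.pi / windows)) if windows > 1 else 0.0

    ori, ter = find_ori_ter(chromosome)
    if ori == ter:
        return 0.0
    c_mask = codes == 1
    g_mask = codes == 2
    # leading replichore: ori+1 .. ter on the forward strand (may wrap)
    if ori < ter:
        lead = np.zeros(L, dtype=bool)
        lead[ori:ter] = True
    else:
        lead = np.ones(L, dtype=bool)
        lead[ter:ori] = False

    def seg_skew(mask: np.ndarray) -> float:
        c = int(np.count_nonzero(c_mask & mask))
        g = int(np.count_nonzero(g_mask & mask))
        return (c - g) / (c + g) if c + g else 0.0

    dist = abs(seg_skew(lead) - seg_skew(~lead)) / 2.0
    return float(np.sqrt(sa * dist))


def skew_report(chromosome: Chromosome, windows: int = GCSI_WINDOWS,
                gcsi_threshold: float = GCSI_THRESHOLD) -> SkewReport:
    cum = cumulative_skew(chromosome)
    ori, ter = find_ori_ter(chromosome)
    index = gcsi(chromosome, windows=windows)
    return SkewReport(
        chromosome=chromosome.id, length=len(chromosome), ori=ori, ter=ter,
        gcsi=index, skew_visible=bool(index >= gcsi_threshold),
        cumulative_max=float(cum.max()), cumulative_min=float(cum.min()),
    )


def replichore_relative(position: float, ori: float, L: float) -> float:
    """Position as % of the replichore from the antipode of the origin.

    0% is directly opposite the origin; 100% is at the origin.
    """
    antipode = ((ori - 1) + L / 2.0) % L
    return circular_distance(position - 1, antipode, L) / (L / 2.0) * 100.0


def compare_positions(predictions: Sequence, skews: Sequence[SkewReport],
                      gcsi_threshold: float = GCSI_THRESHOLD
                      ) -> tuple[list[PositionComparison], float, float]:
    """dif vs ter replichore-relative positions and the two Spearman rhos.

    Chromosomes whose GCSI falls below the threshold have no reliable
    ori/ter and are excluded.  Returns (comparisons, rho of dif_rel vs
    ter_rel, rho of gcsi vs dif-ter distance); the correlations are NaN
    when fewer than 3 chromosomes remain.
    """
    by_chrom = {s.chromosome: s for s in skews}
    comparisons: list[PositionComparison] = []
    for pred in predictions:
        skew = by_chrom.get(pred.hit.chromosome)
        if skew is None or skew.gcsi < gcsi_threshold:
            continue
        L = skew.length
        dif_rel = replichore_relative(pred.hit.start, skew.ori, L)
        ter_rel = replichore_relative(skew.ter, skew.ori, L)
        diff = circular_distance(pred.hit.start, skew.ter, L) / L * 100.0
        comparisons.append(PositionComparison(
            chromosome=pred.hit.chromosome, dif_rel=dif_rel, ter_rel=ter_rel,
            diff_percent_genome=diff, gcsi=skew.gcsi))
    if len(comparisons) < 3:
        return comparisons, float("nan"), float("nan")
    def _rho(x: list[float], y: list[float]) -> float:
        if len(set(x)) < 2 or len(set(y)) < 2:
            return float("nan")     # constant input: rank correlation undefined
        return float(stats.spearmanr(x, y).statistic)

    rho_position = _rho([c.dif_rel for c in comparisons],
                        [c.ter_rel for c in comparisons])
    rho_gcsi = _rho([c.gcsi for c in comparisons],
                    [c.diff_percent_genome for c in comparisons])
    return comparisons, rho_position, rho_gcsi


def position_base_percentages(motifs: Sequence[str]) -> np.ndarray:
    """(28, 4) base composition per position as percentages over A,C,G,T."""
    if not motifs:
        raise ValueError("need at least one motif")
    counts = np.zeros((DIF_LENGTH, 4))
    for m in motifs:
        if len(m) != DIF_LENGTH:
            raise ValueError(f"motifs must be {DIF_LENGTH}-mers")
        codes = encode(m.upper())
        if (codes == 4).any():
            raise ValueError("motifs must be over ACGT")
        counts[np.arange(DIF_LENGTH), codes] += 1
    return counts / len(motifs) * 100.0


def position_variance(percentages: Sequence[float]) -> float:
    """Sample variance (denominator 3) of the four base percentages.

    A monomorphic position (100,0,0,0) scores 2500; a perfectly uniform
    one (25,25,25,25) scores 0 — high variance means high conservation.
    """
    p = np.asarray(percentages, dtype=float)
    if p.shape != (4,):
        raise ValueError("expected four base percentages")
    return float(np.sum((p - p.mean()) ** 2) / 3.0)


def conservation_quantity(motifs: Sequence[str], group: str = "") -> ConservationProfile:
    """Per-position conservation of a group of 28-mers.

    The raw quantity at each position is the sample variance of the four
    base percentages; the normalized value is variance / 2500 x 100.
    """
    pct = position_base_percentages(motifs)
    variances = np.array([position_variance(pct[j]) for j in range(DIF_LENGTH)])
    values = variances / MAX_CONSERVATION_VARIANCE * 100.0
    return ConservationProfile(group=group, variances=variances, values=values)


def average_conservation(groups: Sequence[Sequence[str]], group: str = "") -> ConservationProfile:
    """Average of per-strain conservation profiles, then percent-normalized.

    Used for organisms with multiple chromosomes, where the quantity is
    computed per strain and the average used for normalization.
    """
    all_vars = np.array([conservation_quantity(m).variances for m in groups])
    variances = all_vars.mean(axis=0)
    return ConservationProfile(group=group, variances=variances,
                               values=variances / MAX_CONSERVATION_VARIANCE * 100.0)
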