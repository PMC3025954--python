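"""The 28-column dif profile: building, scanning, exact p-values, LOOCV.

The training set is a gap-free fixed-length alignment of 28-mers (the
bootstrap admits substitutions only), so the profile is an ungapped
28-match-state model: per-column emission probabilities with a shared
pseudocount, scored as log2 odds against the scanned chromosome's
mononucleotide background.  Statistical significance comes from an exact
dynamic program over the discretized per-column score distribution rather
than an extreme-value fit, which is tractable and exact at this motif
length.  E-values are per chromosome: E = p x 2L, the number of scored
windows on both strands of the circular sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from ._seq import BASES, encode, decode, revcomp, base_frequencies
from .genome_io import Chromosome
from .seed_fuzzy import DIF_LENGTH

UNIFORM_BACKGROUND = np.full(4, 0.25)

#: hits with E-value above this are not enumerated by ``scan`` (the single
#: best window is always reported regardless)
REPORT_EVALUE_CEILING = 10.0


@dataclass
class MotifProfile:
    """Position-specific emission model over A,C,G,T for the 28-bp dif."""

    emissions: np.ndarray               # (28, 4) rows sum to 1
    background: np.ndarray              # (4,) training-time background
    pseudocount: float
    training_ids: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.emissions = np.asarray(self.emissions, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.emissions.shape != (DIF_LENGTH, 4):
            raise ValueError(f"emissions must be ({DIF_LENGTH}, 4)")
        if not np.allclose(self.emissions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("emission columns must sum to 1")
        if not math.isclose(float(self.background.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("background must sum to 1")

    @property
    def length(self) -> int:
        return DIF_LENGTH

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.emissions.argmax(axis=1))

    # -- serialization: tabular text, exact round-trip ------------------

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#pseudocount\t{self.pseudocount!r}\n")
            fh.write("#background\t" + "\t".join(repr(float(x)) for x in self.background) + "\n")
            for gid, seq in self.training_ids:
                fh.write(f"#training\t{gid}\t{seq}\n")
            fh.write("column\tbase\tprobability\n")
            for j in range(DIF_LENGTH):
                for b, base in enumerate(BASES):
                    fh.write(f"{j + 1}\t{base}\t{float(self.emissions[j, b])!r}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MotifProfile":
        pseudocount = 0.0
        background = UNIFORM_BACKGROUND.copy()
        training: list[tuple[str, str]] = []
        emissions = np.zeros((DIF_LENGTH, 4))
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if parts[0] == "#pseudocount":
                    pseudocount = float(parts[1])
                elif parts[0] == "#background":
                    background = np.array([float(x) for x in parts[1:5]])
                elif parts[0] == "#training":
                    training.append((parts[1], parts[2]))
                elif parts[0] in ("column", ""):
                    continue
                else:
                    j, base, p = int(parts[0]) - 1, parts[1], float(parts[2])
                    emissions[j, BASES.index(base)] = p
        return cls(emissions, background, pseudocount, training)


@dataclass(frozen=True)
class ScanHit:
    chromosome: str
    start: int              # 1-based, leftmost base on the forward strand
    strand: str
    window: str             # 28-mer as read on the hit strand
    bit_score: float
    p_value: float
    e_value: float


def build_profile(training: Sequence[str],
                  background: np.ndarray | None = None,
                  pseudocount: float = 0.5,
                  training_ids: Iterable[tuple[str, str]] | None = None) -> MotifProfile:
    """Profile from aligned 28-mers: (count + pseudocount)/(n + 4*pseudocount).

    Deterministic and independent of training order.
    """
    if not training:
        raise ValueError("training set must be non-empty")
    for seq in training:
        if len(seq) != DIF_LENGTH or set(seq) - set(BASES):
            raise ValueError(f"training sequences must be {DIF_LENGTH}-mers over ACGT: {seq!r}")
    n = len(training)
    counts = np.zeros((DIF_LENGTH, 4))
    for seq in training:
        codes = encode(seq)
        counts[np.arange(DIF_LENGTH), codes] += 1
    emissions = (counts + pseudocount) / (n + 4 * pseudocount)
    bg = UNIFORM_BACKGROUND.copy() if background is None else np.asarray(background, float)
    ids = list(training_ids) if training_ids is not None else [("", s) for s in training]
    return MotifProfile(emissions, bg, pseudocount, ids)


def _score_matrix(profile: MotifProfile, background: np.ndarray) -> np.ndarray:
    """Per-column log2-odds scores, shape (28, 4).

    Zero-emission entries (possible only without a pseudocount) score -inf:
    a window using such a base can never reach a finite threshold.
    """
    bg = np.asarray(background, float)
    with np.errstate(divide="ignore"):
        return np.log2(profile.emissions / bg[None, :])


def score_window(profile: MotifProfile, window: str,
                 background: np.ndarray | None = None) -> float:
    """Sum of per-column log2(emission/background); None if window has N."""
    if len(window) != DIF_LENGTH:
        raise ValueError(f"window must be {DIF_LENGTH} bp")
    codes = encode(window.upper())
    if (codes == 4).any():
        return float("nan")
    S = _score_matrix(profile, profile.background if background is None else background)
    return float(S[np.arange(DIF_LENGTH), codes].sum())


def _score_distribution(S: np.ndarray, background: np.ndarray, grid: float
                        ) -> tuple[np.ndarray, int]:
    """Exact distribution of the grid-discretized window score under the
    background; returns (pmf over integer scores, integer offset of index 0).

    Probability mass of windows hitting a -inf entry (zero emission) is
    absorbed: the returned pmf then sums to less than 1, which is correct
    for survival queries at any finite threshold.
    """
    finite = np.isfinite(S)
    S_int = np.where(finite, np.rint(S / grid), 0).astype(np.int64)
    cur = np.array([1.0])
    cur_lo = 0
    for j in range(S.shape[0]):
        col, ok = S_int[j], finite[j]
        usable = col[ok]
        new_lo = cur_lo + int(usable.min())
        new_hi = cur_lo + len(cur) - 1 + int(usable.max())
        new = np.zeros(new_hi - new_lo + 1)
        for b in range(4):
            if not ok[b]:
                continue
            off = cur_lo + int(col[b]) - new_lo
            new[off:off + len(cur)] += background[b] * cur
        cur, cur_lo = new, new_lo
    return cur, cur_lo


def _survival(pmf: np.ndarray) -> np.ndarray:
    """sf[i] = P(score index >= i), clipped to [0, 1]."""
    return np.minimum(1.0, np.cumsum(pmf[::-1])[::-1])


def _int_threshold(threshold_bits: float, grid: float) -> int:
    # integer score t_int counts iff t_int * grid >= threshold (to fp tolerance)
    return math.ceil(threshold_bits / grid - 1e-9)


def score_pvalue(profile: MotifProfile, threshold: float,
                 background: np.ndarray | None = None,
                 grid: float = 1e-3) -> float:
    """P(window score >= threshold) for a background-distributed window.

    Exact dynamic programming over per-column scores discretized to
    ``grid`` bits; monotone non-increasing in the threshold.
    """
    bg = profile.background if background is None else np.asarray(background, float)
    S = _score_matrix(profile, bg)
    pmf, lo = _score_distribution(S, bg, grid)
    sf = _survival(pmf)
    t = _int_threshold(threshold, grid)
    idx = t - lo
    if idx <= 0:
        return float(sf[0])
    if idx >= len(sf):
        return 0.0
    return float(sf[idx])


def scan(profile: MotifProfile, chromosome: Chromosome,
         report_evalue: float = REPORT_EVALUE_CEILING,
         grid: float = 1e-3) -> list[ScanHit]:
    """Score all 2L windows (both strands, wrap-around) of a chromosome.

    The background is the scanned chromosome's own (strand-symmetrized)
    mononucleotide frequencies, so scores are relative to local base
    composition rather than a fixed model — important in AT-rich genomes
    where an absolute model would reward composition instead of motif.
    Returns the best hit plus every hit with E-value below
    ``report_evalue``, sorted by descending bit score with ties broken by
    lowest start then '+' strand.
    """
    L = len(chromosome)
    if L < DIF_LENGTH:
        raise ValueError(f"chromosome shorter than {DIF_LENGTH} bp")
    codes = encode(chromosome.sequence)
    bg = base_frequencies(codes)
    S = _score_matrix(profile, bg)
    finite = np.isfinite(S)
    S_int = np.where(finite, np.rint(S / grid), 0).astype(np.int64)
    pmf, lo = _score_distribution(S, bg, grid)
    sf = _survival(pmf)

    ext = np.concatenate([codes, codes[:DIF_LENGTH - 1]])
    n_mask = np.zeros(L, dtype=bool)
    has_n = ext == 4
    if has_n.any():
        for j in range(DIF_LENGTH):
            n_mask |= has_n[j:j + L]
    safe = np.where(ext == 4, 0, ext)

    # reverse-complement score matrices score the minus-strand read of a
    # forward-coordinate window directly: column j pairs with forward
    # position 27-j via the complementary base
    S_rc = S[::-1, ::-1]
    S_int_rc = S_int[::-1, ::-1]

    hits: list[ScanHit] = []
    best: ScanHit | None = None
    n_windows = 2 * L
    for strand, Sf, Si in (("+", S, S_int), ("-", S_rc, S_int_rc)):
        scores = np.zeros(L)
        iscores = np.zeros(L, dtype=np.int64)
        for j in range(DIF_LENGTH):
            col = safe[j:j + L]
            scores += Sf[j, :][col]
            iscores += Si[j, :][col]
        scores[n_mask] = -np.inf
        idx_p = np.clip(iscores - lo, 0, len(sf) - 1)
        pvals = np.where(iscores - lo >= len(sf), 0.0,
                         np.where(iscores - lo < 0, 1.0, sf[idx_p]))
        pvals = np.where(np.isfinite(scores), pvals, 1.0)
        evals = pvals * n_windows
        keep = np.nonzero((evals < report_evalue) & ~n_mask)[0]
        for i in keep:
            hits.append(_make_hit(chromosome.id, int(i), strand, ext, scores, pvals, evals))
        # track the global best even if nothing clears the ceiling
        if (~n_mask).any():
            i_best = int(np.argmax(np.where(n_mask, -np.inf, scores)))
            cand = _make_hit(chromosome.id, i_best, strand, ext, scores, pvals, evals)
            if best is None or (cand.bit_score, -cand.start, cand.strand == "+") > \
                    (best.bit_score, -best.start, best.strand == "+"):
                best = cand
    if best is not None and all((h.start, h.strand) != (best.start, best.strand) for h in hits):
        hits.append(best)
    hits.sort(key=lambda h: (-h.bit_score, h.start, 0 if h.strand == "+" else 1))
    return hits


def _make_hit(chrom_id: str, i: int, strand: str, ext: np.ndarray,
              scores: np.ndarray, pvals: np.ndarray, evals: np.ndarray) -> ScanHit:
    window = decode(ext[i:i + DIF_LENGTH])
    if strand == "-":
        window = revcomp(window)
    return ScanHit(chrom_id, i + 1, strand, window,
                   float(scores[i]), float(pvals[i]), float(evals[i]))


@dataclass(frozen=True)
class TrainingSite:
    """A dif sequence in the accumulated training set, with its origin."""

    genome_id: str
    chromosome_id: str
    start: int
    strand: str
    sequence: str


def loocv(training: Sequence[TrainingSite],
          chromosomes: dict[str, Chromosome],
          score_threshold: float = 10.0,
          evalue_threshold: float = 1.0e-4,
          pseudocount: float = 0.5) -> dict[str, bool]:
    """Leave-one-out cross-validation of the accumulated training set.

    Each held-out site must be re-found on its own chromosome — top hit at
    the true location, clearing both thresholds — by a profile trained on
    all the other sites.  The overall set passes only if every site does.
    """
    if len(training) < 2:
        raise ValueError("LOOCV requires at least 2 training sequences")
    results: dict[str, bool] = {}
    for held in training:
        rest = [t.sequence for t in training if t is not held]
        profile = build_profile(rest, pseudocount=pseudocount)
        chrom = chromosomes[held.chromosome_id]
        hits = scan(profile, chrom)
        ok = False
        if hits:
            top = hits[0]
            ok = (top.start == held.start
                  and top.bit_score >= score_threshold
                  and top.e_value < evalue_threshold)
        results[held.genome_id] = ok
    return results
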