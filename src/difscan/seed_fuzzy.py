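"""Approximate (Hamming) matching of seed dif sequences.

The bootstrap stage locates copies of a printed 28-bp seed dif in genomes
of the seed genus by substitution-only matching: up to ``max_substitutions``
mismatches, no insertions or deletions.  Both strands are scanned and
windows wrapping the origin of the circular sequence are included.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seq import encode, revcomp, revcomp_codes, decode
from .genome_io import Chromosome

DIF_LENGTH = 28

#: Experimentally confirmed (E. coli, B. subtilis) and computationally
#: predicted (F. alni) seed dif sequences used to bootstrap each phylum.
SEED_DIFS = {
    "Escherichia coli": "GGTGCGCATAATGTATATTATGTTAAAT",
    "Bacillus subtilis": "ACTTCCTAGAATATATATTATGTAAACT",
    "Frankia alni": "CACGCCGATAATGCACATTATGTCAAGT",
}


@dataclass(frozen=True)
class SeedDif:
    organism: str
    sequence: str
    provenance: str = "experimental"    # or "computational"

    def __post_init__(self) -> None:
        if len(self.sequence) != DIF_LENGTH:
            raise ValueError(f"seed dif must be {DIF_LENGTH} bp, got {len(self.sequence)}")
        if set(self.sequence) - set("ACGT"):
            raise ValueError("seed dif must be over ACGT")


@dataclass(frozen=True)
class FuzzyHit:
    chromosome: str
    start: int          # 1-based, leftmost base on the forward strand
    strand: str
    substitutions: int
    matched: str        # 28-mer as read 5'->3' on the hit strand


def _mismatch_counts(codes: np.ndarray, seed_codes: np.ndarray) -> np.ndarray:
    """Mismatches of every window of the (linearized) code array vs the seed.

    Windows containing N count every N position as a mismatch against a
    sentinel so they can be filtered by the caller via the n_mask.
    """
    n_windows = len(codes) - DIF_LENGTH + 1
    mism = np.zeros(n_windows, dtype=np.int32)
    for j in range(DIF_LENGTH):
        mism += codes[j:j + n_windows] != seed_codes[j]
    return mism


def fuzzy_scan(chromosome: Chromosome, seed: SeedDif,
               max_substitutions: int) -> list[FuzzyHit]:
    """All 28-bp windows within ``max_substitutions`` Hamming distance.

    Returns hits on both strands, including origin-wrapping windows,
    sorted by ascending substitution count then start coordinate then
    strand ('+' first).  Windows containing N are skipped.
    """
    if not 0 <= max_substitutions <= DIF_LENGTH:
        raise ValueError("max_substitutions must be in [0, 28]")
    L = len(chromosome)
    if L < DIF_LENGTH:
        return []
    codes = encode(chromosome.sequence)
    # wrap-around: append the first 27 bases so every circular window exists
    ext = np.concatenate([codes, codes[:DIF_LENGTH - 1]])
    n_mask = np.zeros(L, dtype=bool)
    has_n = ext == 4
    if has_n.any():
        for j in range(DIF_LENGTH):
            n_mask |= has_n[j:j + L]

    hits: list[FuzzyHit] = []
    seed_fwd = encode(seed.sequence)
    seed_rev = revcomp_codes(seed_fwd)
    for strand, seed_codes in (("+", seed_fwd), ("-", seed_rev)):
        mism = _mismatch_counts(ext, seed_codes)[:L]
        ok = np.nonzero((mism <= max_substitutions) & ~n_mask)[0]
        for i in ok:
            window = decode(ext[i:i + DIF_LENGTH])
            matched = window if strand == "+" else revcomp(window)
            hits.append(FuzzyHit(chromosome.id, int(i) + 1, strand,
                                 int(mism[i]), matched))
    hits.sort(key=lambda h: (h.substitutions, h.start, h.strand))
    return hits


def best_unique_hit(hits: list[FuzzyHit]) -> tuple[FuzzyHit | None, bool]:
    """The single best hit, plus an ambiguity flag.

    Ambiguous when two or more hits tie at the minimal substitution count;
    ambiguity is surfaced (the genome is excluded from profile training)
    rather than silently resolved.
    """
    if not hits:
        return None, False
    best = hits[0]
    ambiguous = len(hits) > 1 and hits[1].substitutions == best.substitutions
    return best, ambiguous
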