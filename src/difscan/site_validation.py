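"""Validation of candidate dif sites.

A scored candidate becomes a validated dif prediction only if it clears
the score and E-value thresholds, shows the palindromic complementarity
of the XerC and XerD binding arms (positions 7-12 pairing with 22-17),
and does not sit near the replication origin — a dif displaced to the
origin region is biologically deleterious, and in practice such hits are
spurious.  Candidates that fail only the score/E-value thresholds but
keep the palindrome and position are reported as provisional, mirroring
the manual-rescue route used for weakly scoring genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

from .config import PipelineConfig
from .motif_profile import ScanHit
from .seed_fuzzy import FuzzyHit, DIF_LENGTH
from .replication_stats import SkewReport, circular_distance

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

#: 1-based position pairs checked for Watson-Crick complementarity:
#: the XerC arm positions 7..12 against the XerD arm positions 22..17.
PALINDROME_PAIRS = tuple((i, 29 - i) for i in range(7, 13))


def palindrome_pairs(site: str) -> int:
    """Count of complementary pairs among (7,22)...(12,17), 0-6.

    An N at a checked position counts as non-complementary.  The count is
    invariant under reverse-complementing the 28-mer because the checked
    pairing is its own mirror image.
    """
    if len(site) != DIF_LENGTH:
        raise ValueError(f"site must be {DIF_LENGTH} bp")
    site = site.upper()
    count = 0
    for i, j in PALINDROME_PAIRS:
        a, b = site[i - 1], site[j - 1]
        if _COMPLEMENT.get(a) == b:
            count += 1
    return count


@dataclass
class DifPrediction:
    """A located, scored and validated (or not) candidate dif site."""

    hit: Union[ScanHit, FuzzyHit]
    organism: str = ""
    palindrome_pairs: int = 0
    status: str = "rejected"      # validated | provisional | rejected | ambiguous
    method: str = "profile"       # fuzzy | profile | profile_class_level |
                                  # alternative_seed | cross_group | manual_relaxed
    checks: dict = field(default_factory=dict)

    @property
    def site(self) -> str:
        return self.hit.matched if isinstance(self.hit, FuzzyHit) else self.hit.window

    @property
    def score(self) -> Optional[float]:
        return getattr(self.hit, "bit_score", None)

    @property
    def evalue(self) -> Optional[float]:
        return getattr(self.hit, "e_value", None)


def validate(candidate: ScanHit, skew: SkewReport, config: PipelineConfig,
             method: str = "profile", organism: str = "") -> DifPrediction:
    """Apply the threshold, palindrome and origin-proximity checks.

    validated:   score and E-value clear the thresholds AND the palindrome
                 count is at least ``palindrome_min`` AND the site is not
                 within ``ori_exclusion_fraction`` of the genome length
                 from the replication origin.
    provisional: fails only the score/E-value thresholds.
    rejected:    fails the palindrome or the position check.

    Chromosomes without a visible skew (GCSI below threshold) have no
    reliable ori, so the position check is skipped for them.
    """
    pairs = palindrome_pairs(candidate.window)
    score_ok = candidate.bit_score >= config.score_threshold
    evalue_ok = candidate.e_value < config.evalue_threshold
    palin_ok = pairs >= config.palindrome_min
    if skew.skew_visible:
        dist_to_ori = circular_distance(candidate.start, skew.ori, skew.length)
        position_ok = dist_to_ori >= config.ori_exclusion_fraction * skew.length
    else:
        dist_to_ori = None
        position_ok = True
    checks = {
        "score": score_ok,
        "evalue": evalue_ok,
        "palindrome": palin_ok,
        "position": position_ok,
        "palindrome_pairs": pairs,
        "distance_to_ori": dist_to_ori,
        "position_checked": skew.skew_visible,
    }
    if score_ok and evalue_ok and palin_ok and position_ok:
        status = "validated"
    elif palin_ok and position_ok:
        status = "provisional"
    else:
        status = "rejected"
    return DifPrediction(hit=candidate, organism=organism,
                         palindrome_pairs=pairs, status=status,
                         method=method, checks=checks)
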