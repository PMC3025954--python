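"""XerC/XerD protein distances and the decreasing-similarity iteration order.

The iterated profile refinement walks outward from the seed organism in
decreasing order of XerC/XerD similarity, so that each profile is only
ever asked to generalize one small phylogenetic step.  The per-organism
distance is the average of the XerC and XerD pairwise identity distances;
organisms are grouped by genus (or class) and groups are visited in
ascending order of their closest member's distance to the seed.
"""

from __future__ import annotations

import functools
import warnings
from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from .genome_io import Chromosome


@dataclass(frozen=True)
class DistanceRecord:
    genome_a: str
    genome_b: str
    xerC_distance: float
    xerD_distance: float

    @property
    def average(self) -> float:
        return (self.xerC_distance + self.xerD_distance) / 2.0


@dataclass
class IterationOrder:
    """Ordered genome groups for the recursive profile refinement."""

    seed_genome: str
    groups: list[tuple[str, list[str], float]]   # (label, member ids, distance)
    excluded: list[str] = field(default_factory=list)

    def __iter__(self):
        return iter(self.groups)


@functools.lru_cache(maxsize=1)
def _aligner(gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    aligner.mode = "global"
    return aligner


@functools.lru_cache(maxsize=65536)
def protein_distance(a: str, b: str, gap_open: float = 10.0,
                     gap_extend: float = 0.5) -> float:
    """Identity distance from a global alignment with affine gaps.

    1 - (identical aligned pairs / aligned columns); BLOSUM62 scoring.
    Symmetric, 0 for identical sequences, in [0, 1].
    """
    if not a or not b:
        raise ValueError("protein sequences must be non-empty")
    if a == b:
        return 0.0
    # canonical order so distance(a, b) == distance(b, a) bit-for-bit
    if a > b:
        a, b = b, a
    alignment = _aligner(gap_open, gap_extend).align(a, b)[0]
    counts = alignment.counts()
    columns = counts.gaps + counts.identities + counts.mismatches
    return 1.0 - counts.identities / columns


def organism_proteins(genomes: list[Chromosome]) -> dict[str, dict[str, str]]:
    """Per-organism XerC/XerD protein sequences pooled over chromosomes."""
    out: dict[str, dict[str, str]] = {}
    for chrom in genomes:
        entry = out.setdefault(chrom.organism, {})
        for symbol in ("xerC", "xerD"):
            seq = chrom.protein(symbol)
            if seq and symbol not in entry:
                entry[symbol] = seq
    return out


def xercd_distance(proteins_a: dict[str, str], proteins_b: dict[str, str]) -> float:
    """Average of the XerC and XerD identity distances between organisms."""
    return (protein_distance(proteins_a["xerC"], proteins_b["xerC"])
            + protein_distance(proteins_a["xerD"], proteins_b["xerD"])) / 2.0


def build_iteration_order(genomes: list[Chromosome], seed_organism: str,
                          group_by: str = "genus") -> IterationOrder:
    """Group organisms by taxon and order groups by distance to the seed.

    Group distance is the minimum member distance (closest representative);
    the seed's own group comes first; ties break by lexicographic label.
    Organisms lacking XerC or XerD are excluded with a warning, mirroring
    the restriction of the survey to XerCD-bearing genomes.
    """
    if group_by not in ("genus", "class"):
        raise ValueError("group_by must be 'genus' or 'class'")
    proteins = organism_proteins(genomes)
    taxon = {c.organism: (c.genus if group_by == "genus" else c.klass)
             for c in genomes}
    if seed_organism not in proteins:
        raise ValueError(f"seed organism {seed_organism!r} not among inputs")
    excluded = sorted(org for org, p in proteins.items()
                      if "xerC" not in p or "xerD" not in p)
    if excluded:
        warnings.warn(f"organisms lacking XerC or XerD excluded: {excluded}")
    seed_prot = proteins[seed_organism]
    if "xerC" not in seed_prot or "xerD" not in seed_prot:
        raise ValueError(f"seed organism {seed_organism!r} lacks XerC/XerD")

    dist = {org: xercd_distance(seed_prot, p)
            for org, p in proteins.items() if org not in excluded}
    groups: dict[str, list[str]] = {}
    for org in dist:
        groups.setdefault(taxon[org], []).append(org)
    seed_label = taxon[seed_organism]
    ordered = []
    for label, members in groups.items():
        members.sort(key=lambda o: (dist[o], o))
        ordered.append((label, members, min(dist[o] for o in members)))
    ordered.sort(key=lambda g: (g[0] != seed_label, g[2], g[0]))
    return IterationOrder(seed_genome=seed_organism, groups=ordered,
                          excluded=excluded)


def nearest_training_genomes(target_proteins: dict[str, str],
                             trained: dict[str, dict[str, str]],
                             k: int = 3) -> list[str]:
    """The k trained organisms with the smallest average XerCD distance.

    Deterministic tie-break by id; returns all (with a warning) when fewer
    than k are available.
    """
    ranked = sorted(trained, key=lambda org: (xercd_distance(target_proteins,
                                                             trained[org]), org))
    if len(ranked) < k:
        warnings.warn(f"only {len(ranked)} trained genomes available; requested {k}")
        return ranked
    return ranked[:k]


def distance_table(genomes: list[Chromosome]) -> list[DistanceRecord]:
    """Full pairwise XerC/XerD distance records (optional TSV dump input)."""
    proteins = organism_proteins(genomes)
    orgs = sorted(o for o, p in proteins.items() if "xerC" in p and "xerD" in p)
    records = []
    for i, a in enumerate(orgs):
        for b in orgs[i + 1:]:
            records.append(DistanceRecord(
                a, b,
                protein_distance(proteins[a]["xerC"], proteins[b]["xerC"]),
                protein_distance(proteins[a]["xerD"], proteins[b]["xerD"])))
    return records
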