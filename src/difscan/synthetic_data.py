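"""Ground-truthed synthetic study inputs for end-to-end testing.

Generates what the prediction method assumes about real data: circular
genomes with a two-replichore GC skew of tunable strength, exactly one
dif site implanted near the skew terminus of each chromosome, and a
balanced clade over genera in which both the dif 28-mer and the XerC/XerD
proteins accumulate substitutions with phylogenetic distance — so iterated
profile refinement in decreasing-similarity order has structure to
exploit, and every implant position, strand and branch length is recorded
for recovery scoring.

Protein evolution is deliberately simple (i.i.d. substitutions on a
fixed-length recombinase-like sequence): only the monotone relationship
between tree distance and sequence distance matters to the method under
test, not biological realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._seq import BASES, revcomp
from .genome_io import Chromosome, GeneAnnotation
from .seed_fuzzy import DIF_LENGTH, SEED_DIFS

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PROTEIN_LENGTH = 298        # typical tyrosine-recombinase length

#: positions 13-28 (1-based) cover the central region boundary and the
#: XerD arm; the arm-rate multiplier applies here
XERD_SIDE = slice(12, DIF_LENGTH)


@dataclass
class CladeSpec:
    """Parameters of one synthetic phylum-level study.

    Defaults define the standard study used throughout the test suite:
    30 genomes in 6 genera with a pronounced skew and a motif divergence
    (0.03 substitutions/site/branch) low enough that homologs stay
    recognizable yet high enough that distant genera are out of reach of
    plain fuzzy matching — the regime the iterated strategy is for.
    """

    n_genera: int = 6
    genomes_per_genus: int = 5
    genome_length: int = 50_000
    gc_content: float = 0.5
    skew_strength: float = 0.5
    motif_sub_rate: float = 0.03
    protein_sub_rate: float = 0.02
    xerD_arm_rate_factor: float = 0.5
    implant_jitter: float = 0.02        # fraction of L around ter
    ter_offset_fraction: float = 0.10   # max |ter - antipode(ori)| as fraction of L
    negative_fraction: float = 0.0      # genomes left without an implant
    root_dif: str = SEED_DIFS["Escherichia coli"]
    phylum: str = "Synthphyla"
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length < 10_000:
            raise ValueError("genome_length must be at least 10,000")
        for name in ("motif_sub_rate", "protein_sub_rate", "skew_strength",
                     "gc_content", "xerD_arm_rate_factor", "negative_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if len(self.root_dif) != DIF_LENGTH:
            raise ValueError(f"root_dif must be {DIF_LENGTH} bp")


@dataclass
class GenomeTruth:
    """Ground truth for one synthetic chromosome."""

    genome_id: str
    organism: str
    genus: str
    implanted: bool
    implant_start: int          # 1-based; 0 when not implanted
    implant_strand: str
    implant_sequence: str
    ori: int
    ter: int
    tree_depth: float           # root-to-leaf branch length sum


@dataclass
class SyntheticTruth:
    spec: CladeSpec
    genomes: dict[str, GenomeTruth] = field(default_factory=dict)

    def implanted_ids(self) -> list[str]:
        return [g for g, t in self.genomes.items() if t.implanted]

    def negative_ids(self) -> list[str]:
        return [g for g, t in self.genomes.items() if not t.implanted]


def generate_skewed_genome(length: int, gc: float, skew_strength: float,
                           ori: int, rng: np.random.Generator,
                           ter: int | None = None,
                           chrom_id: str = "synthetic",
                           organism: str = "synthetic",
                           taxonomy: tuple[str, str, str] = ("", "", "")) -> Chromosome:
    """Circular genome with a two-replichore skew from ``ori`` to ``ter``.

    Bases are i.i.d. within each replichore.  On the leading replichore
    (from ori forward to ter) P(G) - P(C) = skew_strength x gc, with the
    sign reversed on the lagging replichore; A and T are balanced.  When
    ``ter`` is omitted it defaults to the antipode of ori; real
    chromosomes have unequal replichores, so study generation displaces
    ter from the antipode.
    """
    if not 0.0 <= skew_strength <= 1.0 or not 0.0 < gc < 1.0:
        raise ValueError("skew parameters imply invalid probabilities")
    at = 1.0 - gc
    g_lead, c_lead = gc * (1 + skew_strength) / 2, gc * (1 - skew_strength) / 2
    p_lead = [at / 2, c_lead, g_lead, at / 2]       # A, C, G, T
    p_lag = [at / 2, g_lead, c_lead, at / 2]
    o0 = (ori - 1) % length
    t0 = ((ter - 1) % length) if ter is not None else (o0 + length // 2) % length
    lead_len = (t0 - o0) % length
    if lead_len == 0:
        raise ValueError("ori and ter must differ")
    lead_codes = rng.choice(4, size=lead_len, p=p_lead)
    lag_codes = rng.choice(4, size=length - lead_len, p=p_lag)
    codes = np.empty(length, dtype=np.int64)
    idx_lead = (o0 + np.arange(lead_len)) % length
    idx_lag = (t0 + np.arange(length - lead_len)) % length
    codes[idx_lead] = lead_codes
    codes[idx_lag] = lag_codes
    seq = "".join(BASES[c] for c in codes)
    return Chromosome(id=chrom_id, organism=organism, taxonomy=taxonomy,
                      sequence=seq)


def mutate_motif(motif: str, rate: float, arm_factor: float,
                 rng: np.random.Generator) -> str:
    """One branch of dif evolution: per-site substitutions, XerD side slowed.

    Substitution draws are conditioned on the site staying functional: a
    dif variant whose XerC/XerD arms lose Watson-Crick complementarity
    cannot bind the recombinases and would be purged by selection, so
    branch outcomes that drop the palindrome-pair count below 4 (or below
    the parent's count when the parent is already under 4) are redrawn.
    """
    from .site_validation import palindrome_pairs
    floor = min(4, palindrome_pairs(motif))
    child = motif
    for _ in range(100):
        out = list(motif)
        for i in range(DIF_LENGTH):
            r = rate * arm_factor if XERD_SIDE.start <= i < XERD_SIDE.stop else rate
            if rng.random() < r:
                out[i] = rng.choice([b for b in BASES if b != out[i]])
        child = "".join(out)
        if palindrome_pairs(child) >= floor:
            return child
    return motif


def mutate_protein(protein: str, rate: float, rng: np.random.Generator) -> str:
    out = list(protein)
    hits = np.nonzero(rng.random(len(out)) < rate)[0]
    for i in hits:
        out[i] = rng.choice([a for a in AMINO_ACIDS if a != out[i]])
    return "".join(out)


def random_protein(rng: np.random.Generator, length: int = PROTEIN_LENGTH) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def evolve_clade(spec: CladeSpec) -> tuple[list[Chromosome], SyntheticTruth]:
    """Simulate the clade and return chromosomes plus ground truth.

    Genera lie on a chain from the root: the root carries ``root_dif`` and
    one random XerC and XerD, genus g is one mutational branch beyond
    genus g-1, and each leaf within a genus hangs one further branch off
    its genus ancestor.  Divergence from the seed genus therefore grows
    monotonically along the genus index — the gradient the
    decreasing-similarity iteration order is designed to exploit.  Each leaf genome gets a fresh skewed
    chromosome with the (possibly mutated) dif implanted at ter plus
    jitter, except for designated negative controls.  Deterministic for a
    fixed ``random_seed``.
    """
    rng = np.random.default_rng(spec.random_seed)
    expected_identity = (1 - spec.motif_sub_rate) ** spec.n_genera
    if expected_identity < 0.5:
        import warnings
        warnings.warn("motif substitution rate so high that expected leaf "
                      "identity to the root dif is below 50%; the method's "
                      "assumptions are violated")
    root_xerC = random_protein(rng)
    root_xerD = random_protein(rng)

    chroms: list[Chromosome] = []
    truth = SyntheticTruth(spec=spec)
    n_total = spec.n_genera * spec.genomes_per_genus
    n_negative = int(round(spec.negative_fraction * n_total))
    # deterministic spread of negatives across the tail genera
    negative_ids = set()
    if n_negative:
        all_ids = [f"g{gi:02d}s{si:02d}" for gi in range(spec.n_genera)
                   for si in range(spec.genomes_per_genus)]
        negative_ids = set(rng.choice(all_ids, size=n_negative, replace=False))

    genus_dif, genus_xerC, genus_xerD = spec.root_dif, root_xerC, root_xerD
    for gi in range(spec.n_genera):
        genus = f"Genus{chr(ord('A') + gi)}"
        if gi > 0:
            genus_dif = mutate_motif(genus_dif, spec.motif_sub_rate,
                                     spec.xerD_arm_rate_factor, rng)
            genus_xerC = mutate_protein(genus_xerC, spec.protein_sub_rate, rng)
            genus_xerD = mutate_protein(genus_xerD, spec.protein_sub_rate, rng)
        for si in range(spec.genomes_per_genus):
            gid = f"g{gi:02d}s{si:02d}"
            organism = f"{genus} strain{si:02d}"
            leaf_dif = mutate_motif(genus_dif, spec.motif_sub_rate,
                                    spec.xerD_arm_rate_factor, rng)
            leaf_xerC = mutate_protein(genus_xerC, spec.protein_sub_rate, rng)
            leaf_xerD = mutate_protein(genus_xerD, spec.protein_sub_rate, rng)
            L = spec.genome_length
            ori = int(rng.integers(1, L + 1))
            offset = int(rng.integers(-int(spec.ter_offset_fraction * L),
                                      int(spec.ter_offset_fraction * L) + 1))
            ter = (ori - 1 + L // 2 + offset) % L + 1
            chrom = generate_skewed_genome(
                L, spec.gc_content, spec.skew_strength, ori, rng, ter=ter,
                chrom_id=gid, organism=organism,
                taxonomy=(spec.phylum, spec.phylum, genus))
            implanted = gid not in negative_ids
            start, strand, implant = 0, "+", ""
            if implanted:
                jitter = int(rng.integers(-int(spec.implant_jitter * L),
                                          int(spec.implant_jitter * L) + 1))
                start = (ter - 1 + jitter) % L + 1
                strand = "+" if rng.random() < 0.5 else "-"
                implant = leaf_dif
                placed = implant if strand == "+" else revcomp(implant)
                seq = list(chrom.sequence)
                for k in range(DIF_LENGTH):
                    seq[(start - 1 + k) % L] = placed[k]
                chrom.sequence = "".join(seq)
            chrom.annotations = [
                GeneAnnotation("xerC", 1, 1, "+", protein=leaf_xerC),
                GeneAnnotation("xerD", 1, 1, "+", protein=leaf_xerD),
            ]
            chroms.append(chrom)
            truth.genomes[gid] = GenomeTruth(
                genome_id=gid, organism=organism, genus=genus,
                implanted=implanted, implant_start=start,
                implant_strand=strand, implant_sequence=implant,
                ori=ori, ter=ter, tree_depth=float(gi + 1))
    return chroms, truth


def make_study(spec: CladeSpec, out_dir: str | Path,
               overwrite: bool = False) -> Path:
    """Write a study bundle loadable through genome_io without special-casing.

    Layout: genomes/<id>.fasta, annotations.tsv, seeds.fasta, truth.tsv,
    config.yaml.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(f"{out_dir} exists and is not empty; pass overwrite=True")
    (out_dir / "genomes").mkdir(parents=True, exist_ok=True)
    chroms, truth = evolve_clade(spec)

    for chrom in chroms:
        with open(out_dir / "genomes" / f"{chrom.id}.fasta", "w") as fh:
            fh.write(f">{chrom.id}\n")
            for i in range(0, len(chrom.sequence), 70):
                fh.write(chrom.sequence[i:i + 70] + "\n")

    rows = []
    for chrom in chroms:
        rows.append({
            "chromosome": chrom.id, "organism": chrom.organism,
            "phylum": chrom.phylum, "class": chrom.klass, "genus": chrom.genus,
            "xerC_protein": chrom.protein("xerC"),
            "xerD_protein": chrom.protein("xerD"),
        })
    pd.DataFrame(rows).to_csv(out_dir / "annotations.tsv", sep="\t", index=False)

    with open(out_dir / "seeds.fasta", "w") as fh:
        fh.write(f">seed {chroms[0].organism}\n{spec.root_dif}\n")

    pd.DataFrame([asdict(t) for t in truth.genomes.values()]).to_csv(
        out_dir / "truth.tsv", sep="\t", index=False)

    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(spec), fh, sort_keys=True)
    return out_dir
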