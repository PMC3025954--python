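"""Reading genomes and annotations; writing prediction and statistics reports.

Coordinates are 1-based inclusive internally (the GenBank convention);
the BED writer converts to half-open 0-based at the boundary and nowhere
else.  Taxonomy (phylum / class / genus) that is not present in the source
file comes from a sidecar annotation table, because the phylum- and
genus-level grouping that drives the iteration order cannot be inferred
from sequence alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, TYPE_CHECKING

import pandas as pd
from Bio import SeqIO

from ._seq import encode

if TYPE_CHECKING:  # pragma: no cover
    from .site_validation import DifPrediction
    from .replication_stats import SkewReport


class FormatError(ValueError):
    """Unparseable or invalid input file."""


class ConsistencyError(ValueError):
    """Cross-references between inputs do not line up."""


@dataclass
class GeneAnnotation:
    """A gene of interest (xerC / xerD / ftsK) on a chromosome.

    ``start > end`` is permitted only for features spanning the origin of a
    circular sequence.
    """

    symbol: str                 # xerC, xerD, ftsK or other
    start: int                  # 1-based inclusive
    end: int                    # 1-based inclusive
    strand: str                 # '+' or '-'
    protein: Optional[str] = None


@dataclass
class Chromosome:
    """A circular bacterial chromosome with taxonomy and annotations."""

    id: str
    organism: str
    taxonomy: tuple[str, str, str]      # (phylum, class, genus)
    sequence: str
    circular: bool = True
    annotations: list[GeneAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        encode(self.sequence)  # validates the alphabet
        if not self.circular:
            raise FormatError(f"{self.id}: linear sequences are not supported; "
                              "the pipeline operates on circular chromosomes")
        for ann in self.annotations:
            if not (1 <= ann.start <= len(self.sequence) and 1 <= ann.end <= len(self.sequence)):
                raise FormatError(f"{self.id}: annotation {ann.symbol} out of range")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def phylum(self) -> str:
        return self.taxonomy[0]

    @property
    def klass(self) -> str:
        return self.taxonomy[1]

    @property
    def genus(self) -> str:
        return self.taxonomy[2]

    def protein(self, symbol: str) -> Optional[str]:
        for ann in self.annotations:
            if ann.symbol == symbol and ann.protein:
                return ann.protein
        return None


_GENE_SYMBOLS = ("xerc", "xerd", "ftsk")


def _sniff_format(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return "genbank" if line.startswith("LOCUS") else "fasta"
    raise FormatError(f"{path}: empty file")


def _annotations_from_genbank(record) -> list[GeneAnnotation]:
    out = []
    for feat in record.features:
        if feat.type != "CDS":
            continue
        names = [str(v).lower() for key in ("gene", "product")
                 for v in feat.qualifiers.get(key, [])]
        symbol = next((s for s in _GENE_SYMBOLS if any(s in n for n in names)), None)
        if symbol is None:
            continue
        protein = feat.qualifiers.get("translation", [None])[0]
        out.append(GeneAnnotation(
            symbol={"xerc": "xerC", "xerd": "xerD", "ftsk": "ftsK"}[symbol],
            start=int(feat.location.start) + 1,
            end=int(feat.location.end),
            strand="+" if feat.location.strand != -1 else "-",
            protein=protein,
        ))
    return out


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    """Sidecar TSV with one row per chromosome.

    Required columns: chromosome, organism, phylum, class, genus.
    Optional: xerC_protein, xerD_protein.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"chromosome", "organism", "phylum", "class", "genus"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: annotation table missing columns {sorted(missing)}")
    return df.set_index("chromosome", drop=False)


def read_genomes(paths: Iterable[str | Path],
                 annotation_table: str | Path | None = None) -> list[Chromosome]:
    """Read FASTA or GenBank chromosomes, merging sidecar annotations.

    GenBank CDS features named xerC/xerD/ftsK populate ``annotations``;
    the sidecar table supplies taxonomy and protein sequences when the
    source file lacks them.  Lowercase bases are uppercased; ambiguity
    codes other than N are rejected; duplicate ids are a conflict.
    """
    table = read_annotation_table(annotation_table) if annotation_table is not None else None
    chroms: list[Chromosome] = []
    seen: set[str] = set()
    for path in paths:
        path = Path(path)
        fmt = _sniff_format(path)
        try:
            records = list(SeqIO.parse(str(path), fmt))
        except Exception as exc:
            raise FormatError(f"{path}: cannot parse as {fmt}: {exc}") from exc
        if not records:
            raise FormatError(f"{path}: no sequence records")
        for record in records:
            if record.id in seen:
                raise ConsistencyError(f"duplicate chromosome id {record.id!r} in {path}")
            seen.add(record.id)
            circular = True
            organism = record.annotations.get("organism", record.id) if fmt == "genbank" else record.id
            if fmt == "genbank":
                topo = record.annotations.get("topology", "circular")
                circular = topo != "linear"
            annotations = _annotations_from_genbank(record) if fmt == "genbank" else []
            taxonomy = ("", "", "")
            if table is not None and record.id in table.index:
                row = table.loc[record.id]
                taxonomy = (row["phylum"], row["class"], row["genus"])
                organism = row["organism"] or organism
                for sym, col in (("xerC", "xerC_protein"), ("xerD", "xerD_protein")):
                    seq = row.get(col, "")
                    if seq and not any(a.symbol == sym and a.protein for a in annotations):
                        annotations.append(GeneAnnotation(sym, 1, 1, "+", protein=seq))
            chroms.append(Chromosome(
                id=record.id, organism=organism, taxonomy=taxonomy,
                sequence=str(record.seq), circular=circular,
                annotations=annotations,
            ))
    return chroms


REPORT_COLUMNS = [
    "organism", "chromosome", "dif_start", "strand", "sequence", "score",
    "evalue", "palindrome_pairs", "status", "method", "ori", "ter", "gcsi",
    "replichore_relative_pct",
]


def predictions_table(predictions: "list[DifPrediction]",
                      skews: "list[SkewReport]") -> pd.DataFrame:
    from .replication_stats import replichore_relative  # local to avoid cycle

    by_chrom = {s.chromosome: s for s in skews}
    rows = []
    for pred in predictions:
        skew = by_chrom.get(pred.hit.chromosome)
        rel = ""
        if skew is not None and skew.skew_visible:
            rel = f"{replichore_relative(pred.hit.start, skew.ori, skew.length):.3f}"
        rows.append({
            "organism": pred.organism,
            "chromosome": pred.hit.chromosome,
            "dif_start": str(pred.hit.start),
            "strand": pred.hit.strand,
            "sequence": pred.site,
            "score": f"{pred.score:.4f}" if pred.score is not None else "",
            "evalue": f"{pred.evalue:.6e}" if pred.evalue is not None else "",
            "palindrome_pairs": str(pred.palindrome_pairs),
            "status": pred.status,
            "method": pred.method,
            "ori": str(skew.ori) if skew else "",
            "ter": str(skew.ter) if skew else "",
            "gcsi": f"{skew.gcsi:.6f}" if skew else "",
            "replichore_relative_pct": rel,
        })
    return pd.DataFrame(rows, columns=REPORT_COLUMNS, dtype=str)


def write_report(predictions: "list[DifPrediction]",
                 skews: "list[SkewReport]",
                 out_dir: str | Path,
                 run_summary: dict | None = None) -> dict[str, Path]:
    """Write the TSV / GFF3 / BED / JSON report bundle.

    BED is half-open 0-based; GFF3 is 1-based inclusive: both describe the
    identical 28-bp interval.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    known = {s.chromosome for s in skews} | {p.hit.chromosome for p in predictions}
    for pred in predictions:
        if skews and pred.hit.chromosome not in {s.chromosome for s in skews}:
            raise ConsistencyError(f"prediction references unknown chromosome "
                                   f"{pred.hit.chromosome!r}")

    tsv = out_dir / "predictions.tsv"
    predictions_table(predictions, skews).to_csv(tsv, sep="\t", index=False)

    bed = out_dir / "predictions.bed"
    gff = out_dir / "predictions.gff3"
    with open(bed, "w") as bfh, open(gff, "w") as gfh:
        gfh.write("##gff-version 3\n")
        for i, pred in enumerate(predictions):
            start, end = pred.hit.start, pred.hit.start + 27
            name = f"dif_{pred.hit.chromosome}"
            score = f"{pred.score:.2f}" if pred.score is not None else "0"
            bfh.write(f"{pred.hit.chromosome}\t{start - 1}\t{end}\t{name}\t{score}\t{pred.hit.strand}\n")
            gfh.write(f"{pred.hit.chromosome}\tdifscan\trecombination_feature\t{start}\t{end}\t"
                      f"{score}\t{pred.hit.strand}\t.\tID=dif{i};Name={name};status={pred.status}\n")

    skew_tsv = out_dir / "skew.tsv"
    pd.DataFrame([{
        "chromosome": s.chromosome, "length": str(s.length), "ori": str(s.ori),
        "ter": str(s.ter), "gcsi": f"{s.gcsi:.6f}",
        "skew_visible": str(s.skew_visible),
    } for s in skews], columns=["chromosome", "length", "ori", "ter", "gcsi", "skew_visible"],
        dtype=str).to_csv(skew_tsv, sep="\t", index=False)

    summary = dict(run_summary or {})
    summary.update({
        "n_predictions": len(predictions),
        "n_chromosomes": len(known),
        "status_counts": {
            status: sum(1 for p in predictions if p.status == status)
            for status in sorted({p.status for p in predictions})
        },
    })
    summary_path = out_dir / "run_summary.json"
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {"tsv": tsv, "bed": bed, "gff3": gff, "skew": skew_tsv, "summary": summary_path}


def read_report_tsv(path: str | Path) -> pd.DataFrame:
    """Re-read a predictions TSV exactly as written (all columns as text)."""
    return pd.read_csv(path, sep="\t", dtype=str).fillna("")
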