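"""Readers and writers for the formats the pipeline touches.

FASTA via Biopython, trees via scikit-bio Newick support, tabular tracks
(BED6, variant TSV) via pandas. GFF3 gene models use a dedicated
reader/writer restricted to the feature types the pipeline consumes
(gene/mRNA/exon/CDS/five_prime_UTR/three_prime_UTR). GFF3 and variant
positions are 1-based on disk and converted to the package-wide 0-based
half-open convention on read. All readers tolerate gzip.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import TreeNode

from .intervals import GenomicInterval, merge_intervals

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "alt_freq", "outgroup_allele"]


def xopen(path: str | Path, mode: str = "rt") -> IO:
    """Open a possibly gzip-compressed text file."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into {name: sequence}, preserving case (soft masking)."""
    with xopen(path) as fh:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# Gene models


@dataclass
class GeneModel:
    """One transcript: strand-aware exon/CDS/UTR structure.

    ``exons`` are sorted, non-overlapping genomic intervals; ``cds`` and the
    UTR lists are subsets of the exon footprint. The TSS is the transcript
    5' end respecting strand.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval]
    cds: list[GenomicInterval]
    utr5: list[GenomicInterval] = field(default_factory=list)
    utr3: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("gene strand must be + or -")
        self.exons = sorted(self.exons, key=lambda iv: iv.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping exons in {self.transcript_id}")
        self.cds = sorted(self.cds, key=lambda iv: iv.start)

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand,
                               self.gene_id)

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    def promoter(self, upstream_bp: int = 1000) -> GenomicInterval | None:
        """Region within ``upstream_bp`` upstream of the TSS on the gene strand."""
        if self.strand == "+":
            s, e = self.start - upstream_bp, self.start
        else:
            s, e = self.end, self.end + upstream_bp
        s = max(0, s)
        if s >= e:
            return None
        return GenomicInterval(self.chrom, s, e, self.strand, self.gene_id)

    def introns(self) -> list[GenomicInterval]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end < b.start:
                out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand,
                                           self.gene_id))
        return out


_GFF_TYPES = {
    "exon": "exons",
    "CDS": "cds",
    "five_prime_UTR": "utr5",
    "three_prime_UTR": "utr3",
}


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.transcript_id};gene_id={g.gene_id}"
            fh.write(
                f"{g.chrom}\tcnsevo\tmRNA\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            for gff_type, attr in _GFF_TYPES.items():
                for iv in getattr(g, attr):
                    fh.write(
                        f"{g.chrom}\tcnsevo\t{gff_type}\t{iv.start + 1}\t{iv.end}"
                        f"\t.\t{g.strand}\t.\tParent={g.transcript_id}\n"
                    )


def _parse_gff_attrs(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read the transcript features this pipeline consumes from GFF3."""
    transcripts: dict[str, dict] = {}
    children: list[tuple[str, str, GenomicInterval]] = []
    with xopen(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                continue
            chrom, _, ftype, start, end, _, strand, _, attr_text = f[:9]
            attrs = _parse_gff_attrs(attr_text)
            iv = GenomicInterval(chrom, int(start) - 1, int(end), strand)
            if ftype in ("mRNA", "transcript"):
                tid = attrs["ID"]
                transcripts[tid] = {
                    "gene_id": attrs.get("gene_id", attrs.get("Parent", tid)),
                    "chrom": chrom,
                    "strand": strand,
                    "exons": [], "cds": [], "utr5": [], "utr3": [],
                }
            elif ftype in _GFF_TYPES:
                children.append((attrs.get("Parent", ""), _GFF_TYPES[ftype], iv))
    for parent, attr, iv in children:
        if parent in transcripts:
            transcripts[parent][attr].append(iv)
    return [
        GeneModel(
            gene_id=t["gene_id"], transcript_id=tid, chrom=t["chrom"],
            strand=t["strand"], exons=t["exons"], cds=t["cds"],
            utr5=t["utr5"], utr3=t["utr3"],
        )
        for tid, t in transcripts.items()
    ]


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path) -> list[GenomicInterval]:
    out = []
    with xopen(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            name = f[3] if len(f) > 3 else ""
            strand = f[5] if len(f) > 5 else "."
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand, name))
    return out


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# Variant table (TSV; positions 1-based on disk)


def read_variants(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(xopen(path), sep="\t")
    missing = set(VARIANT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")
    df = df.copy()
    df["pos0"] = df["pos"].astype(int) - 1
    return df


def write_variants(df: pd.DataFrame, path: str | Path) -> None:
    df[VARIANT_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Trees


def read_tree(path: str | Path) -> TreeNode:
    with xopen(path) as fh:
        return TreeNode.read(fh, format="newick")


def parse_tree(newick: str) -> TreeNode:
    import io

    return TreeNode.read(io.StringIO(newick), format="newick")


def write_tree(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def mask_intervals_from_sequence(chrom: str, seq: str) -> list[GenomicInterval]:
    """Runs of soft-masked (lowercase) or N bases, as a merged track."""
    out = []
    run_start = None
    for i, c in enumerate(seq):
        masked = c.islower() or c in "Nn"
        if masked and run_start is None:
            run_start = i
        elif not masked and run_start is not None:
            out.append(GenomicInterval(chrom, run_start, i))
            run_start = None
    if run_start is not None:
        out.append(GenomicInterval(chrom, run_start, len(seq)))
    return merge_intervals(out) if out else []
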