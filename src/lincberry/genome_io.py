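"""Readers/writers for GFF3/GTF/FASTA/BED/TSV and the shared coordinate model.

All internal coordinates are 0-based half-open; 1-based inclusive coordinates
exist only at the GFF3/GTF file boundary. Spliced sequences are stored 5'->3'
(minus-strand transcripts are reverse-complemented at extraction), so ORF and
miRNA scans always operate in transcript space.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "AnnotationSet",
    "GenomeIOError",
    "read_gff3",
    "write_gff3",
    "read_gtf_transcripts",
    "write_gtf",
    "read_fasta",
    "write_fasta",
    "write_bed",
    "read_counts",
    "extract_spliced_sequence",
    "reverse_complement",
]


class GenomeIOError(ValueError):
    """Malformed or structurally inconsistent input."""


_VALID_STRANDS = ("+", "-")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise GenomeIOError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in _VALID_STRANDS:
            raise GenomeIOError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class TranscriptModel:
    """An exon-structured transcript on one chromosome and strand.

    ``biotype`` distinguishes reference genes from novel assembled
    transcripts; ``sequence`` (optional) is the spliced sequence 5'->3'.
    """

    id: str
    exons: tuple[GenomicInterval, ...]
    biotype: str = "novel"
    sequence: str | None = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise GenomeIOError(f"transcript {self.id} has no exons")
        self.exons = tuple(sorted(self.exons, key=lambda e: e.start))
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1:
            raise GenomeIOError(f"transcript {self.id} spans chromosomes {chroms}")
        if len(strands) > 1:
            raise GenomeIOError(f"transcript {self.id} mixes strands")
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise GenomeIOError(f"transcript {self.id} has overlapping exons")
        if self.sequence is not None and len(self.sequence) != self.spliced_length:
            raise GenomeIOError(
                f"transcript {self.id}: sequence length {len(self.sequence)} != "
                f"spliced length {self.spliced_length}"
            )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def tss(self) -> int:
        """Transcription start site (strand-aware, 0-based)."""
        return self.start if self.strand == "+" else self.end - 1

    def introns(self) -> tuple[GenomicInterval, ...]:
        """Gaps between consecutive exons."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return tuple(out)


class AnnotationSet:
    """Reference gene models plus strand-aware interval indexes.

    Three per-chromosome interval trees are maintained: gene spans, exons and
    introns, each carrying ``(gene_id, strand)`` payloads so that overlap
    queries can be filtered by strand.
    """

    def __init__(self, genes: list[TranscriptModel]):
        self.genes: list[TranscriptModel] = list(genes)
        self.by_id = {g.id: g for g in self.genes}
        if len(self.by_id) != len(self.genes):
            raise GenomeIOError("duplicate gene ids in annotation")
        self.span_index: dict[str, IntervalTree] = {}
        self.exon_index: dict[str, IntervalTree] = {}
        self.intron_index: dict[str, IntervalTree] = {}
        for g in self.genes:
            self.span_index.setdefault(g.chrom, IntervalTree()).addi(
                g.start, g.end, (g.id, g.strand)
            )
            for e in g.exons:
                self.exon_index.setdefault(g.chrom, IntervalTree()).addi(
                    e.start, e.end, (g.id, g.strand)
                )
            for i in g.introns():
                self.intron_index.setdefault(g.chrom, IntervalTree()).addi(
                    i.start, i.end, (g.id, g.strand)
                )

    def __len__(self) -> int:
        return len(self.genes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationSet):
            return NotImplemented
        return [(g.id, g.exons) for g in sorted(self.genes, key=lambda g: g.id)] == [
            (g.id, g.exons) for g in sorted(other.genes, key=lambda g: g.id)
        ]

    def _query(self, index, chrom, start, end, strand=None, same_strand=True):
        tree = index.get(chrom)
        if tree is None:
            return []
        hits = tree.overlap(start, end)
        if strand is None:
            return [h.data for h in hits]
        if same_strand:
            return [h.data for h in hits if h.data[1] == strand]
        return [h.data for h in hits if h.data[1] != strand]

    def overlapping_spans(self, iv: GenomicInterval, strand=None, same_strand=True):
        return self._query(self.span_index, iv.chrom, iv.start, iv.end, strand, same_strand)

    def overlapping_exons(self, iv: GenomicInterval, strand=None, same_strand=True):
        return self._query(self.exon_index, iv.chrom, iv.start, iv.end, strand, same_strand)

    def containing_introns(self, iv: GenomicInterval, strand=None, same_strand=True):
        """Introns that fully contain ``iv`` (optionally strand-filtered)."""
        tree = self.intron_index.get(iv.chrom)
        if tree is None:
            return []
        hits = [h for h in tree.overlap(iv.start, iv.end)
                if h.begin <= iv.start and h.end >= iv.end]
        if strand is None:
            return [h.data for h in hits]
        if same_strand:
            return [h.data for h in hits if h.data[1] == iv.strand]
        return [h.data for h in hits if h.data[1] != iv.strand]


# ---------------------------------------------------------------------------
# sequence helpers

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_spliced_sequence(transcript: TranscriptModel, genome: dict) -> str:
    """Spliced transcript sequence, 5'->3' (reverse-complemented on minus)."""
    chrom_seq = genome[transcript.chrom]
    parts = [str(chrom_seq[e.start : e.end]) for e in transcript.exons]
    seq = "".join(parts).upper()
    if transcript.strand == "-":
        seq = reverse_complement(seq)
    return seq


# ---------------------------------------------------------------------------
# GFF3 / GTF

def _validate_tabular(path: str, n_cols: int = 9) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != n_cols:
                raise GenomeIOError(
                    f"{path}: line {lineno}: expected {n_cols} tab-separated "
                    f"fields, found {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise GenomeIOError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if start < 1 or end < start:
                raise GenomeIOError(
                    f"{path}: line {lineno}: invalid coordinate range {start}-{end}"
                )


def read_gff3(path: str) -> AnnotationSet:
    """Read a gene/mRNA/exon GFF3 annotation into an :class:`AnnotationSet`.

    GFF3 1-based inclusive coordinates are converted to 0-based half-open.
    Every exon must resolve to an mRNA parent and every mRNA to a gene;
    orphan features raise :class:`GenomeIOError`.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    _validate_tabular(path)
    db = gffutils.create_db(
        path, dbfn=":memory:", merge_strategy="create_unique", keep_order=True
    )
    mrna_parent: dict[str, str] = {}
    for mrna in db.features_of_type("mRNA"):
        parents = mrna.attributes.get("Parent", [])
        if not parents or parents[0] not in {g.id for g in db.features_of_type("gene")}:
            raise GenomeIOError(f"mRNA {mrna.id} lacks a resolvable gene Parent")
        mrna_parent[mrna.id] = parents[0]
    exons_by_mrna: dict[str, list[GenomicInterval]] = {}
    strand_by_mrna: dict[str, str] = {}
    for exon in db.features_of_type("exon"):
        parents = exon.attributes.get("Parent", [])
        if not parents or parents[0] not in mrna_parent:
            raise GenomeIOError(
                f"exon at {exon.seqid}:{exon.start}-{exon.end} has no mRNA parent"
            )
        if exon.strand not in _VALID_STRANDS:
            raise GenomeIOError(f"exon of {parents[0]} is unstranded")
        exons_by_mrna.setdefault(parents[0], []).append(
            GenomicInterval(exon.seqid, exon.start - 1, exon.end, exon.strand)
        )
        strand_by_mrna[parents[0]] = exon.strand
    genes = []
    # one transcript model per gene: the lexicographically first mRNA
    gene_mrnas: dict[str, list[str]] = {}
    for mrna_id, gene_id in mrna_parent.items():
        gene_mrnas.setdefault(gene_id, []).append(mrna_id)
    for gene_id in sorted(gene_mrnas):
        mrna_id = sorted(gene_mrnas[gene_id])[0]
        exons = exons_by_mrna.get(mrna_id)
        if not exons:
            raise GenomeIOError(f"mRNA {mrna_id} of gene {gene_id} has no exons")
        genes.append(TranscriptModel(gene_id, tuple(exons), biotype="reference_gene"))
    return AnnotationSet(genes)


def write_gff3(annotation: AnnotationSet, path: str) -> None:
    """Write gene/mRNA/exon features, 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(annotation.genes, key=lambda g: (g.chrom, g.start, g.id)):
            row = [g.chrom, "lincberry", "gene", str(g.start + 1), str(g.end),
                   ".", g.strand, ".", f"ID={g.id}"]
            fh.write("\t".join(row) + "\n")
            mrna_id = f"{g.id}.t1"
            row[2], row[8] = "mRNA", f"ID={mrna_id};Parent={g.id}"
            fh.write("\t".join(row) + "\n")
            for i, e in enumerate(g.exons, start=1):
                fh.write("\t".join([
                    g.chrom, "lincberry", "exon", str(e.start + 1), str(e.end),
                    ".", g.strand, ".", f"ID={mrna_id}.exon{i};Parent={mrna_id}",
                ]) + "\n")


def read_gtf_transcripts(path: str) -> list[TranscriptModel]:
    """Read assembled transcripts (GTF exon records) as novel transcripts.

    Unstranded ('.') exons are rejected: downstream positional
    classification is strand-dependent and guessing would be silent error.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    _validate_tabular(path)
    try:
        db = gffutils.create_db(
            path,
            dbfn=":memory:",
            force_gff=False,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
            merge_strategy="create_unique",
            keep_order=True,
        )
    except gffutils.exceptions.EmptyInputError:
        return []
    exons: dict[str, list[GenomicInterval]] = {}
    order: list[str] = []
    for exon in db.features_of_type("exon"):
        tid = exon.attributes["transcript_id"][0]
        if exon.strand not in _VALID_STRANDS:
            raise GenomeIOError(
                f"transcript {tid}: unstranded exon; assembled transcripts "
                "must carry an explicit strand"
            )
        if tid not in exons:
            order.append(tid)
        exons.setdefault(tid, []).append(
            GenomicInterval(exon.seqid, exon.start - 1, exon.end, exon.strand)
        )
    return [TranscriptModel(tid, tuple(exons[tid]), biotype="novel") for tid in order]


def write_gtf(transcripts: list[TranscriptModel], path: str) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = f'transcript_id "{t.id}"; gene_id "{t.id}";'
            fh.write("\t".join([
                t.chrom, "lincberry", "transcript", str(t.start + 1), str(t.end),
                ".", t.strand, ".", attrs,
            ]) + "\n")
            for e in t.exons:
                fh.write("\t".join([
                    t.chrom, "lincberry", "exon", str(e.start + 1), str(e.end),
                    ".", t.strand, ".", attrs,
                ]) + "\n")


# ---------------------------------------------------------------------------
# FASTA / BED / counts

def read_fasta(path: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in out:
            raise GenomeIOError(f"duplicate FASTA id {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(sequences: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_bed(calls, path: str) -> None:
    """Write BED6 lines (0-based half-open), sorted by (chrom, start)."""
    rows = []
    for c in calls:
        t = getattr(c, "transcript", c)
        rows.append((t.chrom, t.start, t.end, t.id, 0, t.strand))
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")


def read_counts(path: str):
    """Read a features x samples TSV of non-negative integer counts."""
    from .expression import CountMatrix  # deferred: avoids import cycle

    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise GenomeIOError(f"{path}: no sample columns")
    for col in df.columns:
        series = df[col]
        if not pd.api.types.is_integer_dtype(series):
            if (series % 1 != 0).any():
                raise GenomeIOError(f"{path}: non-integer count in sample {col}")
            df[col] = series.astype(int)
        if (df[col] < 0).any():
            raise GenomeIOError(f"{path}: negative count in sample {col}")
    return CountMatrix(values=df)
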