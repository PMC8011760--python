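"""Seeded generators for every input class the pipeline consumes.

Each generator is a pure function of its parameters and an integer seed, and
emits planted ground-truth labels so downstream recovery can be asserted:
annotations with genes/introns, novel transcripts in each positional class,
sequences with ORFs straddling the coding-filter boundaries, stage-structured
negative-binomial count matrices with optional correlated module blocks and
batch shifts, miRNA target sites (perfect, mismatched, bulged mimic,
cleavable mimic) and 5' RACE clone tables with a configurable modal cleavage
offset.

Default scales are deliberately small (two ~50 kb chromosomes, tens of
transcripts, 3 stages x 3 replicates) so a full pipeline run takes seconds.
Transcripts use the DNA alphabet, miRNAs RNA; pairing logic treats T and U
as equivalent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import discovery
from .genome_io import (
    AnnotationSet,
    GenomicInterval,
    TranscriptModel,
    reverse_complement,
)

__all__ = [
    "SyntheticTruth",
    "make_annotation",
    "plant_transcripts",
    "plant_orf",
    "make_counts",
    "make_mirna",
    "plant_target_sites",
    "make_race_clones",
    "PlacementError",
]


class PlacementError(RuntimeError):
    """Could not place a requested entity within the annotation."""


@dataclass
class SyntheticTruth:
    class_labels: dict[str, str] = field(default_factory=dict)
    planted_orfs: dict[str, list[tuple[int, int, str]]] = field(default_factory=dict)
    planted_sites: list[tuple[str, int, str]] = field(default_factory=list)
    stage_specific: dict[str, str] = field(default_factory=dict)
    module_membership: dict[str, str] = field(default_factory=dict)
    race_modal_offset: int | None = None


_BASES = np.array(list("ACGT"))
_STOP_CODONS = ("TAA", "TAG", "TGA")
# sense codons that are neither stops nor ATG (used as ORF filler)
_SAFE_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOP_CODONS and a + b + c != "ATG"
)


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.40) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def _salt_stops(seq: str, rng: np.random.Generator, max_run: int = 40) -> str:
    """Break long stop-free runs in all three frames.

    Overwrites one codon with a stop whenever a frame accumulates
    ``max_run`` stop-free codons, iterating until no frame carries a run
    long enough to form a disqualifying ORF. Keeps random-looking sequence
    while guaranteeing every ORF stays comfortably below 50 aa.
    """
    s = list(seq)
    for _ in range(12):
        dirty = False
        for frame in range(3):
            run = 0
            for i in range(frame, len(s) - 2, 3):
                codon = "".join(s[i : i + 3])
                if codon in _STOP_CODONS:
                    run = 0
                    continue
                run += 1
                if run >= max_run:
                    stop = _STOP_CODONS[rng.integers(0, 3)]
                    s[i : i + 3] = list(stop)
                    run = 0
                    dirty = True
        if not dirty:
            break
    return "".join(s)


def noncoding_sequence(rng: np.random.Generator, length: int,
                       gc: float = 0.40) -> str:
    """A random sequence free of internal ORFs >100 aa and terminal ORFs >50 aa."""
    for _ in range(20):
        seq = _salt_stops(_random_seq(rng, length, gc), rng)
        orfs = discovery.find_orfs(seq) if length >= 3 else []
        if all(o.length_aa <= 45 for o in orfs):
            return seq
    raise PlacementError(f"could not build a noncoding sequence of length {length}")


# ---------------------------------------------------------------------------
# annotation + genome

def make_annotation(seed: int, n_chrom: int = 2, n_genes: int = 10,
                    intergenic_gap: int = 1500, chrom_length: int = 50_000,
                    gc: float = 0.40):
    """Random multi-chromosome annotation plus matching genome sequences.

    Genes carry 1-5 exons with 100-500 nt introns and are laid out left to
    right with at least ``intergenic_gap`` bases between neighbouring gene
    spans. Returns ``(AnnotationSet, genome dict)``; both are byte-identical
    across calls with the same arguments.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if intergenic_gap < 1:
        raise ValueError("intergenic_gap must be >= 1")
    rng = np.random.default_rng(seed)
    genome = {f"chr{i + 1}": _random_seq(rng, chrom_length, gc)
              for i in range(n_chrom)}
    genes: list[TranscriptModel] = []
    chrom_idx, cursor = 0, intergenic_gap
    for gi in range(n_genes):
        n_exons = int(rng.integers(1, 6))
        exon_lens = rng.integers(150, 400, size=n_exons)
        intron_lens = rng.integers(100, 500, size=max(n_exons - 1, 0))
        gene_len = int(exon_lens.sum() + intron_lens.sum())
        while chrom_idx < n_chrom and cursor + gene_len + intergenic_gap > chrom_length:
            chrom_idx += 1
            cursor = intergenic_gap
        if chrom_idx >= n_chrom:
            raise PlacementError(
                f"cannot place {n_genes} genes on {n_chrom} chromosomes of "
                f"{chrom_length} nt with gap {intergenic_gap}")
        chrom = f"chr{chrom_idx + 1}"
        strand = "+" if rng.random() < 0.5 else "-"
        exons, pos = [], cursor
        for k in range(n_exons):
            exons.append(GenomicInterval(chrom, pos, pos + int(exon_lens[k]), strand))
            pos += int(exon_lens[k])
            if k < n_exons - 1:
                pos += int(intron_lens[k])
        genes.append(TranscriptModel(f"gene{gi + 1:04d}", tuple(exons),
                                     biotype="reference_gene"))
        cursor = pos + intergenic_gap
    return AnnotationSet(genes), genome


def _write_into_genome(genome: dict, chrom: str, start: int, seq: str) -> None:
    s = genome[chrom]
    genome[chrom] = s[:start] + seq + s[start + len(seq):]


def _class_ok(t: TranscriptModel, annotation: AnnotationSet, wanted: str) -> bool:
    got = discovery.classify_position(t, annotation)
    return got == wanted


# ---------------------------------------------------------------------------
# planted transcripts per positional class

def plant_transcripts(annotation: AnnotationSet, genome: dict,
                      class_counts: dict[str, int], seed: int,
                      length_range: tuple[int, int] = (250, 300),
                      max_tries: int = 200):
    """Plant novel single-exon transcripts of each positional class.

    ``class_counts`` maps LINC/INTRONIC/exonAS/intronAS/discard to counts;
    "discard" transcripts overlap reference exons on the sense strand and
    must be rejected by the identification pipeline. Each placement is
    verified against its class definition before acceptance. Sequences are
    noncoding (no disqualifying ORF) and are written back into the genome so
    genomic extraction and the stored transcript sequence agree.

    Returns ``(transcripts, truth, genome)`` with the updated genome.
    """
    rng = np.random.default_rng(seed + 7919)
    genome = dict(genome)
    truth = SyntheticTruth()
    transcripts: list[TranscriptModel] = []
    occupied: dict[str, list[tuple[int, int]]] = {}
    counter = 0

    def _try_place(cls: str) -> TranscriptModel:
        nonlocal counter
        for _ in range(max_tries):
            length = int(rng.integers(length_range[0], length_range[1] + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            if cls == "LINC":
                chrom = rng.choice(sorted(genome))
                start = int(rng.integers(0, len(genome[chrom]) - length))
            elif cls in ("INTRONIC", "intronAS"):
                host = annotation.genes[rng.integers(0, len(annotation.genes))]
                introns = [i for i in host.introns() if len(i) >= length + 10]
                if not introns:
                    continue
                intron = introns[rng.integers(0, len(introns))]
                start = int(rng.integers(intron.start + 2,
                                         intron.end - length - 2))
                chrom = host.chrom
                strand = host.strand if cls == "INTRONIC" else (
                    "+" if host.strand == "-" else "-")
            elif cls in ("exonAS", "discard"):
                host = annotation.genes[rng.integers(0, len(annotation.genes))]
                exon = host.exons[rng.integers(0, host.n_exons)]
                # start inside the exon so >=1 exonic base overlaps
                lo = max(exon.start - length + 20, 0)
                hi = exon.end - 20
                if hi <= lo:
                    continue
                start = int(rng.integers(lo, hi))
                chrom = host.chrom
                strand = host.strand if cls == "discard" else (
                    "+" if host.strand == "-" else "-")
            else:
                raise ValueError(f"unknown class {cls!r}")
            if start < 0 or start + length > len(genome[chrom]):
                continue
            # keep planted loci disjoint so genome writes never collide
            if any(start < e and s < start + length
                   for s, e in occupied.get(chrom, [])):
                continue
            counter += 1
            tid = f"novel{counter:04d}"
            t = TranscriptModel(
                tid, (GenomicInterval(chrom, start, start + length, strand),))
            wanted = "discard" if cls == "discard" else cls
            if not _class_ok(t, annotation, wanted):
                counter -= 1
                continue
            seq = noncoding_sequence(rng, length)
            genomic = seq if strand == "+" else reverse_complement(seq)
            _write_into_genome(genome, chrom, start, genomic)
            occupied.setdefault(chrom, []).append((start, start + length))
            t.sequence = seq
            return t
        raise PlacementError(f"could not place a {cls} transcript after "
                             f"{max_tries} tries")

    for cls in ("LINC", "INTRONIC", "exonAS", "intronAS", "discard"):
        for _ in range(class_counts.get(cls, 0)):
            t = _try_place(cls)
            transcripts.append(t)
            truth.class_labels[t.id] = cls
    return transcripts, truth, genome


# ---------------------------------------------------------------------------
# planted ORFs

def plant_orf(sequence: str, start_nt: int, length_aa: int,
              terminal: bool = False, seed: int = 0) -> str:
    """Overwrite ``sequence`` so one ATG-initiated ORF of ``length_aa``
    amino acids starts at ``start_nt``.

    Internal ORFs are closed by a stop codon; terminal ORFs run to the 3'
    end of the sequence (no stop, at most 2 leftover nucleotides). A stop is
    also written immediately upstream in the same frame so the planted ATG
    is not absorbed into an earlier reading frame.
    """
    if length_aa < 1:
        raise ValueError("length_aa must be >= 1")
    rng = np.random.default_rng(seed + 104729)
    need = 3 * length_aa if terminal else 3 * (length_aa + 1)
    if terminal:
        tail = len(sequence) - start_nt - 3 * length_aa
        if tail < 0 or tail > 2:
            raise ValueError(
                "terminal ORF must run to the sequence 3' end "
                f"(start {start_nt}, {length_aa} aa, sequence "
                f"{len(sequence)} nt leaves tail {tail})")
    elif start_nt + need > len(sequence):
        raise ValueError("insufficient room for internal ORF plus stop")
    codons = ["ATG"] + [
        _SAFE_CODONS[rng.integers(0, len(_SAFE_CODONS))]
        for _ in range(length_aa - 1)
    ]
    if not terminal:
        codons.append(_STOP_CODONS[rng.integers(0, 3)])
    insert = "".join(codons)
    s = list(sequence)
    s[start_nt : start_nt + len(insert)] = list(insert)
    if start_nt >= 3:
        s[start_nt - 3 : start_nt] = list(_STOP_CODONS[rng.integers(0, 3)])
    return "".join(s)


# ---------------------------------------------------------------------------
# counts

def make_counts(design: dict[str, int] | None = None, n_features: int = 200,
                seed: int = 1, base_mean: float = 50.0, dispersion: float = 0.1,
                stage_specific_per_stage: int = 20, specific_mean: float = 400.0,
                off_mean: float = 0.01, module_sizes: list[int] | None = None,
                module_sd: float = 1.2, batch_shift: float | None = None,
                batch_samples: list[str] | None = None):
    """Stage-structured negative-binomial count matrix with planted truth.

    ``design`` maps stage name to replicate count (default three stages x
    three replicates, the usual ripening time-course layout). The first
    ``stage_specific_per_stage`` features per stage are expressed only in
    that stage (mean ``specific_mean`` there, ``off_mean`` elsewhere); the
    rest are constitutive around ``base_mean``. Optional ``module_sizes``
    carve correlated blocks driven by a shared per-sample log-normal factor
    (sd ``module_sd`` on log2 scale); optional ``batch_shift`` multiplies
    the means of ``batch_samples``. Variance follows mean + dispersion *
    mean^2.

    Returns ``(CountMatrix, SyntheticTruth)``.
    """
    from .expression import CountMatrix  # deferred import avoids cycle

    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    design = design or {"Fv1": 3, "Fv2": 3, "Fv3": 3}
    stages = list(design)
    samples = [f"{st}_rep{r + 1}" for st in stages for r in range(design[st])]
    sample_stage = {s: s.rsplit("_rep", 1)[0] for s in samples}
    rng = np.random.default_rng(seed + 15485863)
    truth = SyntheticTruth()

    features = [f"feat{i + 1:05d}" for i in range(n_features)]
    n_specific = stage_specific_per_stage * len(stages)
    if n_specific > n_features:
        raise ValueError("more stage-specific features than features")
    means = np.empty((n_features, len(samples)))
    for i, feat in enumerate(features):
        if i < n_specific:
            stage = stages[i // stage_specific_per_stage]
            truth.stage_specific[feat] = stage
            mu = np.array([specific_mean if sample_stage[s] == stage else off_mean
                           for s in samples])
        else:
            truth.stage_specific[feat] = "constitutive"
            mu = np.full(len(samples),
                         base_mean * float(rng.lognormal(0, 0.4)))
        means[i] = mu

    if module_sizes:
        pos = 0
        for m, size in enumerate(module_sizes, start=1):
            latent = rng.normal(0.0, module_sd, size=len(samples))
            for i in range(pos, pos + size):
                if i >= n_features:
                    raise ValueError("module sizes exceed n_features")
                means[i] = means[i] * (2.0 ** latent)
                truth.module_membership[features[i]] = f"M{m}"
            pos += size

    if batch_shift is not None and batch_samples:
        cols = [samples.index(s) for s in batch_samples]
        means[:, cols] *= batch_shift

    r = 1.0 / dispersion
    p = r / (r + means)
    counts = rng.negative_binomial(r, p)
    df = pd.DataFrame(counts, index=features, columns=samples)
    sample_design = pd.DataFrame({
        "stage": [sample_stage[s] for s in samples],
        "replicate": [int(s.rsplit("rep", 1)[1]) for s in samples],
        "library_type": "rRNA_depleted",
        "batch": ["B2" if batch_samples and s in batch_samples else "B1"
                  for s in samples],
    }, index=samples)
    return CountMatrix(values=df, sample_design=sample_design), truth


# ---------------------------------------------------------------------------
# miRNA sites and RACE clones

def make_mirna(seed: int, length: int = 21, name: str = "syn-miR01") -> tuple[str, str]:
    """A random mature miRNA sequence (RNA alphabet, 5'->3')."""
    if not 20 <= length <= 24:
        raise ValueError("miRNA length must be in 20..24")
    rng = np.random.default_rng(seed + 32452843)
    seq = _random_seq(rng, length).replace("T", "U")
    return name, seq


def _perfect_site(mirna_rna: str) -> str:
    """Target-space (DNA) reverse complement of the miRNA."""
    return reverse_complement(mirna_rna.replace("U", "T"))


def _mismatch_base(mirna_base: str) -> str:
    """A target base that neither Watson-Crick- nor wobble-pairs the given
    miRNA base."""
    complement = {"A": "T", "C": "G", "G": "C", "U": "A"}[mirna_base]
    wobble = {"G": "T", "U": "G"}.get(mirna_base)
    for cand in "ACGT":
        if cand != complement and cand != wobble:
            return cand
    raise AssertionError


def plant_target_sites(transcripts: list[TranscriptModel], mirna_rna: str,
                       site_specs: list[dict], seed: int = 0):
    """Overwrite transcript sequences with planted miRNA binding sites.

    Each spec is a dict with keys ``transcript`` (id), ``start`` (0-based
    offset in the spliced sequence), ``type`` (perfect / mismatched /
    eTM_bulge / cleavable_mimic) and optionally ``mismatch_positions``
    (miRNA coordinates, 1-based) or ``modal_offset`` (for cleavable_mimic).

    - perfect / cleavable_mimic: contiguous reverse complement, L target nt;
    - mismatched: substitutions breaking pairing at the stated positions;
    - eTM_bulge: 3 unpairable nucleotides inserted between the target bases
      pairing miRNA positions 10 and 11 (L+3 target nt).

    Returns ``(transcripts, SyntheticTruth)``; transcripts are modified in
    place.
    """
    if not 20 <= len(mirna_rna) <= 24:
        raise ValueError("miRNA length must be in 20..24")
    rng = np.random.default_rng(seed + 49979687)
    L = len(mirna_rna)
    by_id = {t.id: t for t in transcripts}
    truth = SyntheticTruth()
    for spec in site_specs:
        t = by_id[spec["transcript"]]
        start, stype = spec["start"], spec["type"]
        site = list(_perfect_site(mirna_rna))
        if stype == "mismatched":
            for pos in spec["mismatch_positions"]:
                # miRNA position k pairs site index L-k
                site[L - pos] = _mismatch_base(mirna_rna[pos - 1])
        elif stype == "eTM_bulge":
            # between the bases pairing positions 11 (index L-11) and 10
            bulge = "".join(_mismatch_base(mirna_rna[rng.integers(0, L)])
                            for _ in range(3))
            site = site[: L - 10] + list(bulge) + site[L - 10:]
        elif stype not in ("perfect", "cleavable_mimic"):
            raise ValueError(f"unknown site type {stype!r}")
        site_seq = "".join(site)
        if start < 0 or start + len(site_seq) > len(t.sequence or ""):
            raise ValueError(
                f"site does not fit transcript {t.id} at {start}")
        s = list(t.sequence)
        s[start : start + len(site_seq)] = list(site_seq)
        t.sequence = "".join(s)
        truth.planted_sites.append((t.id, start, stype))
        if stype == "cleavable_mimic":
            truth.race_modal_offset = int(spec.get("modal_offset", 12))
    return transcripts, truth


def make_race_clones(transcript_id: str, site_start: int, mirna_length: int,
                     modal_offset: int, n_clones: int, noise: float = 0.0,
                     seed: int = 0) -> pd.DataFrame:
    """Clone 5'-end positions for a contiguous site, 1-based coordinates.

    The bond whose 5'-side miRNA nucleotide is ``modal_offset`` receives the
    plurality of clones (a clone 5' end sits on the target base pairing that
    miRNA nucleotide); a ``noise`` fraction is scattered within +/-2 nt.
    Returns a tidy table with columns transcript, position, count.
    """
    if not 1 <= modal_offset < mirna_length:
        raise ValueError("modal_offset must be in [1, miRNA length - 1]")
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    rng = np.random.default_rng(seed + 86028121)
    # target base pairing miRNA nt k, 1-based: site_start + L - k + 1
    modal_pos = site_start + mirna_length - modal_offset + 1
    positions = []
    for _ in range(n_clones):
        if noise > 0 and rng.random() < noise:
            shift = int(rng.choice([-2, -1, 1, 2]))
            positions.append(modal_pos + shift)
        else:
            positions.append(modal_pos)
    tally = pd.Series(positions).value_counts().sort_index()
    return pd.DataFrame({
        "transcript": transcript_id,
        "position": tally.index.astype(int),
        "count": tally.values.astype(int),
    }).reset_index(drop=True)
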