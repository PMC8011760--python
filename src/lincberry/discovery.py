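"""lncRNA identification: length filter, positional classification, ORF filter.

The pipeline mirrors the standard three-section plant lncRNA workflow:

1. keep assembled transcripts with spliced length strictly greater than
   ``min_length_nt`` (default 200);
2. classify each retained transcript against the reference annotation into
   LINC (intergenic), INTRONIC (sense, inside one intron), exonAS
   (antisense, touching exonic bases) or intronAS (antisense, confined to
   intronic bases) — transcripts with sense exonic overlap are discarded;
3. drop transcripts whose internal ORFs exceed ``max_internal_orf_aa``
   (default 100 aa) or whose terminal ORFs exceed ``max_terminal_orf_aa``
   (default 50 aa); "longer than" is strict, so the boundary values are kept.

Terminal ORFs cover both stop-less 3' runoff frames initiated at an ATG and
ATG-less 5' runoff frames closed by a stop; ORF lengths exclude the stop
codon. An optional homology hook lets callers plug an external
protein-similarity predicate into the coding filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

from .genome_io import AnnotationSet, TranscriptModel

__all__ = [
    "Orf",
    "LncRNACall",
    "DiscoveryConfig",
    "find_orfs",
    "classify_position",
    "coding_filter",
    "discover",
    "tally_classes",
    "POSITIONAL_CLASSES",
]

POSITIONAL_CLASSES = ("LINC", "INTRONIC", "exonAS", "intronAS")

_STOPS = frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True)
class Orf:
    """An ATG-initiated or end-anchored reading frame in transcript space."""

    start_nt: int  # 0-based offset of the first codon in the spliced sequence
    length_aa: int  # codons counted, excluding any stop codon
    kind: str  # "internal" or "terminal"
    frame: int  # 0..2


@dataclass
class DiscoveryConfig:
    min_length_nt: int = 200
    max_internal_orf_aa: int = 100
    max_terminal_orf_aa: int = 50
    homology_hook: Callable[[TranscriptModel], bool] | None = None

    def __post_init__(self) -> None:
        if min(self.min_length_nt, self.max_internal_orf_aa,
               self.max_terminal_orf_aa) <= 0:
            raise ValueError("all discovery thresholds must be positive")


@dataclass
class LncRNACall:
    transcript: TranscriptModel
    positional_class: str | None
    orfs: list[Orf] = field(default_factory=list)
    verdict: str = "kept"
    evidence: str = ""


def _clean_sequence(seq: str) -> str:
    seq = seq.upper().replace("U", "T")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"non-nucleotide symbols in sequence: {sorted(bad)}")
    return seq


def find_orfs(spliced_sequence: str) -> list[Orf]:
    """All ORFs in the three forward frames of a spliced transcript.

    Reported ORFs are (a) ATG-initiated, closed by an in-frame stop
    (internal) or running off the 3' end (terminal), and (b) ATG-less 5'
    runoff frames closed by a stop (terminal). Nested ATGs inside a longer
    same-frame ORF are not reported separately. Codons containing N never
    count as ATG or stop.
    """
    seq = _clean_sequence(spliced_sequence)
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    orfs: list[Orf] = []
    for frame in range(3):
        codons = [seq[i : i + 3] for i in range(frame, len(seq) - 2, 3)]
        if not codons:
            continue
        # 5' runoff: frame enters from the 5' end without an ATG and is
        # closed by a stop; length counted in full codons before the stop.
        if codons[0] != "ATG":
            for j, codon in enumerate(codons):
                if codon in _STOPS:
                    if j >= 1:
                        orfs.append(Orf(frame, j, "terminal", frame))
                    break
        # ATG-initiated ORFs
        i = 0
        while i < len(codons):
            if codons[i] != "ATG":
                i += 1
                continue
            stop_at = None
            for j in range(i + 1, len(codons)):
                if codons[j] in _STOPS:
                    stop_at = j
                    break
            if stop_at is None:
                orfs.append(Orf(frame + 3 * i, len(codons) - i, "terminal", frame))
                break
            orfs.append(Orf(frame + 3 * i, stop_at - i, "internal", frame))
            i = stop_at + 1
    orfs.sort(key=lambda o: (o.start_nt, -o.length_aa))
    return orfs


def classify_position(transcript: TranscriptModel, annotation: AnnotationSet) -> str:
    """Positional class of a transcript relative to reference genes.

    Returns one of ``LINC``, ``INTRONIC``, ``exonAS``, ``intronAS`` or
    ``discard``. A transcript overlapping multiple genes takes the
    highest-priority verdict, in order discard > exonAS > intronAS >
    INTRONIC; sense gene-span overlap that fits no retained class is also
    discarded.
    """
    strand = transcript.strand
    # (a) sense exonic overlap on any exon -> discard
    for e in transcript.exons:
        if annotation.overlapping_exons(e, strand=strand, same_strand=True):
            return "discard"
    # antisense exonic overlap
    for e in transcript.exons:
        if annotation.overlapping_exons(e, strand=strand, same_strand=False):
            return "exonAS"
    span = transcript.span
    anti_span = any(
        annotation.overlapping_spans(e, strand=strand, same_strand=False)
        for e in transcript.exons)
    if anti_span:
        # overlap exists, touches no exon -> confined to intronic bases
        return "intronAS"
    sense_span = any(
        annotation.overlapping_spans(e, strand=strand, same_strand=True)
        for e in transcript.exons)
    if sense_span:
        if annotation.containing_introns(span, strand=strand, same_strand=True):
            return "INTRONIC"
        # sense overlap that is neither exonic nor a clean intronic
        # containment (e.g. pokes out of the gene) is not a retained class
        return "discard"
    return "LINC"


def coding_filter(transcript: TranscriptModel, orfs: list[Orf],
                  config: DiscoveryConfig | None = None) -> str:
    """``dropped_coding`` iff any ORF exceeds its class bound (strict >)."""
    config = config or DiscoveryConfig()
    for orf in orfs:
        if orf.kind == "internal" and orf.length_aa > config.max_internal_orf_aa:
            return "dropped_coding"
        if orf.kind == "terminal" and orf.length_aa > config.max_terminal_orf_aa:
            return "dropped_coding"
    if config.homology_hook is not None and config.homology_hook(transcript):
        return "dropped_coding"
    return "kept"


def discover(transcripts: list[TranscriptModel], annotation: AnnotationSet,
             sequences: dict[str, str] | None = None,
             config: DiscoveryConfig | None = None) -> list[LncRNACall]:
    """Run length filter -> positional classification -> coding filter.

    Each transcript carries the first failing verdict; survivors are
    ``kept`` with a positional class. Transcript sequences come from the
    models themselves or from ``sequences``; ids without a sequence raise.
    """
    config = config or DiscoveryConfig()
    missing = [t.id for t in transcripts
               if t.sequence is None and (sequences is None or t.id not in sequences)]
    if missing:
        raise ValueError(f"transcripts without sequence: {missing}")
    calls: list[LncRNACall] = []
    for t in transcripts:
        seq = t.sequence if t.sequence is not None else sequences[t.id]
        if t.spliced_length <= config.min_length_nt:
            calls.append(LncRNACall(
                t, None, [], "dropped_length",
                f"spliced length {t.spliced_length} <= {config.min_length_nt}"))
            continue
        pos_class = classify_position(t, annotation)
        if pos_class == "discard":
            calls.append(LncRNACall(
                t, None, [], "dropped_sense_overlap",
                "sense overlap with reference gene exons/span"))
            continue
        orfs = find_orfs(seq)
        verdict = coding_filter(t, orfs, config)
        if verdict == "dropped_coding":
            worst = max(orfs, key=lambda o: o.length_aa)
            evidence = (f"{worst.kind} ORF of {worst.length_aa} aa exceeds bound")
        else:
            evidence = f"class {pos_class}; no disqualifying ORF"
        calls.append(LncRNACall(t, pos_class, orfs, verdict, evidence))
    return calls


def tally_classes(calls: list[LncRNACall]) -> dict[str, int]:
    """Per-class kept counts plus per-verdict drop counts."""
    out = {c: 0 for c in POSITIONAL_CLASSES}
    for call in calls:
        if call.verdict == "kept":
            out[call.positional_class] += 1
        else:
            out[call.verdict] = out.get(call.verdict, 0) + 1
    return out
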