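"""ORF finding, positional classification and filter behaviour.

Classification is checked against an exhaustive per-base overlap oracle
that re-implements the class definitions with plain base sets; ORF finding
against a naive codon-scan oracle.
"""

import itertools

import numpy as np
import pytest

from lincberry import discovery as dc
from lincberry import synthetic_data as sd
from lincberry.genome_io import AnnotationSet, GenomicInterval, TranscriptModel

# ---------------------------------------------------------------------------
# oracles


def brute_force_orfs(seq):
    """Naive codon scan, independent of discovery.find_orfs."""
    seq = seq.upper().replace("U", "T")
    stops = {"TAA", "TAG", "TGA"}
    found = []
    for frame in range(3):
        codons = [seq[i:i + 3] for i in range(frame, len(seq) - 2, 3)]
        claimed = set()
        # 5' runoff closed by a stop
        if codons and codons[0] != "ATG":
            for j, c in enumerate(codons):
                if c in stops:
                    if j >= 1:
                        found.append((frame, j, "terminal"))
                    break
        for i, c in enumerate(codons):
            if c != "ATG" or i in claimed:
                continue
            stop = next((j for j in range(i + 1, len(codons))
                         if codons[j] in stops), None)
            if stop is None:
                found.append((frame + 3 * i, len(codons) - i, "terminal"))
                claimed.update(range(i, len(codons)))
            else:
                found.append((frame + 3 * i, stop - i, "internal"))
                claimed.update(range(i, stop + 1))
    return sorted(found)


def brute_force_class(t, ann: AnnotationSet):
    """Per-base set re-implementation of the positional decision tree."""
    tx_bases = {(t.chrom, p) for e in t.exons for p in range(e.start, e.end)}
    sense_exon = antisense_exon = False
    sense_span = antisense_span = False
    inside_intron = False
    for g in ann.genes:
        if g.chrom != t.chrom:
            continue
        gene_bases = set(range(g.start, g.end))
        exon_bases = {p for e in g.exons for p in range(e.start, e.end)}
        tpos = {p for (c, p) in tx_bases}
        if tpos & exon_bases:
            if g.strand == t.strand:
                sense_exon = True
            else:
                antisense_exon = True
        if tpos & gene_bases:
            if g.strand == t.strand:
                sense_span = True
            else:
                antisense_span = True
        if g.strand == t.strand:
            for i in g.introns():
                if i.start <= t.start and t.end <= i.end:
                    inside_intron = True
    if sense_exon:
        return "discard"
    if antisense_exon:
        return "exonAS"
    if antisense_span:
        return "intronAS"
    if sense_span:
        return "INTRONIC" if inside_intron else "discard"
    return "LINC"


# ---------------------------------------------------------------------------
# find_orfs


def test_minimal_internal_orf():
    (orf,) = find = dc.find_orfs("ATGAAATAA")
    assert (orf.start_nt, orf.length_aa, orf.kind) == (0, 2, "internal")


def test_minimal_terminal_orf_runs_off_3prime_end():
    orfs = dc.find_orfs("CCCATGAAA")
    terminal = [o for o in orfs if o.kind == "terminal" and o.start_nt == 3]
    assert terminal and terminal[0].length_aa == 2


def test_atg_less_5prime_runoff_counts_as_terminal():
    # frame 0: AAA AAA TGA -> 2 full codons before the stop, no ATG
    orfs = dc.find_orfs("AAAAAATGA")
    assert any(o.kind == "terminal" and o.start_nt == 0 and o.length_aa == 2
               for o in orfs)


def test_n_codons_never_start_or_stop():
    # ANG is not a start; TNA is not a stop
    assert dc.find_orfs("ANGAAATNA") == []
    with pytest.raises(ValueError):
        dc.find_orfs("ATGXXXTAA")


def test_planted_orf_recovered_at_exact_coordinates(rng):
    seq = sd.noncoding_sequence(rng, 400)
    seq = sd.plant_orf(seq, start_nt=30, length_aa=120, seed=5)
    orfs = dc.find_orfs(seq)
    assert any(o.start_nt == 30 and o.length_aa == 120 and o.kind == "internal"
               for o in orfs)


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_find_orfs_matches_codon_scan_oracle(seed):
    r = np.random.default_rng(seed)
    seq = "".join(r.choice(list("ACGT"), size=240))
    got = sorted((o.start_nt, o.length_aa, o.kind) for o in dc.find_orfs(seq))
    assert got == brute_force_orfs(seq)


# ---------------------------------------------------------------------------
# classification


def _gene(gid, chrom, strand, blocks):
    return TranscriptModel(
        gid, tuple(GenomicInterval(chrom, s, e, strand) for s, e in blocks),
        biotype="reference_gene")


@pytest.fixture(scope="module")
def toy_annotation():
    # gene G: two exons 1000-1300 / 1700-2000 on +, so intron 1300-1700
    return AnnotationSet([_gene("G", "chr1", "+", [(1000, 1300), (1700, 2000)])])


@pytest.mark.parametrize("start,end,strand,expected", [
    (3000, 3400, "+", "LINC"),               # far from the gene
    (1350, 1650, "+", "INTRONIC"),           # sense, inside the intron
    (1350, 1650, "-", "intronAS"),           # antisense, intronic bases only
    (1290, 1600, "-", "exonAS"),             # antisense, touches one exon
    (1299, 1600, "+", "discard"),            # sense, one exonic base
    (1290, 1600, "+", "discard"),
])
def test_decision_tree_on_hand_cases(toy_annotation, start, end, strand, expected):
    t = TranscriptModel("t", (GenomicInterval("chr1", start, end, strand),))
    assert dc.classify_position(t, toy_annotation) == expected


def test_single_antisense_exon_base_is_exonAS(toy_annotation):
    t = TranscriptModel("t", (GenomicInterval("chr1", 1299, 1550, "-"),))
    assert dc.classify_position(t, toy_annotation) == "exonAS"


def test_classification_matches_per_base_oracle(planted_fixture):
    ann, _, transcripts, truth = planted_fixture
    for t in transcripts:
        assert dc.classify_position(t, ann) == brute_force_class(t, ann)


def test_random_placements_match_per_base_oracle(annotation_and_genome):
    ann, genome = annotation_and_genome
    r = np.random.default_rng(11)
    for _ in range(200):
        chrom = "chr1" if r.random() < 0.5 else "chr2"
        start = int(r.integers(0, len(genome[chrom]) - 400))
        length = int(r.integers(50, 400))
        strand = "+" if r.random() < 0.5 else "-"
        t = TranscriptModel(
            "t", (GenomicInterval(chrom, start, start + length, strand),))
        assert dc.classify_position(t, ann) == brute_force_class(t, ann)


# ---------------------------------------------------------------------------
# filters and the full pipeline


def test_coding_filter_boundaries(rng):
    cfg = dc.DiscoveryConfig()
    base = sd.noncoding_sequence(rng, 400)

    def verdict(length_aa, terminal):
        if terminal:
            seq = sd.noncoding_sequence(np.random.default_rng(9), 400)
            start = 400 - 3 * length_aa
            seq = sd.plant_orf(seq, start, length_aa, terminal=True, seed=2)
        else:
            seq = sd.plant_orf(base, 12, length_aa, seed=2)
        t = TranscriptModel("t", (GenomicInterval("chr1", 0, 400, "+"),),
                            sequence=seq)
        return dc.coding_filter(t, dc.find_orfs(seq), cfg)

    assert verdict(100, terminal=False) == "kept"
    assert verdict(101, terminal=False) == "dropped_coding"
    assert verdict(50, terminal=True) == "kept"
    assert verdict(51, terminal=True) == "dropped_coding"


def test_homology_hook_can_drop(simple_transcript):
    cfg = dc.DiscoveryConfig(homology_hook=lambda t: t.id == "tx1")
    assert dc.coding_filter(simple_transcript, [], cfg) == "dropped_coding"


def test_length_filter_is_strict(planted_fixture):
    ann, _, _, _ = planted_fixture
    short = TranscriptModel(
        "short", (GenomicInterval("chr1", 10, 160, "+"),), sequence="A" * 150)
    (call,) = dc.discover([short], ann)
    assert call.verdict == "dropped_length"
    exact = TranscriptModel(
        "exact", (GenomicInterval("chr1", 10, 210, "+"),), sequence="A" * 200)
    (call,) = dc.discover([exact], ann)
    assert call.verdict == "dropped_length"


def test_discover_recovers_planted_truth(planted_fixture):
    ann, _, transcripts, truth = planted_fixture
    calls = dc.discover(transcripts, ann)
    tally = dc.tally_classes(calls)
    assert (tally["LINC"], tally["INTRONIC"], tally["exonAS"],
            tally["intronAS"]) == (5, 2, 3, 1)
    assert tally["dropped_sense_overlap"] == 2
    for call in calls:
        label = truth.class_labels[call.transcript.id]
        if label == "discard":
            assert call.verdict == "dropped_sense_overlap"
        else:
            assert call.verdict == "kept" and call.positional_class == label


def test_discover_empty_input_and_missing_sequence(planted_fixture):
    ann, _, transcripts, _ = planted_fixture
    assert dc.discover([], ann) == []
    naked = TranscriptModel("naked", (GenomicInterval("chr1", 0, 300, "+"),))
    with pytest.raises(ValueError, match="naked"):
        dc.discover([naked], ann)


def test_filter_order_is_irrelevant_to_kept_set(planted_fixture):
    """Length, class and ORF predicates are independent, so applying the
    coding filter before classification keeps the same transcripts."""
    ann, _, transcripts, _ = planted_fixture
    cfg = dc.DiscoveryConfig()
    kept_pipeline = {c.transcript.id for c in dc.discover(transcripts, ann)
                     if c.verdict == "kept"}
    kept_permuted = set()
    for t in transcripts:
        if dc.coding_filter(t, dc.find_orfs(t.sequence), cfg) != "kept":
            continue
        if dc.classify_position(t, ann) == "discard":
            continue
        if t.spliced_length <= cfg.min_length_nt:
            continue
        kept_permuted.add(t.id)
    assert kept_pipeline == kept_permuted


def test_lowering_internal_bound_is_monotone(planted_fixture, rng):
    ann, _, transcripts, _ = planted_fixture
    seqs = {t.id: sd.plant_orf(t.sequence, 9, 60, seed=3) for t in transcripts[:4]}
    ts = [TranscriptModel(t.id, t.exons, sequence=seqs.get(t.id, t.sequence))
          for t in transcripts]
    kept_counts = []
    for bound in (120, 80, 59, 20):
        cfg = dc.DiscoveryConfig(max_internal_orf_aa=bound,
                                 max_terminal_orf_aa=10_000)
        kept_counts.append(sum(c.verdict == "kept"
                               for c in dc.discover(ts, ann, config=cfg)))
    assert kept_counts == sorted(kept_counts, reverse=True)
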