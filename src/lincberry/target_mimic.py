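"""Plant miRNA target scanning, duplex energetics, cleavage and mimicry.

Sites are scored under two position-weighted penalty schemes that differ
only in how far the 5' "seed-like" doubling region extends (miRNA positions
2-13 vs 2-12); a site is a consensus call only when it passes both schemes,
mirroring the intersect-two-predictors design common in plant miRNA target
work. Alignments are exact banded searches allowing at most one bulge of up
to four nucleotides, which covers perfect sites, mismatched variants and
the three-nucleotide 10-11 bulge of canonical endogenous target mimics
(eTMs).

Cleavage follows the AGO slicer convention: the scissile bond sits between
the target bases pairing miRNA nucleotides 10 and 11 (counted 1-based from
the miRNA 5' end). A consensus site that is contiguous through positions
10-11 yet shows RACE-supported cleavage at a different bond is reported as
a noncanonical mimic; a 3-nt bulge between positions 10 and 11 is the
canonical eTM configuration.

Duplex free energies use a reduced 16-entry nearest-neighbour stacking
table; absolute values are coarse and only orderings between duplexes
should be interpreted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align

__all__ = [
    "MiRNA",
    "DuplexScheme",
    "SCHEME_A",
    "SCHEME_B",
    "DuplexAlignment",
    "TargetSite",
    "MimicCall",
    "score_duplex",
    "scan_targets",
    "duplex_energy",
    "predict_cleavage",
    "classify_mimic",
    "conservation_window",
]


@dataclass(frozen=True)
class MiRNA:
    """A mature miRNA, RNA alphabet, 5'->3', positions numbered 1..L."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("T", "U")
        object.__setattr__(self, "sequence", seq)
        if not 20 <= len(seq) <= 24:
            raise ValueError(f"miRNA length {len(seq)} outside 20..24")
        if set(seq) - set("ACGU"):
            raise ValueError("miRNA must be over {A,C,G,U}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DuplexScheme:
    """Penalty scheme: mismatch 1, G:U 0.5, bulged nt 2.

    Penalties at miRNA positions in [double_start, double_end] are doubled
    (mismatches, wobbles and bulged miRNA nucleotides). Target bulges sit
    between miRNA positions and always cost the flat per-nucleotide rate,
    so a central bulge is never traded away for off-register mismatches.
    """

    name: str
    double_start: int
    double_end: int
    mismatch: float = 1.0
    gu: float = 0.5
    bulge_per_nt: float = 2.0

    def weight(self, position: int) -> float:
        return 2.0 if self.double_start <= position <= self.double_end else 1.0


SCHEME_A = DuplexScheme("A", 2, 13)
SCHEME_B = DuplexScheme("B", 2, 12)

MATCH, GU, MISMATCH, MIRNA_BULGE = "match", "GU_wobble", "mismatch", "mirna_bulge"

_PAIR = {("A", "T"), ("C", "G"), ("G", "C"), ("U", "A")}
_WOBBLE = {("G", "T"), ("U", "G")}


def _pair_state(mirna_base: str, target_base: str) -> str:
    key = (mirna_base, target_base)
    if key in _PAIR:
        return MATCH
    if key in _WOBBLE:
        return GU
    return MISMATCH


@dataclass
class DuplexAlignment:
    """Per-miRNA-position pairing states for one target window.

    ``states[k-1]`` is the state at miRNA position k. ``pair_index`` maps
    each paired/mismatched position to its 0-based index inside the target
    window (windows read 5'->3' in transcript space, so miRNA position 1
    pairs the last window base). ``target_bulge`` is ``(j, length)`` for a
    bulge of target nucleotides between miRNA positions j and j+1, or None.
    ``target_span`` is filled by the scanner with transcript coordinates.
    """

    states: tuple[str, ...]
    pair_index: dict[int, int]
    target_bulge: tuple[int, int] | None = None
    target_span: tuple[int, int] | None = None

    @property
    def length(self) -> int:
        return len(self.states)

    def target_position(self, mirna_nt: int) -> int | None:
        """Absolute transcript index (0-based) pairing a miRNA position."""
        idx = self.pair_index.get(mirna_nt)
        if idx is None or self.target_span is None:
            return None
        return self.target_span[0] + idx


@dataclass
class TargetSite:
    transcript_id: str
    alignment: DuplexAlignment
    score_A: float
    score_B: float
    delta_g: float
    predicted_cleavage: tuple[int, int] | None  # (5'-side miRNA nt, target bond)
    consensus: bool = True

    @property
    def start(self) -> int:
        return self.alignment.target_span[0]

    @property
    def end(self) -> int:
        return self.alignment.target_span[1]


@dataclass
class MimicCall:
    site: TargetSite
    category: str  # cleavable_target | canonical_eTM | noncanonical_mimic
    race_evidence: object | None = None


def _dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def score_duplex(mirna: MiRNA | str, target_window: str,
                 scheme: DuplexScheme = SCHEME_A) -> tuple[float, DuplexAlignment]:
    """Optimal banded miRNA/target alignment under a penalty scheme.

    The window length must lie within [L-1, L+4]; the difference from L
    fixes the bulge size (target bulge when longer, single-nucleotide miRNA
    bulge when shorter) and every bulge placement is enumerated exactly.
    Ties prefer the bulge position closest to the 3' (high-numbered) end of
    the miRNA, which keeps placements deterministic.
    """
    m = mirna.sequence if isinstance(mirna, MiRNA) else mirna.upper().replace("T", "U")
    t = _dna(target_window)
    L, W = len(m), len(t)
    if not L - 1 <= W <= L + 4:
        raise ValueError(f"window length {W} outside [{L - 1}, {L + 4}]")

    def positional_penalty(k: int, state: str) -> float:
        base = {MATCH: 0.0, GU: scheme.gu, MISMATCH: scheme.mismatch}[state]
        return base * scheme.weight(k)

    best: tuple[float, DuplexAlignment] | None = None
    best_key: tuple[float, int] | None = None
    if W == L:
        placements = [None]
    elif W > L:
        placements = list(range(1, L))  # target bulge after miRNA position j
    else:
        placements = list(range(2, L))  # bulged miRNA nt m (unpaired)
    for place in placements:
        states: list[str] = []
        pair_index: dict[int, int] = {}
        penalty = 0.0
        bulge = None
        if W == L:
            for k in range(1, L + 1):
                idx = W - k
                st = _pair_state(m[k - 1], t[idx])
                states.append(st)
                pair_index[k] = idx
                penalty += positional_penalty(k, st)
        elif W > L:
            b = W - L
            j = place
            for k in range(1, L + 1):
                idx = W - k if k <= j else W - k - b
                st = _pair_state(m[k - 1], t[idx])
                states.append(st)
                pair_index[k] = idx
                penalty += positional_penalty(k, st)
            bulge = (j, b)
            # a target bulge lies between miRNA positions, so the seed
            # doubling (defined per position) does not apply to it
            penalty += scheme.bulge_per_nt * b
        else:  # W == L - 1, one unpaired miRNA nucleotide
            mb = place
            for k in range(1, L + 1):
                if k == mb:
                    states.append(MIRNA_BULGE)
                    penalty += scheme.bulge_per_nt * scheme.weight(k)
                    continue
                idx = W - k if k < mb else W - k + 1
                st = _pair_state(m[k - 1], t[idx])
                states.append(st)
                pair_index[k] = idx
                penalty += positional_penalty(k, st)
        # ties prefer the 3'-most bulge placement (deterministic)
        key = (round(penalty, 9), -(place or 0))
        if best_key is None or key < best_key:
            best_key = key
            best = (penalty, DuplexAlignment(tuple(states), pair_index, bulge))
    assert best is not None
    return best


def _reduce_hits(hits: list[tuple[int, int, float, DuplexAlignment]],
                 radius: int = 3):
    """Keep the best-scoring window per locus (midpoints within ``radius``)."""
    hits = sorted(hits, key=lambda h: (h[2], h[0], h[1]))
    kept: list[tuple[int, int, float, DuplexAlignment]] = []
    for h in hits:
        mid = (h[0] + h[1]) / 2
        if all(abs(mid - (k[0] + k[1]) / 2) > radius for k in kept):
            kept.append(h)
    return kept


def scan_targets(mirna: MiRNA, transcripts, cutoff_A: float = 4.0,
                 cutoff_B: float = 4.0) -> list[TargetSite]:
    """Slide every admissible window over every transcript, keep consensus.

    Hits passing scheme A and scheme B independently are intersected by
    span midpoint (within +/-3 nt); only consensus sites are returned,
    ordered by (transcript, start). Scores and the scheme-A alignment are
    attached, along with duplex energy and the canonical cleavage call.
    """
    L = len(mirna)
    sites: list[TargetSite] = []
    items = transcripts.items() if isinstance(transcripts, dict) else (
        (t.id, t.sequence) for t in transcripts)
    for tid, seq in sorted(items):
        if seq is None:
            raise ValueError(f"transcript {tid} has no sequence")
        seq = _dna(seq)
        per_scheme: dict[str, list] = {"A": [], "B": []}
        for W in range(L - 1, L + 5):
            for start in range(0, len(seq) - W + 1):
                window = seq[start : start + W]
                for name, scheme, cutoff in (("A", SCHEME_A, cutoff_A),
                                             ("B", SCHEME_B, cutoff_B)):
                    score, aln = score_duplex(mirna, window, scheme)
                    if score <= cutoff:
                        per_scheme[name].append((start, start + W, score, aln))
        hits_a = _reduce_hits(per_scheme["A"])
        hits_b = _reduce_hits(per_scheme["B"])
        for start, end, score_a, aln in sorted(hits_a):
            mid = (start + end) / 2
            partner = [h for h in hits_b if abs((h[0] + h[1]) / 2 - mid) <= 3]
            if not partner:
                continue
            score_b = min(h[2] for h in partner)
            aln.target_span = (start, end)
            dg = duplex_energy(aln, mirna, seq[start:end])
            site = TargetSite(tid, aln, score_a, score_b, dg, None, True)
            site.predicted_cleavage = predict_cleavage(site)
            sites.append(site)
    sites.sort(key=lambda s: (s.transcript_id, s.start))
    return sites


# reduced RNA/RNA nearest-neighbour stacking table, kcal/mol; keyed by the
# miRNA-side dinucleotide 5'->3' assuming Watson-Crick partners
_STACK = {
    "AA": -0.9, "AU": -1.1, "AC": -2.1, "AG": -2.1,
    "UA": -1.3, "UU": -0.9, "UC": -2.1, "UG": -2.1,
    "CA": -2.1, "CU": -2.1, "CC": -3.3, "CG": -2.4,
    "GA": -2.4, "GU": -2.2, "GC": -3.4, "GG": -3.3,
}
_GU_STACK = -0.5  # stack involving a wobble pair
_LOOP_PENALTY = 0.5  # per mismatched or bulged nucleotide


def duplex_energy(alignment: DuplexAlignment, mirna: MiRNA | str,
                  target_window: str) -> float:
    """Simplified nearest-neighbour free energy of an aligned duplex.

    Adjacent paired positions contribute stacking terms (wobble-containing
    stacks get a flat weak value); every mismatched or bulged nucleotide
    adds a fixed destabilizing term. No pairs -> 0.
    """
    m = mirna.sequence if isinstance(mirna, MiRNA) else mirna.upper().replace("T", "U")
    dg = 0.0
    paired = [st in (MATCH, GU) for st in alignment.states]
    for k in range(1, len(alignment.states)):
        # stack between miRNA positions k and k+1; a target bulge there
        # interrupts the helix, so no stacking term is gained
        if alignment.target_bulge is not None and alignment.target_bulge[0] == k:
            continue
        if paired[k - 1] and paired[k]:
            if alignment.states[k - 1] == MATCH and alignment.states[k] == MATCH:
                dg += _STACK[m[k - 1] + m[k]]
            else:
                dg += _GU_STACK
    for st in alignment.states:
        if st == MISMATCH:
            dg += _LOOP_PENALTY
        elif st == MIRNA_BULGE:
            dg += _LOOP_PENALTY
    if alignment.target_bulge:
        dg += _LOOP_PENALTY * alignment.target_bulge[1]
    return round(dg, 3)


def predict_cleavage(site: TargetSite) -> tuple[int, int] | None:
    """Canonical scissile bond between the bases pairing miRNA nt 10 and 11.

    Returns ``(10, target_bond)`` where ``target_bond`` is the 0-based
    transcript index of the base pairing miRNA nucleotide 10 (the first
    base of the 3' cleavage fragment; the bond lies immediately 5' of it).
    Unpaired positions 10/11 or a bulge between them yield None.
    """
    aln = site.alignment
    if len(aln.states) < 11:
        return None
    if aln.states[9] not in (MATCH, GU) or aln.states[10] not in (MATCH, GU):
        return None
    if aln.target_bulge is not None and aln.target_bulge[0] == 10:
        return None
    pos = aln.target_position(10)
    if pos is None:
        return None
    return (10, pos)


def classify_mimic(site: TargetSite, race_tally=None) -> MimicCall:
    """Classify a consensus site as target, canonical eTM or noncanonical mimic.

    canonical_eTM: 3-nt target bulge between miRNA positions 10 and 11.
    noncanonical_mimic: contiguous pairing through 10-11 but RACE clones
    place the modal scissile bond at an offset other than 10.
    Otherwise: cleavable_target.
    """
    if race_tally is not None and race_tally.transcript_id != site.transcript_id:
        raise ValueError("RACE tally is for a different transcript")
    aln = site.alignment
    if aln.target_bulge == (10, 3):
        return MimicCall(site, "canonical_eTM", race_tally)
    contiguous = (aln.states[9] in (MATCH, GU) and aln.states[10] in (MATCH, GU)
                  and aln.target_bulge != (10, 3))
    if (race_tally is not None and contiguous
            and race_tally.modal_mirna_offset not in (None, 10)):
        return MimicCall(site, "noncanonical_mimic", race_tally)
    return MimicCall(site, "cleavable_target", race_tally)


def conservation_window(homolog_sequences: dict[str, str], reference: str,
                        site: tuple[int, int]) -> tuple[np.ndarray, float]:
    """Per-column identity of homologs over a reference site window.

    Each homolog is globally aligned to the reference (match +1, mismatch
    -1, gap -2); identity per reference column is averaged over homologs
    and the mean within ``site`` (0-based half-open) is returned alongside
    the per-column vector.
    """
    if len(homolog_sequences) < 2:
        raise ValueError("need at least 2 homolog sequences")
    ref = _dna(reference)
    if not ref:
        raise ValueError("empty reference sequence")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    identity = np.zeros((len(homolog_sequences), len(ref)))
    for row, (name, seq) in enumerate(sorted(homolog_sequences.items())):
        seq = _dna(seq)
        if not seq:
            raise ValueError(f"empty homolog sequence {name!r}")
        aln = aligner.align(ref, seq)[0]
        for (r0, r1), (q0, q1) in zip(*aln.aligned):
            block_ref = ref[r0:r1]
            block_q = seq[q0:q1]
            for off, (a, b) in enumerate(zip(block_ref, block_q)):
                if a == b:
                    identity[row, r0 + off] = 1.0
    per_column = identity.mean(axis=0)
    s, e = site
    if not 0 <= s < e <= len(ref):
        raise ValueError("site window outside reference")
    return per_column, float(per_column[s:e].mean())
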