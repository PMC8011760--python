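"""Quantitative assay computations: RLM-RACE tallies and anthocyanin index.

A 5' RLM-RACE clone marks the 5' end of the 3' cleavage fragment, so the
scissile bond sits immediately 5' of the clone's first base on the
transcript. Mapping that base through the miRNA/target alignment gives the
bond in miRNA coordinates: a clone starting on the target base that pairs
miRNA nucleotide k implies a bond between miRNA nucleotides k and k+1,
reported as offset k (the 5'-side nucleotide, so "10" reads "between the
10th and 11th").

The anthocyanin index is the spectrophotometric proxy
(A530 - 0.25 x A657) / M with M the tissue mass in grams.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .target_mimic import TargetSite

__all__ = ["RaceTally", "AssayReading", "tally_cleavage", "anthocyanin_index"]


@dataclass
class RaceTally:
    """Clone 5'-end counts per 1-based transcript position."""

    transcript_id: str
    counts: dict[int, int]
    modal_position: int
    modal_mirna_offset: int | None  # None when outside the pairable range
    tie: bool = False
    offsets: dict[int, int | None] = field(default_factory=dict)

    @property
    def n_clones(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class AssayReading:
    A530: float
    A657: float
    M: float  # grams of tissue

    def __post_init__(self) -> None:
        if self.M <= 0:
            raise ValueError("sample mass M must be > 0")
        if self.A530 < 0 or self.A657 < 0:
            raise ValueError("absorbances must be >= 0")


def tally_cleavage(clone_positions, site: TargetSite) -> RaceTally:
    """Tally clone 5' ends and infer the modal scissile bond.

    ``clone_positions`` are 1-based transcript coordinates of clone 5'
    ends, given either as an iterable of positions or as a mapping/table of
    position -> count. The modal position (ties resolved toward the
    smaller position, with the tie flagged) is translated into a miRNA
    offset through the site alignment; positions that pair no miRNA
    nucleotide in 1..L-1 report offset None.
    """
    if hasattr(clone_positions, "itertuples"):  # tidy DataFrame
        counts: dict[int, int] = {}
        for row in clone_positions.itertuples(index=False):
            counts[int(row.position)] = counts.get(int(row.position), 0) + int(
                getattr(row, "count", 1))
    elif isinstance(clone_positions, dict):
        counts = {int(p): int(c) for p, c in clone_positions.items()}
    else:
        counts = {}
        for p in clone_positions:
            counts[int(p)] = counts.get(int(p), 0) + 1
    if not counts:
        raise ValueError("empty clone list")

    aln = site.alignment
    span = aln.target_span
    if span is None:
        raise ValueError("site alignment lacks a target span")
    # invert the pairing map: 0-based target index -> miRNA nt
    target_to_mirna = {span[0] + idx: k for k, idx in aln.pair_index.items()}
    L = aln.length

    def offset_of(pos_1based: int) -> int | None:
        k = target_to_mirna.get(pos_1based - 1)
        if k is None or not 1 <= k <= L - 1:
            return None
        return k

    best = max(counts.values())
    modal_candidates = sorted(p for p, c in counts.items() if c == best)
    modal_position = modal_candidates[0]
    return RaceTally(
        transcript_id=site.transcript_id,
        counts=dict(sorted(counts.items())),
        modal_position=modal_position,
        modal_mirna_offset=offset_of(modal_position),
        tie=len(modal_candidates) > 1,
        offsets={p: offset_of(p) for p in sorted(counts)},
    )


def anthocyanin_index(reading: AssayReading) -> float:
    """(A530 - 0.25 x A657) / M; negative values are reported with a warning."""
    value = (reading.A530 - 0.25 * reading.A657) / reading.M
    if value < 0:
        warnings.warn("anthocyanin index is negative; check the readings")
    return value
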