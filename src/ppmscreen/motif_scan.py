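"""Exact-match scanning for HMX1 binding sites in promoter windows.

HMX1 binds the canonical CAAGTG hexamer (reverse complement CACTTG); the
minimal CAAG core (reverse CTTG) also binds, with lower affinity. Both
orientations of a motif are scanned because downstream pairing rules
disregard orientation. No position-weight matrix exists for HMX1, so
scanning is exact string matching: case-insensitive, with N never matching.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .errors import FormatError
from .promoter_io import PromoterWindow, reverse_complement

FORWARD = "forward"
REVERSE = "reverse"


@dataclass(frozen=True)
class Motif:
    name: str
    forward: str
    reverse: str

    def __post_init__(self) -> None:
        if not self.forward or set(self.forward) - set("ACGT"):
            raise FormatError(f"motif {self.name!r}: forward string must be non-empty ACGT")
        if self.reverse != reverse_complement(self.forward):
            raise FormatError(
                f"motif {self.name!r}: reverse {self.reverse!r} is not the "
                f"reverse complement of {self.forward!r}"
            )

    @property
    def length(self) -> int:
        return len(self.forward)


CANONICAL = Motif("canonical", "CAAGTG", "CACTTG")
CORE = Motif("core", "CAAG", "CTTG")


@dataclass(frozen=True, order=True)
class MotifHit:
    """One motif occurrence; ``start_offset`` is the 0-based window offset of
    the 5'-most matched base on the window strand."""

    start_offset: int
    motif_name: str
    orientation: str
    length: int

    @property
    def end_offset(self) -> int:
        """Exclusive end, BED-style."""
        return self.start_offset + self.length

    def overlaps(self, other: "MotifHit") -> bool:
        return self.start_offset < other.end_offset and other.start_offset < self.end_offset


def find_exact(sequence: str, pattern: str) -> list[int]:
    """All start offsets of ``pattern`` in ``sequence``, ascending, including
    overlapping occurrences. Case-insensitive; N never matches (patterns are
    ACGT-only)."""
    if not pattern:
        raise FormatError("empty pattern")
    if set(pattern.upper()) - set("ACGT"):
        raise FormatError(f"pattern {pattern!r} must be over ACGT")
    seq = sequence.upper()
    pat = pattern.upper()
    hits: list[int] = []
    pos = seq.find(pat)
    while pos != -1:
        hits.append(pos)
        pos = seq.find(pat, pos + 1)
    return hits


def scan_window(window: PromoterWindow | str, motif: Motif) -> list[MotifHit]:
    """All oriented occurrences of ``motif`` in the window, sorted by
    start offset with forward before reverse at equal starts."""
    seq = window.sequence if isinstance(window, PromoterWindow) else window
    hits = [
        MotifHit(start, motif.name, FORWARD, motif.length)
        for start in find_exact(seq, motif.forward)
    ] + [
        MotifHit(start, motif.name, REVERSE, motif.length)
        for start in find_exact(seq, motif.reverse)
    ]
    hits.sort(key=lambda h: (h.start_offset, h.orientation != FORWARD))
    return hits


def hits_to_bed(
    hits: Iterable[MotifHit], chrom: str, shift: int = 0
) -> str:
    """Render hits as BED lines (0-based half-open); ``shift`` converts
    window-local offsets to genomic coordinates when needed."""
    lines = []
    for h in hits:
        name = f"{h.motif_name}/{h.orientation}"
        strand = "+" if h.orientation == FORWARD else "-"
        lines.append(
            f"{chrom}\t{h.start_offset + shift}\t{h.end_offset + shift}\t{name}\t0\t{strand}"
        )
    return "\n".join(lines) + ("\n" if lines else "")
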