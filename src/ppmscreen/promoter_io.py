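"""Genome and gene-table input, promoter window extraction and deduplication.

A promoter window is the transcription-oriented sequence covering
``[-upstream, +downstream]`` around a TSS (default ``[-250, +200]``, 450 nt).
Signed promoter coordinates skip zero: offset ``upstream - 1`` maps to ``-1``
(last untranscribed base) and offset ``upstream`` maps to ``+1`` (the TSS base
itself), following the usual promoter interval labelling.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from .errors import BoundaryError, ContigNotFoundError, FormatError

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_BASES = frozenset("ACGTN")

GENE_TABLE_COLUMNS = ("transcript_id", "gene_symbol", "contig", "strand", "tss")


def reverse_complement(sequence: str) -> str:
    """Reverse complement over the ACGTN alphabet (case preserved as upper)."""
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeSource:
    """Uppercase ACGTN contigs keyed by name."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not seq:
                raise FormatError(f"contig {name!r} is empty")
            bad = set(seq) - _VALID_BASES
            if bad:
                raise FormatError(
                    f"contig {name!r} contains non-ACGTN characters: {sorted(bad)}"
                )

    def __getitem__(self, name: str) -> str:
        try:
            return self.contigs[name]
        except KeyError:
            raise ContigNotFoundError(name) from None

    def __contains__(self, name: str) -> bool:
        return name in self.contigs


def read_genome_fasta(path: str | Path) -> GenomeSource:
    """Read a (wrapped or unwrapped) multi-record FASTA into a GenomeSource."""
    contigs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in contigs:
            raise FormatError(f"duplicate contig name {record.id!r}")
        contigs[record.id] = str(record.seq).upper()
    if not contigs:
        raise FormatError(f"no FASTA records found in {path}")
    return GenomeSource(contigs)


@dataclass(frozen=True)
class TranscriptRecord:
    """One TSS-bearing transcript; ``tss`` is the 1-based coordinate of the
    first transcribed base on ``contig``."""

    transcript_id: str
    gene_symbol: str
    contig: str
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tss < 1:
            raise FormatError(f"tss must be >= 1, got {self.tss}")


def read_gene_table(path: str | Path) -> list[TranscriptRecord]:
    """Parse a refGene-like TSV with header columns
    transcript_id, gene_symbol, contig, strand, tss (extra columns ignored)."""
    records: list[TranscriptRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        missing = [c for c in GENE_TABLE_COLUMNS if c not in header]
        if missing:
            raise FormatError(
                f"gene table {path} is missing required column(s): {', '.join(missing)}"
            )
        for lineno, row in enumerate(reader, start=2):
            strand = (row["strand"] or "").strip()
            if strand not in ("+", "-"):
                raise FormatError(
                    f"{path} line {lineno}: strand must be '+' or '-', got {strand!r}"
                )
            try:
                tss = int((row["tss"] or "").strip())
            except ValueError:
                raise FormatError(
                    f"{path} line {lineno}: non-integer tss {row['tss']!r}"
                ) from None
            try:
                records.append(
                    TranscriptRecord(
                        transcript_id=row["transcript_id"].strip(),
                        gene_symbol=row["gene_symbol"].strip(),
                        contig=row["contig"].strip(),
                        strand=strand,
                        tss=tss,
                    )
                )
            except FormatError as exc:
                raise FormatError(f"{path} line {lineno}: {exc}") from None
    return records


@dataclass(frozen=True)
class WindowSpec:
    """Window bounds around the TSS: ``upstream`` untranscribed bases and
    ``downstream`` transcribed bases (the TSS base is position +1)."""

    upstream: int = 250
    downstream: int = 200

    def __post_init__(self) -> None:
        if self.upstream < 1 or self.downstream < 1:
            raise FormatError("window bounds must be positive integers")

    @property
    def length(self) -> int:
        return self.upstream + self.downstream

    def offset_to_signed(self, offset: int) -> int:
        """Map a 0-based window offset to a signed promoter coordinate
        (no position 0: ..., -2, -1, +1, +2, ...)."""
        if not 0 <= offset < self.length:
            raise ValueError(f"offset {offset} outside window of length {self.length}")
        return offset - self.upstream if offset < self.upstream else offset - self.upstream + 1

    def signed_to_offset(self, coord: int) -> int:
        if coord == 0:
            raise ValueError("signed promoter coordinates have no position 0")
        offset = coord + self.upstream if coord < 0 else coord + self.upstream - 1
        if not 0 <= offset < self.length:
            raise ValueError(f"coordinate {coord:+d} outside window")
        return offset

    def label(self) -> str:
        return f"-{self.upstream}..+{self.downstream}"


@dataclass
class PromoterWindow:
    """A 5'->3' transcription-oriented promoter sequence for one gene."""

    gene_symbol: str
    transcript_ids: tuple[str, ...]
    sequence: str
    window_spec: WindowSpec = field(default_factory=WindowSpec)

    def __post_init__(self) -> None:
        self.transcript_ids = tuple(self.transcript_ids)
        if len(self.sequence) != self.window_spec.length:
            raise FormatError(
                f"window for {self.gene_symbol} has length {len(self.sequence)}, "
                f"expected {self.window_spec.length}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def extract_window(
    genome: GenomeSource, rec: TranscriptRecord, spec: WindowSpec | None = None
) -> PromoterWindow:
    """Extract the oriented [-upstream,+downstream] window around ``rec``'s TSS.

    For a ``+`` strand transcript the window is contig bases
    ``[tss-upstream, tss+downstream-1]`` (1-based inclusive); for ``-`` the
    mirrored interval ``[tss-downstream+1, tss+upstream]`` reverse-complemented,
    so the returned string always reads 5'->3' in transcription direction with
    the TSS base at offset ``upstream``.
    """
    spec = spec or WindowSpec()
    contig_seq = genome[rec.contig]
    if rec.strand == "+":
        start, end = rec.tss - spec.upstream, rec.tss + spec.downstream - 1
    else:
        start, end = rec.tss - spec.downstream + 1, rec.tss + spec.upstream
    if start < 1 or end > len(contig_seq):
        raise BoundaryError(
            f"window [{start},{end}] for {rec.transcript_id} overhangs contig "
            f"{rec.contig} (length {len(contig_seq)})"
        )
    raw = contig_seq[start - 1 : end]
    sequence = raw if rec.strand == "+" else reverse_complement(raw)
    return PromoterWindow(
        gene_symbol=rec.gene_symbol,
        transcript_ids=(rec.transcript_id,),
        sequence=sequence,
        window_spec=spec,
    )


def dedupe_windows(windows: Iterable[PromoterWindow]) -> list[PromoterWindow]:
    """Merge windows with identical (gene_symbol, sequence) — redundant
    promoters from alternative splicing — keeping distinct alternative
    promoters of the same gene. First-seen order is preserved and transcript
    ids are unioned in first-seen order."""
    merged: dict[tuple[str, str], PromoterWindow] = {}
    for win in windows:
        key = (win.gene_symbol, win.sequence)
        if key in merged:
            existing = merged[key]
            new_ids = tuple(
                dict.fromkeys(existing.transcript_ids + win.transcript_ids)
            )
            existing.transcript_ids = new_ids
        else:
            merged[key] = PromoterWindow(
                gene_symbol=win.gene_symbol,
                transcript_ids=win.transcript_ids,
                sequence=win.sequence,
                window_spec=win.window_spec,
            )
    return list(merged.values())


def write_windows_fasta(windows: Iterable[PromoterWindow], path: str | Path) -> None:
    """Export windows as FASTA with ``gene|tid1,tid2|-250..+200`` headers."""
    with open(path, "w") as fh:
        for win in windows:
            header = f"{win.gene_symbol}|{','.join(win.transcript_ids)}|{win.window_spec.label()}"
            fh.write(f">{header}\n")
            for i in range(0, len(win.sequence), 70):
                fh.write(win.sequence[i : i + 70] + "\n")
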