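"""Sequence and anchor I/O plus the coordinate conventions used throughout.

Promoter positions are numbered relative to a transcription start site with
**no position 0**: +1 is the TSS base itself and −1 is the base immediately
upstream, so the interval −156..+46 spans 202 bp.  Internally all sequence
offsets are 1-based inclusive; BED input (0-based half-open) is converted on
read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

DNA_RESIDUES = frozenset("ACGTN")
PROTEIN_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

Alphabet = Literal["DNA", "protein"]


class SequenceError(ValueError):
    """Malformed sequence input (bad residue, empty record, parse failure)."""


class CoordinateError(ValueError):
    """Invalid promoter coordinate or out-of-window position."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA or protein sequence, uppercased and residue-validated."""

    id: str
    alphabet: Alphabet
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        if not self.residues:
            raise SequenceError(f"record {self.id!r}: empty sequence")
        allowed = DNA_RESIDUES if self.alphabet == "DNA" else PROTEIN_RESIDUES
        for i, ch in enumerate(self.residues, start=1):
            if ch not in allowed:
                raise SequenceError(
                    f"record {self.id!r}: illegal {self.alphabet} residue "
                    f"{ch!r} at position {i}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Anchor:
    """A 1-based anchor position (a TSS or processed-RNA 5' end) on a reference."""

    seq_id: str
    position: int
    strand: str = "+"
    label: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise CoordinateError(
                f"anchor {self.label or self.seq_id}: position must be >= 1, "
                f"got {self.position}"
            )
        if self.strand not in {"+", "-"}:
            raise CoordinateError(f"anchor strand must be '+' or '-', got {self.strand!r}")


def _check_promoter(value: int, name: str = "coordinate") -> int:
    if value == 0:
        raise CoordinateError(f"{name} 0 does not exist in promoter numbering")
    return int(value)


def interval_length(a: int, b: int) -> int:
    """Inclusive bp length of the promoter interval a..b, skipping position 0.

    Same sign: ``|b - a| + 1``; spanning the TSS (a < 0 < b): ``(-a) + b``.
    The competitor −124..−75 is 50 bp; the probe −156..+46 is 202 bp.
    """
    a = _check_promoter(a, "start")
    b = _check_promoter(b, "end")
    if (a < 0 < b) or (b < 0 < a):
        lo, hi = min(a, b), max(a, b)
        return (-lo) + hi
    return abs(b - a) + 1


def promoter_to_offset(c: int, window_start: int) -> int:
    """1-based offset of promoter position ``c`` within a window starting at
    ``window_start`` (both in no-zero promoter numbering)."""
    c = _check_promoter(c)
    window_start = _check_promoter(window_start, "window start")
    if _promoter_rank(c) < _promoter_rank(window_start):
        raise CoordinateError(f"position {c} lies before window start {window_start}")
    return interval_length(window_start, c)


def offset_to_promoter(offset: int, window_start: int) -> int:
    """Inverse of :func:`promoter_to_offset`."""
    if offset < 1:
        raise CoordinateError(f"offset must be >= 1, got {offset}")
    window_start = _check_promoter(window_start, "window start")
    rank = _promoter_rank(window_start) + offset - 1
    return _rank_to_promoter(rank)


def _promoter_rank(c: int) -> int:
    # Map ...,-2,-1,+1,+2,... onto consecutive integers ...,-2,-1,0,1,...
    return c if c < 0 else c - 1


def _rank_to_promoter(rank: int) -> int:
    return rank if rank < 0 else rank + 1


def reverse_complement(record: SequenceRecord) -> SequenceRecord:
    """Reverse complement of a DNA record (N maps to N)."""
    if record.alphabet != "DNA":
        raise SequenceError(f"record {record.id!r}: reverse complement requires DNA")
    return SequenceRecord(
        id=record.id,
        alphabet="DNA",
        residues=record.residues.translate(_COMPLEMENT)[::-1],
    )


def revcomp_str(s: str) -> str:
    """Reverse complement of a plain DNA string (helper for motif code)."""
    return s.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceWindow:
    """A flank window around an anchor, with the bookkeeping needed to report
    window offsets back in promoter numbering.

    ``genomic_start``/``genomic_end`` are 1-based inclusive on the reference.
    For a − strand anchor the stored record is the reverse complement and
    offsets run along the annotated direction.
    """

    record: SequenceRecord
    anchor: Anchor
    genomic_start: int
    genomic_end: int

    def __len__(self) -> int:
        return len(self.record)

    def offset_to_genomic(self, offset: int) -> int:
        if not 1 <= offset <= len(self):
            raise CoordinateError(f"offset {offset} outside window of length {len(self)}")
        if self.anchor.strand == "+":
            return self.genomic_start + offset - 1
        return self.genomic_end - offset + 1

    def offset_to_promoter(self, offset: int) -> int:
        """No-zero promoter coordinate of a window offset relative to the anchor."""
        g = self.offset_to_genomic(offset)
        if self.anchor.strand == "+":
            d = g - self.anchor.position
        else:
            d = self.anchor.position - g
        return d + 1 if d >= 0 else d


def extract_window(
    ref: SequenceRecord, anchor: Anchor, flank: int = 1000
) -> SequenceWindow:
    """Extract ``[position - flank, position + flank]`` clipped to the sequence.

    Clipping (rather than erroring) matters for short references such as an
    rDNA repeat unit, where ±1 kb flanks routinely run off an end; the achieved
    window length feeds the per-kb density denominator.
    """
    if flank < 0:
        raise CoordinateError(f"flank must be >= 0, got {flank}")
    if not 1 <= anchor.position <= len(ref):
        raise CoordinateError(
            f"anchor at {anchor.position} falls outside sequence "
            f"{ref.id!r} of length {len(ref)}"
        )
    start = max(1, anchor.position - flank)
    end = min(len(ref), anchor.position + flank)
    sub = ref.residues[start - 1 : end]
    if anchor.strand == "-":
        sub = revcomp_str(sub)
    rec = SequenceRecord(id=f"{ref.id}:{start}-{end}({anchor.strand})",
                         alphabet="DNA", residues=sub)
    return SequenceWindow(record=rec, anchor=anchor,
                          genomic_start=start, genomic_end=end)


# ---------------------------------------------------------------------------
# File I/O


def read_fasta(path: str | Path, alphabet: Alphabet = "DNA") -> list[SequenceRecord]:
    """Read a FASTA file into validated records.

    Record ids are the first whitespace-delimited header token; residues are
    uppercased with line breaks removed.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise SequenceError(f"{path}: empty FASTA file")
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip():
            if not line.startswith(">"):
                raise SequenceError(
                    f"{path}: line {lineno}: sequence data before first header"
                )
            break
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(SequenceRecord(id=rec.id, alphabet=alphabet,
                                      residues=str(rec.seq)))
    if not records:
        raise SequenceError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 70) -> None:
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def read_anchors_tsv(path: str | Path) -> list[Anchor]:
    """Read anchors from TSV with columns seq_id, position (1-based), strand, label."""
    df = pd.read_csv(path, sep="\t", dtype={"seq_id": str, "label": str})
    required = {"seq_id", "position", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise CoordinateError(f"{path}: anchor TSV missing columns {sorted(missing)}")
    if "label" not in df.columns:
        df["label"] = ""
    return [
        Anchor(seq_id=row.seq_id, position=int(row.position),
               strand=row.strand, label="" if pd.isna(row.label) else str(row.label))
        for row in df.itertuples()
    ]


def read_anchors_bed(path: str | Path) -> list[Anchor]:
    """Read anchors from BED (0-based half-open); the anchor is the interval
    start for + strand features and the interval end for − strand features,
    converted to 1-based."""
    anchors = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise CoordinateError(f"{path}: line {lineno}: fewer than 3 BED columns")
            chrom, start0, end0 = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else ""
            strand = parts[5] if len(parts) > 5 else "+"
            pos = start0 + 1 if strand == "+" else end0
            anchors.append(Anchor(seq_id=chrom, position=pos, strand=strand, label=name))
    return anchors
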