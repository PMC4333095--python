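"""Degenerate gapped-motif scanning: two half-sites separated by a variable spacer.

The zinc transcriptional regulatory element (ZTRE) is the motivating case: a
near-palindromic element whose 7-nt and 6-nt half-sites flank a spacer of 0–50
arbitrary bases.  Matching is set-membership per position (no scoring); N in
the scanned text matches nothing; both strands are scanned by default and
matches on the reverse strand are reported on forward-text coordinates.  A
*footprint* is the unique (start, end) interval of one or more matches and is
the unit in which element copies are counted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

from .sequence_io import SequenceRecord

_COMPLEMENT_BASE = {"A": "T", "C": "G", "G": "C", "T": "A"}


class MotifError(ValueError):
    """Invalid motif definition or gap classification input."""


@dataclass(frozen=True)
class HalfSitePattern:
    """Ordered per-position residue sets over {A,C,G,T}."""

    positions: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if not self.positions:
            raise MotifError("half-site must have at least one position")
        for i, s in enumerate(self.positions, start=1):
            if not s or not s <= {"A", "C", "G", "T"}:
                raise MotifError(
                    f"half-site position {i}: residue set must be a non-empty "
                    f"subset of ACGT, got {sorted(s)}"
                )

    def __len__(self) -> int:
        return len(self.positions)

    @classmethod
    def from_string(cls, notation: str) -> "HalfSitePattern":
        """Parse a dash-separated set notation, e.g. ``C-A/C-C-T/A/G-C-C-T/C``."""
        sets = []
        for token in notation.upper().split("-"):
            sets.append(frozenset(token.split("/")))
        return cls(tuple(sets))

    def to_string(self) -> str:
        return "-".join("/".join(sorted(s)) for s in self.positions)

    def matches_at(self, text: str, start0: int) -> bool:
        """True if the half-site matches ``text`` at 0-based ``start0``."""
        if start0 < 0 or start0 + len(self) > len(text):
            return False
        for s, ch in zip(self.positions, text[start0 : start0 + len(self)]):
            if ch not in s:
                return False
        return True

    def reverse_complement(self) -> "HalfSitePattern":
        comp = tuple(
            frozenset(_COMPLEMENT_BASE[b] for b in s)
            for s in reversed(self.positions)
        )
        return HalfSitePattern(comp)


@dataclass(frozen=True)
class GappedMotif:
    """Two ordered half-sites with an integer spacer range."""

    left: HalfSitePattern
    right: HalfSitePattern
    gap_min: int = 0
    gap_max: int = 50

    def __post_init__(self) -> None:
        if self.gap_min < 0 or self.gap_max < self.gap_min:
            raise MotifError(
                f"invalid gap range [{self.gap_min}, {self.gap_max}]"
            )

    def span_length(self, gap_len: int) -> int:
        return len(self.left) + gap_len + len(self.right)


def compile_ztre(gap_min: int = 0, gap_max: int = 50) -> GappedMotif:
    """The ZTRE consensus: C-[A/C]-C-[T/A/G]-C-C-[T/C] ... N(0-50) ... [G/A]-G-[A/T/C]-G-[T/G]-G."""
    left = HalfSitePattern.from_string("C-A/C-C-T/A/G-C-C-T/C")
    right = HalfSitePattern.from_string("G/A-G-A/T/C-G-T/G-G")
    return GappedMotif(left=left, right=right, gap_min=gap_min, gap_max=gap_max)


def motif_from_json(path: str | Path) -> GappedMotif:
    """Load a motif from a small JSON config with keys left, right, gap_min, gap_max."""
    cfg = json.loads(Path(path).read_text())
    return GappedMotif(
        left=HalfSitePattern.from_string(cfg["left"]),
        right=HalfSitePattern.from_string(cfg["right"]),
        gap_min=int(cfg.get("gap_min", 0)),
        gap_max=int(cfg.get("gap_max", 50)),
    )


def reverse_complement_motif(m: GappedMotif) -> GappedMotif:
    """Motif that matches the reverse complement: swap and revcomp the half-sites."""
    return GappedMotif(
        left=m.right.reverse_complement(),
        right=m.left.reverse_complement(),
        gap_min=m.gap_min,
        gap_max=m.gap_max,
    )


@dataclass(frozen=True, order=True)
class MotifMatch:
    """One (start, gap, strand) parse; coordinates 1-based inclusive on the
    forward text regardless of strand."""

    seq_id: str
    start: int
    end: int
    strand: str
    gap_len: int
    matched: str


@dataclass(frozen=True)
class MotifFootprint:
    """The unique interval of one or more matches; the counted 'copy'."""

    seq_id: str
    start: int
    end: int
    strands: frozenset[str]
    gap_len: int

    @property
    def strands_str(self) -> str:
        return "".join(s for s in "+-" if s in self.strands)


def _half_site_hits(text: str, pattern: HalfSitePattern) -> list[bool]:
    n = len(text)
    w = len(pattern)
    return [pattern.matches_at(text, i) for i in range(n - w + 1)] if n >= w else []


def _scan_one_strand(
    text: str, seq_id: str, m: GappedMotif, strand: str
) -> list[MotifMatch]:
    motif = m if strand == "+" else reverse_complement_motif(m)
    left_hits = _half_site_hits(text, motif.left)
    right_hits = _half_site_hits(text, motif.right)
    lw, rw = len(motif.left), len(motif.right)
    out = []
    for i, ok in enumerate(left_hits):
        if not ok:
            continue
        for gap in range(m.gap_min, m.gap_max + 1):
            j = i + lw + gap
            if j >= len(right_hits):  # right half would run off the sequence
                break
            if right_hits[j]:
                start = i + 1
                end = j + rw
                out.append(
                    MotifMatch(
                        seq_id=seq_id,
                        start=start,
                        end=end,
                        strand=strand,
                        gap_len=gap,
                        matched=text[i:end],
                    )
                )
    return out


def scan(
    seq: SequenceRecord,
    m: GappedMotif | None = None,
    strands: Literal["+", "-", "both"] = "both",
) -> list[MotifMatch]:
    """All (start, gap, strand) parses of the motif on the sequence.

    Reverse-strand matches are found by scanning the forward text with the
    reverse-complemented motif, so their coordinates need no conversion.
    Matching is case-insensitive (records are uppercased on construction) and
    N never matches.  Sorted by (start, end, strand).
    """
    if seq.alphabet != "DNA":
        raise MotifError(f"record {seq.id!r}: motif scanning requires DNA")
    if m is None:
        m = compile_ztre()
    text = seq.residues
    out: list[MotifMatch] = []
    if strands in ("+", "both"):
        out.extend(_scan_one_strand(text, seq.id, m, "+"))
    if strands in ("-", "both"):
        out.extend(_scan_one_strand(text, seq.id, m, "-"))
    out.sort(key=lambda x: (x.start, x.end, x.strand))
    return out


def dedupe_footprints(matches: Iterable[MotifMatch]) -> list[MotifFootprint]:
    """Collapse matches sharing a (start, end) interval into one footprint.

    A palindromic site typically matches on both strands; counting footprints
    rather than matches avoids double counting.  The footprint's canonical gap
    is that of the lexicographically smallest (strand, gap) parse ('+' sorts
    before '-').
    """
    by_interval: dict[tuple[str, int, int], list[MotifMatch]] = {}
    for match in matches:
        by_interval.setdefault((match.seq_id, match.start, match.end), []).append(match)
    footprints = []
    for (seq_id, start, end), group in sorted(by_interval.items()):
        canonical = min(group, key=lambda x: (x.strand, x.gap_len))
        footprints.append(
            MotifFootprint(
                seq_id=seq_id,
                start=start,
                end=end,
                strands=frozenset(x.strand for x in group),
                gap_len=canonical.gap_len,
            )
        )
    return footprints


def classify_gap(footprint_or_gap: MotifFootprint | int) -> str:
    """'short' for spacers under 30 nt, 'long' for 30–50 nt."""
    gap = (
        footprint_or_gap.gap_len
        if isinstance(footprint_or_gap, MotifFootprint)
        else int(footprint_or_gap)
    )
    if not 0 <= gap <= 50:
        raise MotifError(f"gap {gap} outside the classifiable range [0, 50]")
    return "short" if gap < 30 else "long"
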