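"""C2H2-type zinc-finger annotation by spacing pattern.

A classical C2H2 finger is detected as the 21-residue pattern
C-X2-C-X12-H-X3-H: the four metal-coordinating residues sit at window
positions 1, 4, 17 and 21.  Two non-canonical configurations seen in natural
tandem arrays are supported behind a flag: an H in place of the first C
(His-Cys-His2) and an R in place of the final H (Cys2-His-Arg).  Overlapping
candidate windows are resolved greedily left to right, the way tandem finger
arrays tile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .sequence_io import SequenceRecord, SequenceError

CANONICAL = "canonical C2H2"
VARIANT_POS1 = "H-C-H2 variant"
VARIANT_POS21 = "C2-H-R variant"


@dataclass(frozen=True)
class ZincFingerPattern:
    """Spacing pattern for one finger; spacers are exact lengths."""

    pos1_set: frozenset[str] = frozenset("C")
    spacer1: int = 2
    pos2_set: frozenset[str] = frozenset("C")
    spacer2: int = 12
    pos3_set: frozenset[str] = frozenset("H")
    spacer3: int = 3
    pos4_set: frozenset[str] = frozenset("H")
    allow_H_at_pos1: bool = True
    allow_R_at_pos4: bool = True

    @property
    def window(self) -> int:
        return 4 + self.spacer1 + self.spacer2 + self.spacer3

    def coordinating_offsets(self) -> tuple[int, int, int, int]:
        """0-based offsets of the four coordinating residues within the window."""
        a = 0
        b = a + 1 + self.spacer1
        c = b + 1 + self.spacer2
        d = c + 1 + self.spacer3
        return a, b, c, d


@dataclass(frozen=True)
class ZincFingerAnnotation:
    index: int
    start: int  # 1-based inclusive
    end: int
    configuration: str
    sequence: str


def scan_zinc_fingers(
    protein: SequenceRecord,
    pattern: ZincFingerPattern | None = None,
    allow_variants: bool = True,
) -> list[ZincFingerAnnotation]:
    """Greedy left-to-right annotation of non-overlapping finger windows.

    With ``allow_variants`` the first coordinating position may be H and the
    last may be R; each annotated window is classified by which sets matched.
    """
    if protein.alphabet != "protein":
        raise SequenceError(
            f"record {protein.id!r}: zinc-finger scan requires a protein sequence"
        )
    if pattern is None:
        pattern = ZincFingerPattern()
    p1 = set(pattern.pos1_set)
    p4 = set(pattern.pos4_set)
    if allow_variants:
        if pattern.allow_H_at_pos1:
            p1 |= {"H"}
        if pattern.allow_R_at_pos4:
            p4 |= {"R"}
    o1, o2, o3, o4 = pattern.coordinating_offsets()
    w = pattern.window
    seq = protein.residues
    out: list[ZincFingerAnnotation] = []
    i = 0
    while i + w <= len(seq):
        if (
            seq[i + o1] in p1
            and seq[i + o2] in pattern.pos2_set
            and seq[i + o3] in pattern.pos3_set
            and seq[i + o4] in p4
        ):
            config = CANONICAL
            if seq[i + o1] not in pattern.pos1_set:
                config = VARIANT_POS1
            elif seq[i + o4] not in pattern.pos4_set:
                config = VARIANT_POS21
            out.append(
                ZincFingerAnnotation(
                    index=len(out) + 1,
                    start=i + 1,
                    end=i + w,
                    configuration=config,
                    sequence=seq[i : i + w],
                )
            )
            i += w  # fingers tile without overlap
        else:
            i += 1
    return out


def finger_summary(annotations: Sequence[ZincFingerAnnotation]) -> dict[str, int]:
    """Total and per-configuration counts."""
    summary = {"total": len(annotations), CANONICAL: 0, VARIANT_POS1: 0, VARIANT_POS21: 0}
    for ann in annotations:
        summary[ann.configuration] = summary.get(ann.configuration, 0) + 1
    return summary
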