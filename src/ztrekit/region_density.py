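"""Motif density over anchor windows: merged mapped regions, per-kb counts,
and target-vs-nearest-neighbor comparisons.

The analysis mirrors how clustered regulatory elements are summarised around
transcription start sites: flank windows around a set of anchors are merged
into disjoint mapped regions, element footprints falling entirely inside a
mapped region are counted, and counts are normalised per kilobase of mapped
sequence so groups with different mapped extents are comparable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .motif_scan import MotifFootprint
from .sequence_io import Anchor, CoordinateError


@dataclass(frozen=True)
class MappedRegionSet:
    """Disjoint, sorted, 1-based inclusive intervals from merged anchor windows."""

    seq_id: str
    intervals: tuple[tuple[int, int], ...]

    @property
    def total_length(self) -> int:
        return sum(e - s + 1 for s, e in self.intervals)


@dataclass(frozen=True)
class DensityReport:
    group: str
    n_footprints: int
    mapped_bp: int

    @property
    def mapped_kb(self) -> float:
        return self.mapped_bp / 1000.0

    @property
    def density_per_kb(self) -> float:
        return density_per_kb(self.n_footprints, self.mapped_bp)


def build_mapped_regions(
    anchors: Sequence[Anchor], seq_len: int, flank: int = 1000
) -> MappedRegionSet:
    """Merge the clipped ``[pos - flank, pos + flank]`` windows of the anchors.

    Overlapping windows collapse into one interval, so the total mapped length
    is the denominator the per-kb densities expect.
    """
    if not anchors:
        return MappedRegionSet(seq_id="", intervals=())
    seq_ids = {a.seq_id for a in anchors}
    if len(seq_ids) > 1:
        raise CoordinateError(f"anchors span multiple sequences: {sorted(seq_ids)}")
    windows = []
    for a in anchors:
        if not 1 <= a.position <= seq_len:
            raise CoordinateError(
                f"anchor {a.label or a.seq_id} at {a.position} outside sequence of "
                f"length {seq_len}"
            )
        windows.append((max(1, a.position - flank), min(seq_len, a.position + flank)))
    windows.sort()
    merged = [list(windows[0])]
    for s, e in windows[1:]:
        if s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return MappedRegionSet(
        seq_id=anchors[0].seq_id, intervals=tuple((s, e) for s, e in merged)
    )


def count_footprints(
    regions: MappedRegionSet, footprints: Iterable[MotifFootprint]
) -> int:
    """Number of footprints lying entirely within some mapped interval.

    Containment (not mere overlap) is the membership rule: a motif only partly
    inside the mapped sequence was not fully observed there.
    """
    n = 0
    for fp in footprints:
        if any(s <= fp.start and fp.end <= e for s, e in regions.intervals):
            n += 1
    return n


def density_per_kb(n: int, mapped_length_bp: int) -> float:
    """Footprints per kilobase of mapped sequence; e.g. 10 in 14 kb = 0.71/kb."""
    if mapped_length_bp <= 0:
        raise CoordinateError("mapped length must be positive for a density")
    return n / (mapped_length_bp / 1000.0)


def nearest_neighbor(
    targets: Sequence[int], annotation: Sequence[int]
) -> list[tuple[int, int]]:
    """Pair each target TSS with the closest annotation TSS (TSS-to-TSS distance).

    Ties break toward the smaller coordinate, so the pairing is deterministic.
    The annotation list must exclude the targets themselves.
    """
    if not annotation:
        raise CoordinateError("annotation TSS list is empty")
    cand = sorted(annotation)
    pairs = []
    for t in targets:
        best = min(cand, key=lambda c: (abs(c - t), c))
        pairs.append((t, best))
    return pairs


def compare_groups(
    reports: Sequence[DensityReport], reference: str
) -> list[dict]:
    """Density ratio of each group to a designated reference group.

    Ratios are taken between the two-decimal reported densities, matching the
    arithmetic of a figure legend that quotes densities to two decimals.
    """
    if len(reports) < 2:
        raise CoordinateError("need at least two density reports to compare")
    by_group = {r.group: r for r in reports}
    if reference not in by_group:
        raise CoordinateError(f"reference group {reference!r} not among reports")
    ref_density = round(by_group[reference].density_per_kb, 2)
    rows = []
    for r in reports:
        density = round(r.density_per_kb, 2)
        if ref_density == 0:
            ratio, defined = math.nan, False
        else:
            ratio, defined = density / ref_density, True
        rows.append(
            {
                "group": r.group,
                "n_footprints": r.n_footprints,
                "mapped_kb": round(r.mapped_kb, 3),
                "density_per_kb": density,
                "ratio_to_reference": round(ratio, 2) if defined else None,
                "ratio_defined": defined,
            }
        )
    return rows
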