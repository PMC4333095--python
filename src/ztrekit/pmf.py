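"""Peptide-mass-fingerprint arithmetic: in-silico trypsin digestion,
monoisotopic masses, ppm-tolerance peak matching and sequence coverage.

Trypsin cleaves C-terminal to K or R except before proline (the Keil rule);
fragments carry their parent-sequence span and missed-cleavage count so
coverage can be computed as a union of matched spans.  Peaks are compared as
singly protonated [M+H]+ ions, the species a MALDI reflector instrument
reports, within a configurable ppm tolerance and scanned mass range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from pyteomics import mass as _ptmass

from .sequence_io import SequenceRecord, SequenceError

WATER_MONO = 18.010565
PROTON_MONO = 1.007276


@dataclass(frozen=True)
class ResidueMassTable:
    """Monoisotopic residue masses (Da) with optional fixed modifications.

    Defaults come from the standard amino-acid residue-mass table; a fixed
    modification (e.g. carbamidomethyl C, +57.02146) is a per-residue offset.
    """

    masses: Mapping[str, float] = field(
        default_factory=lambda: {
            aa: _ptmass.std_aa_mass[aa] for aa in "ACDEFGHIKLMNPQRSTVWY"
        }
    )
    fixed_mods: Mapping[str, float] = field(default_factory=dict)
    water: float = WATER_MONO
    proton: float = PROTON_MONO

    def residue_mass(self, aa: str) -> float:
        if aa not in self.masses:
            raise SequenceError(f"unknown amino-acid residue {aa!r}")
        return self.masses[aa] + self.fixed_mods.get(aa, 0.0)


@dataclass(frozen=True)
class PeptideFragment:
    """A digestion product with its span on the parent (1-based inclusive)."""

    sequence: str
    start: int
    end: int
    missed_cleavages: int
    neutral_mass: float

    @property
    def mh_plus(self) -> float:
        return self.neutral_mass + PROTON_MONO


@dataclass(frozen=True)
class PeakMatch:
    observed_mz: float
    fragment: PeptideFragment
    error_ppm: float


def peptide_mass(sequence: str, table: ResidueMassTable | None = None) -> float:
    """Neutral monoisotopic mass: sum of residue masses plus one water."""
    if table is None:
        table = ResidueMassTable()
    if not sequence:
        raise SequenceError("cannot compute the mass of an empty peptide")
    return sum(table.residue_mass(aa) for aa in sequence.upper()) + table.water


def digest(
    protein: SequenceRecord,
    missed_cleavages: int = 0,
    keil_rule: bool = True,
    table: ResidueMassTable | None = None,
) -> list[PeptideFragment]:
    """Tryptic fragments of a protein, with spans, missed-cleavage counts and masses.

    With ``missed_cleavages = m``, every concatenation of up to m+1 adjacent
    fully cleaved fragments is also emitted.  The zero-missed fragments tile
    the parent exactly.
    """
    if protein.alphabet != "protein":
        raise SequenceError(f"record {protein.id!r}: digestion requires a protein")
    if table is None:
        table = ResidueMassTable()
    seq = protein.residues
    cut_after = []  # 0-based index of last residue of each fully cleaved fragment
    for i, aa in enumerate(seq[:-1]):
        if aa in "KR" and not (keil_rule and seq[i + 1] == "P"):
            cut_after.append(i)
    bounds = [0] + [c + 1 for c in cut_after] + [len(seq)]
    base = [(bounds[k], bounds[k + 1]) for k in range(len(bounds) - 1)]
    fragments = []
    for k in range(len(base)):
        for m in range(0, missed_cleavages + 1):
            if k + m >= len(base):
                break
            s = base[k][0]
            e = base[k + m][1]
            pep = seq[s:e]
            fragments.append(
                PeptideFragment(
                    sequence=pep,
                    start=s + 1,
                    end=e,
                    missed_cleavages=m,
                    neutral_mass=peptide_mass(pep, table),
                )
            )
    fragments.sort(key=lambda f: (f.start, f.end))
    return fragments


def match_peaks(
    peaks: Sequence[float],
    fragments: Sequence[PeptideFragment],
    tolerance_ppm: float = 50.0,
    mass_range: tuple[float, float] = (900.0, 4000.0),
    compare_neutral: bool = False,
) -> list[PeakMatch]:
    """Best fragment assignment for each observed m/z within tolerance.

    A peak matches a fragment when |observed − theoretical| / theoretical ×
    10⁶ ≤ tolerance (boundary inclusive) and the theoretical mass lies in the
    scanned range.  Each peak gets its smallest-|ppm| match; ties break toward
    the fragment with the smaller start.  ``compare_neutral`` switches the
    theoretical mass from [M+H]+ to the neutral monoisotopic mass.
    """
    lo, hi = mass_range
    candidates = []
    for frag in fragments:
        theo = frag.neutral_mass if compare_neutral else frag.mh_plus
        if lo <= theo <= hi:
            candidates.append((theo, frag))
    out = []
    for mz in peaks:
        if mz <= 0:
            raise SequenceError(f"observed m/z must be positive, got {mz}")
        best: tuple[float, int, PeptideFragment] | None = None
        for theo, frag in candidates:
            ppm = (mz - theo) / theo * 1e6
            if abs(ppm) <= tolerance_ppm:
                key = (abs(ppm), frag.start)
                if best is None or key < (abs(best[0]), best[1]):
                    best = (ppm, frag.start, frag)
        if best is not None:
            out.append(PeakMatch(observed_mz=mz, fragment=best[2], error_ppm=best[0]))
    return out


def coverage(
    matches: Sequence[PeakMatch],
    protein_length: int,
    n_total_fragments: int | None = None,
) -> dict:
    """Sequence coverage from the union of matched fragment spans."""
    covered: set[int] = set()
    matched_frags = {(m.fragment.start, m.fragment.end) for m in matches}
    for s, e in matched_frags:
        covered.update(range(s, e + 1))
    return {
        "covered_residues": len(covered),
        "fraction": len(covered) / protein_length if protein_length else 0.0,
        "n_matched_fragments": len(matched_frags),
        "n_total_fragments": n_total_fragments,
    }
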