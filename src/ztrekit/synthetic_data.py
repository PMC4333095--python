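"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator draws from a single seeded :class:`numpy.random.Generator` and
returns the generated objects together with a *truth manifest* (a plain dict)
recording exactly what was planted, so downstream recovery can be scored
automatically.  Backgrounds that must not contain accidental pattern hits are
rejection-sampled: the generated sequence is re-drawn until a full scan finds
nothing but the planted features, which makes recovery assertions exact
rather than probabilistic.
"""

from __future__ import annotations

import itertools
from typing import Sequence

import numpy as np
import pandas as pd

from . import motif_scan, pmf, protein_domains
from .expression_stats import ExpressionMatrix
from .motif_scan import GappedMotif, compile_ztre
from .sequence_io import Anchor, SequenceRecord, revcomp_str


class GenerationError(ValueError):
    """Infeasible generator configuration (overlapping plants, impossible decoys)."""


_DNA = np.array(list("ACGT"))


def _random_dna(rng: np.random.Generator, length: int, gc_fraction: float = 0.5) -> str:
    p_gc = gc_fraction / 2.0
    p_at = (1.0 - gc_fraction) / 2.0
    return "".join(rng.choice(_DNA, size=length, p=[p_at, p_gc, p_gc, p_at]))


def _sample_half_site(rng: np.random.Generator, half) -> str:
    return "".join(rng.choice(sorted(s)) for s in half.positions)


def sample_motif_instance(
    rng: np.random.Generator, motif: GappedMotif, gap_len: int, strand: str = "+"
) -> str:
    """A concrete sequence matching the motif with the given spacer length.

    For the reverse strand the instance is reverse-complemented so that it is
    found as a − strand match on the forward text.
    """
    inst = (
        _sample_half_site(rng, motif.left)
        + _random_dna(rng, gap_len)
        + _sample_half_site(rng, motif.right)
    )
    return revcomp_str(inst) if strand == "-" else inst


def make_dna_with_ztres(
    length: int,
    plants: Sequence[tuple[int, int, str]] = (),
    gc_fraction: float = 0.5,
    motif: GappedMotif | None = None,
    seed: int | np.random.Generator = 0,
    max_tries: int = 200,
    seq_id: str = "synthetic_dna",
) -> tuple[SequenceRecord, dict]:
    """Random DNA with concrete motif instances planted at known positions.

    ``plants`` is a list of (position, gap_len, strand) with 1-based positions.
    Plants whose gap exceeds the motif's gap range are emitted but flagged
    invalid in the manifest (negative controls).  The background is re-drawn
    until a both-strand scan recovers exactly the valid planted footprints.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if motif is None:
        motif = compile_ztre()
    spans = []
    for pos, gap, strand in plants:
        span = motif.span_length(gap)
        if pos < 1 or pos + span - 1 > length:
            raise GenerationError(f"plant at {pos} (gap {gap}) exceeds length {length}")
        spans.append((pos, pos + span - 1, gap, strand))
    spans.sort()
    for (s1, e1, *_), (s2, *_rest) in zip(spans, spans[1:]):
        if s2 <= e1:
            raise GenerationError(f"planted motifs overlap at positions {s1} and {s2}")
    valid = [
        (s, e, g, st) for s, e, g, st in spans if motif.gap_min <= g <= motif.gap_max
    ]
    wide = GappedMotif(motif.left, motif.right, motif.gap_min, motif.gap_max)
    for _ in range(max_tries):
        seq = list(_random_dna(rng, length, gc_fraction))
        for s, e, g, st in spans:
            inst = sample_motif_instance(rng, motif, g, st)
            seq[s - 1 : e] = inst
        record = SequenceRecord(id=seq_id, alphabet="DNA", residues="".join(seq))
        found = {
            (fp.start, fp.end)
            for fp in motif_scan.dedupe_footprints(motif_scan.scan(record, wide))
        }
        if found == {(s, e) for s, e, _, _ in valid}:
            manifest = {
                "length": length,
                "planted": [
                    {"start": s, "end": e, "gap_len": g, "strand": st,
                     "valid": motif.gap_min <= g <= motif.gap_max}
                    for s, e, g, st in spans
                ],
            }
            return record, manifest
    raise GenerationError(
        f"could not draw an accidental-hit-free background in {max_tries} tries"
    )


def make_anchor_panel(
    n_targets: int = 10,
    n_neighbors: int = 10,
    target_density_per_kb: float = 0.7,
    background_density_per_kb: float = 0.15,
    flank: int = 1000,
    motif: GappedMotif | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[SequenceRecord, list[Anchor], dict[str, str], dict]:
    """A reference with target and neighbor anchor windows at contrasting
    motif densities.

    Each anchor window is a disjoint 2·flank+1 segment seeded with a
    Poisson(density × window_kb) number of motif instances; segments are
    separated by runs of N so no motif can arise in, or span into, the filler.
    Returns (reference, anchors, anchor-label→group map, manifest).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if motif is None:
        motif = compile_ztre()
    if min(target_density_per_kb, background_density_per_kb) < 0:
        raise GenerationError("densities must be non-negative")
    window_len = 2 * flank + 1
    spacer = "N" * 60
    segments: list[str] = []
    anchors: list[Anchor] = []
    groups: dict[str, str] = {}
    truth = []
    offset = 0
    panel = [("target", i) for i in range(n_targets)] + [
        ("neighbor", i) for i in range(n_neighbors)
    ]
    for group, i in panel:
        density = target_density_per_kb if group == "target" else background_density_per_kb
        n_plant = int(rng.poisson(density * window_len / 1000.0))
        # place non-overlapping plants with short spacers so they always fit
        for _ in range(20):
            gaps = rng.integers(motif.gap_min, min(motif.gap_max, 10) + 1, size=n_plant)
            span_total = sum(motif.span_length(int(g)) for g in gaps)
            if span_total <= window_len // 2:
                break
        else:
            raise GenerationError("requested density too high for the window size")
        positions = _place_nonoverlapping(
            rng, window_len, [motif.span_length(int(g)) for g in gaps],
            min_separation=motif.gap_max + len(motif.left) + len(motif.right) + 10,
        )
        plants = [
            (int(p), int(g), rng.choice(["+", "-"]))
            for p, g in zip(positions, gaps)
        ]
        seg_rec, seg_manifest = make_dna_with_ztres(
            window_len, plants, motif=motif, seed=rng, seq_id=f"win_{group}_{i}"
        )
        label = f"{group}_{i}"
        anchors.append(
            Anchor(seq_id="panel", position=offset + flank + 1, strand="+", label=label)
        )
        groups[label] = group
        truth.append(
            {"label": label, "group": group, "window_start": offset + 1,
             "n_planted": n_plant,
             "planted": [
                 {**p, "start": p["start"] + offset, "end": p["end"] + offset}
                 for p in seg_manifest["planted"]
             ]}
        )
        segments.append(seg_rec.residues)
        offset += window_len + len(spacer)
    reference = SequenceRecord(
        id="panel", alphabet="DNA", residues=spacer.join(segments) if segments else "N"
    )
    manifest = {
        "flank": flank,
        "target_density_per_kb": target_density_per_kb,
        "background_density_per_kb": background_density_per_kb,
        "windows": truth,
        "n_planted_target": sum(t["n_planted"] for t in truth if t["group"] == "target"),
        "n_planted_neighbor": sum(t["n_planted"] for t in truth if t["group"] == "neighbor"),
    }
    return reference, anchors, groups, manifest


def _place_nonoverlapping(
    rng: np.random.Generator,
    window_len: int,
    span_lengths: Sequence[int],
    min_separation: int = 0,
) -> list[int]:
    """1-based non-overlapping start positions for spans inside a window.

    ``min_separation`` keeps plants far enough apart that half-sites of two
    different plants cannot combine into an extra gapped match between them.
    """
    n = len(span_lengths)
    if n == 0:
        return []
    total = sum(span_lengths) + min_separation * (n - 1)
    slack = window_len - total
    if slack < 0:
        raise GenerationError("plants do not fit in the window")
    cuts = np.sort(rng.integers(0, slack + 1, size=n))
    positions = []
    consumed = 0
    for k, (cut, span) in enumerate(zip(cuts, span_lengths)):
        positions.append(int(cut) + consumed + 1)
        consumed += span + (min_separation if k < n - 1 else 0)
    return positions


_FINGER_FILLER = np.array(list("ADEFGILMNQSTVWY"))  # no C/H/K/P/R


def make_protein_with_fingers(
    length: int = 600,
    planted: Sequence[tuple[int, str]] = (),
    k_r_fraction: float = 0.0,
    seed: int | np.random.Generator = 0,
    max_tries: int = 200,
    seq_id: str = "synthetic_protein",
) -> tuple[SequenceRecord, dict]:
    """A protein with zinc fingers planted at known 1-based positions.

    ``planted`` holds (position, configuration) pairs where configuration is
    one of the classes in :mod:`ztrekit.protein_domains`.  The background is
    drawn from residues that cannot form the pattern, with K/R sprinkled in at
    ``k_r_fraction`` so tryptic-digest tests get predictable cleavage sites;
    the result is rejection-checked so a scan recovers exactly the plants.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pattern = protein_domains.ZincFingerPattern()
    w = pattern.window
    spans = sorted((pos, pos + w - 1, cfg) for pos, cfg in planted)
    for (s1, e1, _), (s2, _, _) in zip(spans, spans[1:]):
        if s2 <= e1:
            raise GenerationError(f"planted fingers overlap at {s1} and {s2}")
    if spans and spans[-1][1] > length:
        raise GenerationError("planted finger exceeds protein length")
    o1, o2, o3, o4 = pattern.coordinating_offsets()
    for _ in range(max_tries):
        residues = list(rng.choice(_FINGER_FILLER, size=length))
        if k_r_fraction > 0:
            n_kr = int(round(k_r_fraction * length))
            for idx in rng.choice(length, size=n_kr, replace=False):
                residues[idx] = rng.choice(["K", "R"])
        for pos, _, cfg in spans:
            finger = list(rng.choice(_FINGER_FILLER, size=w))
            finger[o1] = "H" if cfg == protein_domains.VARIANT_POS1 else "C"
            finger[o2] = "C"
            finger[o3] = "H"
            finger[o4] = "R" if cfg == protein_domains.VARIANT_POS21 else "H"
            residues[pos - 1 : pos - 1 + w] = finger
        record = SequenceRecord(id=seq_id, alphabet="protein", residues="".join(residues))
        found = protein_domains.scan_zinc_fingers(record, allow_variants=True)
        if [(f.start, f.end, f.configuration) for f in found] == [
            (s, e, c) for s, e, c in spans
        ]:
            manifest = {
                "length": length,
                "planted": [
                    {"start": s, "end": e, "configuration": c} for s, e, c in spans
                ],
            }
            return record, manifest
    raise GenerationError(
        f"could not draw a finger-free background in {max_tries} tries"
    )


def make_peak_list(
    protein: SequenceRecord,
    n_true_peaks: int = 10,
    ppm_jitter_sd: float = 10.0,
    n_decoys: int = 5,
    tolerance_ppm: float = 50.0,
    mass_range: tuple[float, float] = (900.0, 4000.0),
    seed: int | np.random.Generator = 0,
    max_tries: int = 10000,
) -> tuple[list[float], dict]:
    """An observed peak list drawn from the protein's theoretical digest.

    True peaks are in-range fragment [M+H]+ values jittered by
    Normal(0, ``ppm_jitter_sd``) ppm; decoy peaks are placed at least three
    tolerances away from every theoretical mass so they can never be matched.
    The manifest records the true assignments and the coverage they imply.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fragments = pmf.digest(protein)
    lo, hi = mass_range
    in_range = [f for f in fragments if lo <= f.mh_plus <= hi]
    if n_true_peaks > len(in_range):
        raise GenerationError(
            f"requested {n_true_peaks} true peaks but only {len(in_range)} "
            f"fragments fall in {mass_range}"
        )
    chosen_idx = rng.choice(len(in_range), size=n_true_peaks, replace=False)
    chosen = [in_range[i] for i in sorted(chosen_idx)]
    peaks = []
    truth = []
    for frag in chosen:
        ppm = rng.normal(0.0, ppm_jitter_sd)
        mz = frag.mh_plus * (1.0 + ppm * 1e-6)
        peaks.append(mz)
        truth.append(
            {"observed_mz": mz, "start": frag.start, "end": frag.end,
             "sequence": frag.sequence, "jitter_ppm": ppm}
        )
    theoretical = np.array([f.mh_plus for f in fragments])
    decoys = []
    for _ in range(max_tries):
        if len(decoys) == n_decoys:
            break
        cand = rng.uniform(lo, hi)
        rel = np.abs(cand - theoretical) / theoretical * 1e6
        if rel.min() >= 3.0 * tolerance_ppm:
            decoys.append(float(cand))
    if len(decoys) < n_decoys:
        raise GenerationError("could not place decoys away from all theoretical masses")
    covered: set[int] = set()
    for frag in chosen:
        covered.update(range(frag.start, frag.end + 1))
    manifest = {
        "true_assignments": truth,
        "decoys": decoys,
        "expected_covered_residues": len(covered),
        "expected_coverage_fraction": len(covered) / len(protein),
        "n_total_fragments": len(fragments),
    }
    all_peaks = sorted(peaks + decoys)
    return all_peaks, manifest


def make_ct_table(
    fold_changes: dict[str, float],
    reference_gene: str = "GAPDH",
    conditions: tuple[str, str] = ("3 uM zinc", "100 uM zinc"),
    n_replicates: int = 3,
    ct_noise_sd: float = 0.0,
    base_ct: float = 22.0,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, dict]:
    """A CT table in which each target's level in the second condition is the
    requested fold of its level in the first (calibrator) condition.

    Folds are encoded as −log2(fold) shifts of the target CT with the
    reference unchanged, plus optional Normal CT noise.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for gene, fold in fold_changes.items():
        if fold <= 0:
            raise GenerationError(f"fold change for {gene!r} must be positive")
    calibrator, treatment = conditions
    rows = []
    for cond in conditions:
        for rep in range(1, n_replicates + 1):
            sample = f"{cond}_rep{rep}"
            rows.append(
                {"sample": sample, "condition": cond, "gene": reference_gene,
                 "ct": base_ct - 3.0 + rng.normal(0.0, ct_noise_sd)}
            )
            for gene, fold in fold_changes.items():
                shift = -np.log2(fold) if cond == treatment else 0.0
                rows.append(
                    {"sample": sample, "condition": cond, "gene": gene,
                     "ct": base_ct + shift + rng.normal(0.0, ct_noise_sd)}
                )
    manifest = {"fold_changes": fold_changes, "calibrator": calibrator,
                "treatment": treatment, "reference_gene": reference_gene}
    return pd.DataFrame(rows), manifest


def make_expression_matrix(
    n_genes: int = 500,
    n_per_group: int = 3,
    planted_up: dict[str, float] | int = 10,
    planted_down: dict[str, float] | int = 10,
    planted_fold: float = 1.5,
    noise_sd: float = 0.25,
    undetected_fraction: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> tuple[ExpressionMatrix, dict]:
    """A two-group log2 expression matrix with planted differential genes.

    Planted genes shift by ±log2(fold) in the knockdown group on top of
    gene-specific baselines with Normal(0, ``noise_sd``) log2 noise; a random
    fraction of unplanted probes is marked undetected (detection p ≥ 0.01).
    ``planted_up``/``planted_down`` may be counts (all at ``planted_fold``) or
    explicit gene→fold dicts.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    genes = [f"gene_{i:04d}" for i in range(n_genes)]
    if isinstance(planted_up, int):
        planted_up = {genes[i]: planted_fold for i in range(planted_up)}
    if isinstance(planted_down, int):
        start = len(planted_up)
        planted_down = {
            genes[start + i]: planted_fold for i in range(planted_down)
        }
    for gene, fold in itertools.chain(planted_up.items(), planted_down.items()):
        if fold <= 1.0:
            raise GenerationError(f"planted fold for {gene!r} must exceed 1")
    baseline = rng.normal(8.0, 1.0, size=n_genes)
    cols = {}
    samples, labels = [], {}
    for group, sign in (("knockdown", +1), ("control", 0)):
        for rep in range(1, n_per_group + 1):
            name = f"{group}_{rep}"
            col = baseline + rng.normal(0.0, noise_sd, size=n_genes)
            if sign:
                for i, g in enumerate(genes):
                    if g in planted_up:
                        col[i] += np.log2(planted_up[g])
                    elif g in planted_down:
                        col[i] -= np.log2(planted_down[g])
            cols[name] = col
            samples.append(name)
            labels[name] = group
    data = pd.DataFrame(cols, index=genes)
    planted_genes = set(planted_up) | set(planted_down)
    unplanted = [g for g in genes if g not in planted_genes]
    n_undet = int(round(undetected_fraction * len(unplanted)))
    undetected = set(
        rng.choice(unplanted, size=n_undet, replace=False)
    ) if n_undet else set()
    detection_p = pd.Series(
        [0.5 if g in undetected else 0.001 for g in genes], index=genes
    )
    matrix = ExpressionMatrix(
        data=data, groups=labels, treatment="knockdown", control="control",
        detection_p=detection_p, scale="log2",
    )
    manifest = {
        "planted_up": planted_up, "planted_down": planted_down,
        "undetected": sorted(undetected), "n_genes": n_genes,
        "n_per_group": n_per_group,
    }
    return matrix, manifest
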