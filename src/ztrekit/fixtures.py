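"""Bundled worked-example data: the SLC30A5 promoter probe, its ZTRE-deletion
variant, the ZTRE consensus definition, and the primer/element coordinate
table, all usable offline."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .motif_scan import GappedMotif, motif_from_json
from .sequence_io import SequenceRecord, read_fasta

PROBE_WINDOW_START = -156  # promoter coordinate of probe position 1
PROBE_WINDOW_END = 46


def _data_path(name: str) -> Path:
    return Path(resources.files("ztrekit.data") / name)


def slc30a5_probe() -> SequenceRecord:
    """The 202-nt SLC30A5 promoter probe covering −156..+46 (no position 0)."""
    return read_fasta(_data_path("slc30a5_probe.fasta"), alphabet="DNA")[0]


def slc30a5_probe_deletion() -> SequenceRecord:
    """The probe with promoter −91..−84 (the 5' side of the ZTRE) deleted."""
    return read_fasta(_data_path("slc30a5_probe_del_m91_m84.fasta"), alphabet="DNA")[0]


def ztre_consensus() -> GappedMotif:
    """The bundled ZTRE consensus motif definition."""
    return motif_from_json(_data_path("ztre_consensus.json"))


def primer_coordinates() -> pd.DataFrame:
    """Coordinates of the probe, ZTRE element/deletion/competitor and qPCR primers."""
    return pd.read_csv(_data_path("primer_coordinates.tsv"), sep="\t")
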