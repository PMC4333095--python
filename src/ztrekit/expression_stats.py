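"""qPCR and microarray statistics for zinc-responsive expression.

Two families of computation live here:

* ΔΔCT relative quantification (and the dilution-corrected abundance ratio it
  implies when one transcript must be measured from a diluted RT reaction),
  assuming 100% amplification efficiency so one cycle equals a factor of two.

* The rank-product differential-expression statistic for a two-group
  comparison: per-comparison fold-change ranks, their geometric mean per gene,
  and a permutation estimate of the false-positive proportion (pfp), plus the
  detection-p and fold-change filters used to build up/down gene lists.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .sequence_io import SequenceError


class StatsError(ValueError):
    """Invalid input to an expression statistic."""


@dataclass(frozen=True)
class CTRecord:
    sample: str
    condition: str
    gene: str
    ct: float

    def __post_init__(self) -> None:
        if not self.ct > 0:
            raise StatsError(f"CT must be positive, got {self.ct} for {self.gene}")


def _ct_frame(records: Iterable[CTRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        missing = {"sample", "condition", "gene", "ct"} - set(df.columns)
        if missing:
            raise StatsError(f"CT table missing columns {sorted(missing)}")
        return df
    return pd.DataFrame(
        [{"sample": r.sample, "condition": r.condition, "gene": r.gene, "ct": r.ct}
         for r in records]
    )


def ddct(
    records: Iterable[CTRecord] | pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    calibrator_condition: str,
) -> pd.DataFrame:
    """Relative level of the target per condition by the ΔΔCT method.

    ΔCT = CT(target) − CT(reference) per sample; ΔΔCT = mean ΔCT(condition) −
    mean ΔCT(calibrator); relative level = 2^(−ΔΔCT).  The calibrator
    condition has relative level 1 by construction.
    """
    df = _ct_frame(records)
    for gene, role in ((target_gene, "target"), (reference_gene, "reference")):
        if gene not in set(df["gene"]):
            raise StatsError(f"{role} gene {gene!r} absent from CT table")
    wide = df.pivot_table(index=["sample", "condition"], columns="gene", values="ct")
    if wide[[target_gene, reference_gene]].isna().any().any():
        raise StatsError("target and reference must be measured in every sample")
    wide = wide.reset_index()
    wide["dct"] = wide[target_gene] - wide[reference_gene]
    per_cond = wide.groupby("condition")["dct"].agg(["mean", "count"])
    if calibrator_condition not in per_cond.index:
        raise StatsError(f"calibrator condition {calibrator_condition!r} not present")
    ddct_vals = per_cond["mean"] - per_cond.loc[calibrator_condition, "mean"]
    out = pd.DataFrame(
        {
            "condition": per_cond.index,
            "n_samples": per_cond["count"].to_numpy(),
            "mean_dct": per_cond["mean"].to_numpy(),
            "ddct": ddct_vals.to_numpy(),
            "relative_level": np.power(2.0, -ddct_vals.to_numpy()),
        }
    ).reset_index(drop=True)
    return out


def abundance_ratio_from_ct(
    ct_low_abundant: float, ct_high_abundant: float, dilution_factor: float = 1.0
) -> float:
    """Fold ratio of two transcripts from their CTs and the dilution applied to
    the more abundant one: dilution × 2^(CT_low − CT_high), at 100% efficiency."""
    if dilution_factor < 1:
        raise StatsError(f"dilution factor must be >= 1, got {dilution_factor}")
    return dilution_factor * 2.0 ** (ct_low_abundant - ct_high_abundant)


# ---------------------------------------------------------------------------
# Rank product


@dataclass
class ExpressionMatrix:
    """Normalised intensities (genes × samples) with two-group labels.

    ``scale`` declares whether intensities are linear or log2; fold changes
    are always reported on the linear scale.
    """

    data: pd.DataFrame
    groups: dict[str, str]  # sample column -> group label
    treatment: str
    control: str
    detection_p: pd.Series | None = None
    scale: Literal["linear", "log2"] = "linear"

    def __post_init__(self) -> None:
        unknown = set(self.groups) - set(self.data.columns)
        if unknown:
            raise StatsError(f"group labels for unknown samples: {sorted(unknown)}")
        if self.data.isna().any().any():
            raise StatsError("expression matrix contains missing values")
        for g in (self.treatment, self.control):
            if len(self.group_columns(g)) < 2:
                raise StatsError(f"group {g!r} needs at least 2 samples")

    def group_columns(self, label: str) -> list[str]:
        return [c for c in self.data.columns if self.groups.get(c) == label]

    def linear(self) -> pd.DataFrame:
        return np.power(2.0, self.data) if self.scale == "log2" else self.data


def _fold_change_columns(
    matrix: ExpressionMatrix, pairing: str = "all"
) -> np.ndarray:
    """Per-comparison linear fold changes, one column per sample comparison.

    ``pairing='all'`` uses every (treatment, control) sample pair;
    ``pairing='paired'`` pairs treatment replicate i with control replicate i
    only, giving comparisons on disjoint samples (independent rank columns,
    the setting in which the permutation null is exact).
    """
    lin = matrix.linear()
    t_cols = matrix.group_columns(matrix.treatment)
    c_cols = matrix.group_columns(matrix.control)
    if pairing == "paired":
        if len(t_cols) != len(c_cols):
            raise StatsError("paired comparisons require equal group sizes")
        pairs = list(zip(t_cols, c_cols))
    elif pairing == "all":
        pairs = list(itertools.product(t_cols, c_cols))
    else:
        raise StatsError(f"unknown pairing {pairing!r}")
    cols = [lin[t].to_numpy() / lin[c].to_numpy() for t, c in pairs]
    return np.column_stack(cols)


def _rank_columns(values: np.ndarray, direction: str) -> np.ndarray:
    """Average ranks per column; rank 1 = most extreme in ``direction``."""
    df = pd.DataFrame(values)
    ascending = direction == "down"
    return df.rank(axis=0, ascending=ascending, method="average").to_numpy()


def _rp(ranks: np.ndarray) -> np.ndarray:
    return np.exp(np.mean(np.log(ranks), axis=1))


def _pfp_from_null(observed_rp: np.ndarray, null_rp_per_instance: Iterable[np.ndarray],
                   n_instances: int) -> np.ndarray:
    """pfp(g) = E[# null RPs <= RP_g per instance] / rank of RP_g among observed."""
    counts = np.zeros_like(observed_rp)
    # tiny relative slack so rank products that are equal analytically but
    # computed through log arithmetic still count as ties
    thresh = observed_rp * (1.0 + 1e-9)
    for null_rp in null_rp_per_instance:
        counts += np.searchsorted(np.sort(null_rp), thresh, side="right")
    expected = counts / n_instances
    obs_rank = pd.Series(observed_rp).rank(method="average").to_numpy()
    return expected / obs_rank


def rank_product(
    matrix: ExpressionMatrix,
    n_permutations: int = 10000,
    seed: int | None = 0,
    method: Literal["permutation", "exact"] = "permutation",
    pairing: Literal["all", "paired"] = "all",
) -> pd.DataFrame:
    """Two one-sided rank-product analyses (up- and down-regulation).

    RP(g) is the geometric mean of gene g's fold-change ranks across all
    treatment-vs-control sample pairings (rank 1 = most changed in the tested
    direction, average ranks on ties).  The false-positive proportion is
    estimated from a null in which each comparison's ranks are an independent
    random permutation; ``method='exact'`` enumerates that null completely and
    is only feasible for tiny instances.
    """
    folds = _fold_change_columns(matrix, pairing=pairing)
    n_genes, k = folds.shape
    out = pd.DataFrame(index=matrix.data.index)
    lin = matrix.linear()
    out["fold_change"] = (
        lin[matrix.group_columns(matrix.treatment)].mean(axis=1)
        / lin[matrix.group_columns(matrix.control)].mean(axis=1)
    )
    rng = np.random.default_rng(seed)
    for direction in ("up", "down"):
        ranks = _rank_columns(folds, direction)
        rp = _rp(ranks)
        out[f"rp_{direction}"] = rp
        if method == "exact":
            if math.factorial(n_genes) ** k > 200_000:
                raise StatsError("exact enumeration is only feasible for tiny instances")
            perms = list(itertools.permutations(range(1, n_genes + 1)))
            instances = itertools.product(perms, repeat=k)
            nulls = (
                _rp(np.array(cols, dtype=float).T) for cols in instances
            )
            out[f"pfp_{direction}"] = _pfp_from_null(
                rp, nulls, math.factorial(n_genes) ** k
            )
        else:
            def null_gen():
                for _ in range(n_permutations):
                    cols = np.column_stack(
                        [rng.permutation(n_genes) + 1.0 for _ in range(k)]
                    )
                    yield _rp(cols)
            out[f"pfp_{direction}"] = _pfp_from_null(rp, null_gen(), n_permutations)
    out["direction"] = np.where(out["fold_change"] >= 1.0, "up", "down")
    return out


def apply_filters(
    results: pd.DataFrame,
    detection_p: pd.Series | None = None,
    detection_p_threshold: float = 0.01,
    fold_threshold: float = 1.2,
    pfp_threshold: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Detection filter, then fold filter, then rank-product significance.

    Probes whose detection p-value is not below the threshold are removed
    first; of the rest, up-regulated genes need fold > threshold and down-
    regulated genes fold < 1/threshold (strict inequalities), plus a pfp at or
    below the significance level in the corresponding direction.  Returns
    (up, down) tables sorted by magnitude of change.
    """
    df = results.copy()
    if detection_p is not None:
        detected = detection_p.reindex(df.index) < detection_p_threshold
        df = df[detected.fillna(False)]
    up = df[(df["fold_change"] > fold_threshold) & (df["pfp_up"] <= pfp_threshold)]
    down = df[
        (df["fold_change"] < 1.0 / fold_threshold) & (df["pfp_down"] <= pfp_threshold)
    ]
    up = up.sort_values("fold_change", ascending=False)
    down = down.sort_values("fold_change", ascending=True)
    return up, down
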