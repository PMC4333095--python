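"""ΔΔCT arithmetic and the rank-product statistic.

The rank-product oracle enumerates the complete permutation null by hand on a
tiny instance (3 genes × 2 comparisons → 36 equally likely rank
configurations) using exact integer rank products, independently of the
implementation's log-space geometric means.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from ztrekit.expression_stats import (
    CTRecord,
    ExpressionMatrix,
    StatsError,
    abundance_ratio_from_ct,
    apply_filters,
    ddct,
    rank_product,
)


def ct_table(rows):
    return pd.DataFrame(rows, columns=["sample", "condition", "gene", "ct"])


def two_condition_cts(target_shift):
    rows = []
    for cond, shift in (("low", 0.0), ("high", target_shift)):
        for rep in range(3):
            s = f"{cond}{rep}"
            rows.append((s, cond, "TG", 24.0 + shift))
            rows.append((s, cond, "REF", 18.0))
    return ct_table(rows)


class TestDdct:
    def rel(self, df):
        res = ddct(df, "TG", "REF", calibrator_condition="low")
        return dict(zip(res["condition"], res["relative_level"]))

    def test_no_change(self):
        assert self.rel(two_condition_cts(0.0))["high"] == pytest.approx(1.0)

    def test_one_cycle_up_halves_level(self):
        assert self.rel(two_condition_cts(1.0))["high"] == pytest.approx(0.5)

    def test_one_cycle_down_doubles_level(self):
        assert self.rel(two_condition_cts(-1.0))["high"] == pytest.approx(2.0)

    def test_calibrator_level_is_one(self):
        assert self.rel(two_condition_cts(0.73))["low"] == pytest.approx(1.0)

    def test_invariant_to_per_sample_ct_offset(self):
        df = two_condition_cts(1.0)
        shifted = df.copy()
        offsets = {s: i * 0.37 for i, s in enumerate(shifted["sample"].unique())}
        shifted["ct"] = shifted["ct"] + shifted["sample"].map(offsets)
        assert self.rel(shifted)["high"] == pytest.approx(self.rel(df)["high"])

    def test_missing_reference_errors(self):
        df = two_condition_cts(1.0)
        with pytest.raises(StatsError):
            ddct(df, "TG", "NOPE", calibrator_condition="low")

    def test_ct_records_accepted(self):
        recs = [
            CTRecord("s1", "low", "TG", 24.0), CTRecord("s1", "low", "REF", 18.0),
            CTRecord("s2", "high", "TG", 23.0), CTRecord("s2", "high", "REF", 18.0),
        ]
        res = ddct(recs, "TG", "REF", calibrator_condition="low")
        out = dict(zip(res["condition"], res["relative_level"]))
        assert out["high"] == pytest.approx(2.0)


class TestAbundanceRatio:
    def test_equal_cts_no_dilution(self):
        assert abundance_ratio_from_ct(20.0, 20.0, 1.0) == pytest.approx(1.0)

    def test_power_of_two(self):
        assert abundance_ratio_from_ct(30.0, 20.0, 1.0) == pytest.approx(1024.0)

    def test_dilution_corrected(self):
        # ΔCT 6.54 with a 20-fold dilution of the abundant species
        ratio = abundance_ratio_from_ct(26.54, 20.0, 20.0)
        assert ratio == pytest.approx(20 * 2**6.54, rel=1e-12)
        assert ratio == pytest.approx(1.86e3, rel=0.01)

    def test_invalid_dilution(self):
        with pytest.raises(StatsError):
            abundance_ratio_from_ct(20.0, 20.0, 0.5)


def tiny_matrix():
    """3 genes, 2 samples per group, constructed tie-free."""
    data = pd.DataFrame(
        {
            "kd_1": [10.0, 4.0, 1.0],
            "kd_2": [9.0, 5.0, 2.0],
            "ctl_1": [2.0, 4.5, 1.5],
            "ctl_2": [3.0, 5.5, 2.5],
        },
        index=["g_up", "g_flat", "g_mid"],
    )
    groups = {"kd_1": "kd", "kd_2": "kd", "ctl_1": "ctl", "ctl_2": "ctl"}
    return ExpressionMatrix(data=data, groups=groups, treatment="kd", control="ctl",
                            scale="linear")


def oracle_rank_columns(folds, direction):
    """Integer ranks per comparison column (no ties by construction)."""
    cols = []
    for j in range(folds.shape[1]):
        order = sorted(
            range(folds.shape[0]),
            key=lambda i: -folds[i, j] if direction == "up" else folds[i, j],
        )
        ranks = [0] * folds.shape[0]
        for r, i in enumerate(order, start=1):
            ranks[i] = r
        cols.append(ranks)
    return np.array(cols).T


def oracle_exact_pfp(folds, direction):
    """pfp by complete enumeration of per-comparison rank permutations,
    comparing exact integer rank products."""
    n, k = folds.shape
    ranks = oracle_rank_columns(folds, direction)
    obs_prod = ranks.prod(axis=1)
    perms = list(itertools.permutations(range(1, n + 1)))
    counts = np.zeros(n)
    n_inst = 0
    for cols in itertools.product(perms, repeat=k):
        null_prod = np.ones(n, dtype=int)
        for col in cols:
            null_prod = null_prod * np.array(col)
        for g in range(n):
            counts[g] += int((null_prod <= obs_prod[g]).sum())
        n_inst += 1
    expected = counts / n_inst
    obs_rank = pd.Series(obs_prod).rank(method="average").to_numpy()
    return expected / obs_rank


class TestRankProduct:
    def test_extreme_gene_has_rp_one(self):
        em = tiny_matrix()
        res = rank_product(em, n_permutations=200, seed=1)
        assert res.loc["g_up", "rp_up"] == pytest.approx(1.0)
        assert res["pfp_up"].idxmin() == "g_up"

    def test_exact_enumeration_matches_brute_force(self):
        em = tiny_matrix()
        # restrict to one kd and both ctl columns -> 2 comparisons
        em2 = ExpressionMatrix(
            data=em.data[["kd_1", "kd_2", "ctl_1", "ctl_2"]],
            groups=em.groups, treatment="kd", control="ctl", scale="linear",
        )
        res = rank_product(em2, method="exact")
        from ztrekit.expression_stats import _fold_change_columns

        folds = _fold_change_columns(em2)
        for direction in ("up", "down"):
            expected = oracle_exact_pfp(folds, direction)
            np.testing.assert_allclose(
                res[f"pfp_{direction}"].to_numpy(), expected, rtol=1e-12
            )

    def test_permutation_estimate_approaches_exact(self):
        em = tiny_matrix()
        exact = rank_product(em, method="exact")
        mc = rank_product(em, n_permutations=20000, seed=7)
        np.testing.assert_allclose(
            mc["pfp_up"].to_numpy(), exact["pfp_up"].to_numpy(), atol=0.05
        )

    def test_invariant_under_monotone_transformation(self):
        em = tiny_matrix()
        res = rank_product(em, n_permutations=100, seed=3)
        cubed = ExpressionMatrix(
            data=em.data**3, groups=em.groups, treatment="kd", control="ctl",
            scale="linear",
        )
        res3 = rank_product(cubed, n_permutations=100, seed=3)
        for col in ("rp_up", "rp_down", "pfp_up", "pfp_down"):
            np.testing.assert_allclose(res[col].to_numpy(), res3[col].to_numpy())

    def test_deterministic_given_seed(self):
        em = tiny_matrix()
        a = rank_product(em, n_permutations=300, seed=11)
        b = rank_product(em, n_permutations=300, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_small_group_rejected(self):
        data = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0], "c": [1.5, 1.2]})
        with pytest.raises(StatsError):
            ExpressionMatrix(data=data, groups={"a": "t", "b": "t", "c": "c"},
                             treatment="t", control="c")


class TestApplyFilters:
    def results_frame(self):
        return pd.DataFrame(
            {
                "fold_change": [2.0, 1.21, 1.19, 0.5, 0.9],
                "pfp_up": [0.001, 0.01, 0.01, 0.9, 0.9],
                "pfp_down": [0.9, 0.9, 0.9, 0.001, 0.2],
            },
            index=["big_up", "just_up", "below_threshold", "down", "weak_down"],
        )

    def test_detection_filter_first(self):
        detection = pd.Series(
            [0.02, 0.001, 0.001, 0.001, 0.001], index=self.results_frame().index
        )
        up, down = apply_filters(self.results_frame(), detection_p=detection)
        assert "big_up" not in up.index  # excluded regardless of fold

    def test_fold_threshold_strict(self):
        up, down = apply_filters(self.results_frame())
        assert "just_up" in up.index
        assert "below_threshold" not in up.index

    def test_up_down_split_and_sorting(self):
        up, down = apply_filters(self.results_frame())
        assert list(up.index) == ["big_up", "just_up"]
        assert list(down.index) == ["down"]

    def test_null_calibration(self, rng):
        """Under a complete null the estimated null CDF at the observed RPs
        (pfp × rank / n_genes) is approximately uniform."""
        from ztrekit.synthetic_data import make_expression_matrix

        em, _ = make_expression_matrix(
            n_genes=120, n_per_group=3, planted_up=0, planted_down=0,
            noise_sd=0.3, undetected_fraction=0.0, seed=rng,
        )
        res = rank_product(em, n_permutations=400, seed=5, pairing="paired")
        n = len(res)
        rank_up = res["rp_up"].rank(method="average")
        p_implied = (res["pfp_up"] * rank_up / n).to_numpy()
        assert abs(np.mean(p_implied) - 0.5) < 0.08
        assert np.max(p_implied) > 0.8 and np.min(p_implied) < 0.2


class TestPlantedRecovery:
    def test_planted_up_genes_recovered(self, rng):
        from ztrekit.synthetic_data import make_expression_matrix

        em, manifest = make_expression_matrix(
            n_genes=300, n_per_group=3, planted_up=10, planted_down=10,
            planted_fold=1.5, noise_sd=0.2, seed=rng,
        )
        res = rank_product(em, n_permutations=1000, seed=2)
        up, down = apply_filters(res, detection_p=em.detection_p)
        assert set(manifest["planted_up"]) <= set(up.index)
        assert set(manifest["planted_down"]) <= set(down.index)
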