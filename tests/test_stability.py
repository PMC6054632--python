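"""Stability indices, condition medians, and differential classification."""

import numpy as np
import pandas as pd
import pytest

from bruchase.quantify import compute_rpkm
from bruchase.stability import (
    condition_stability,
    differential_stability,
    replicate_stability_index,
    stability_analysis,
)


def _paired_sheet(n_rep=2, groups=("ctrl",)):
    rows = []
    for g in groups:
        for r in range(1, n_rep + 1):
            for assay in ("pulse", "chase"):
                rows.append(
                    {
                        "library_id": f"{g}_r{r}_{assay}",
                        "subject_id": f"{g}_s{r}",
                        "group": g,
                        "assay": assay,
                        "replicate": r,
                    }
                )
    return pd.DataFrame(rows)


class TestReplicateIndex:
    def test_basic_ratios(self):
        sheet = _paired_sheet(1)
        expr = pd.DataFrame(
            {"ctrl_r1_pulse": [7.3, 8.0, 0.0], "ctrl_r1_chase": [7.3, 2.0, 4.0]},
            index=pd.Index(["G1", "G2", "G3"], name="gene_id"),
        )
        S, pairs = replicate_stability_index(expr, sheet)
        col = S.iloc[:, 0]
        assert col["G1"] == pytest.approx(1.0)
        assert col["G2"] == pytest.approx(0.25)
        assert np.isnan(col["G3"])  # guarded division, no exception

    def test_pulse_guard_threshold(self):
        sheet = _paired_sheet(1)
        expr = pd.DataFrame(
            {"ctrl_r1_pulse": [0.4, 0.5], "ctrl_r1_chase": [1.0, 1.0]},
            index=pd.Index(["G1", "G2"], name="gene_id"),
        )
        S, _ = replicate_stability_index(expr, sheet, pulse_min_rpkm=0.5)
        assert np.isnan(S.iloc[0, 0]) and S.iloc[1, 0] == pytest.approx(2.0)

    def test_orphan_chase_library_raises(self):
        sheet = _paired_sheet(1)
        sheet = sheet[sheet["library_id"] != "ctrl_r1_pulse"]
        expr = pd.DataFrame(
            {"ctrl_r1_chase": [1.0]}, index=pd.Index(["G1"], name="gene_id")
        )
        with pytest.raises(ValueError, match="ctrl_r1_chase"):
            replicate_stability_index(expr, sheet)


class TestConditionStability:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([0.8, 1.0, 1.2], 1.0),
            ([1.0, 2.0, 4.0, 8.0], 3.0),  # even count: mean of central two
            ([5.0], 5.0),
        ],
    )
    def test_median_rules(self, values, expected):
        S = pd.DataFrame(
            {f"s{i}": [v] for i, v in enumerate(values)},
            index=pd.Index(["G1"], name="gene_id"),
        )
        pairs = pd.DataFrame(
            {
                "pair_id": list(S.columns),
                "subject_id": list(S.columns),
                "replicate": 1,
                "group": "ctrl",
            }
        )
        assert condition_stability(S, pairs, "ctrl")["G1"] == pytest.approx(expected)

    def test_permutation_invariance(self, rng):
        vals = rng.lognormal(0, 1, 5)
        S = pd.DataFrame([vals], index=pd.Index(["G1"], name="gene_id"),
                         columns=[f"s{i}" for i in range(5)])
        pairs = pd.DataFrame({"pair_id": S.columns, "subject_id": S.columns,
                              "replicate": 1, "group": "g"})
        perm = rng.permutation(5)
        S2 = S.iloc[:, perm]
        pairs2 = pairs.iloc[perm].reset_index(drop=True)
        assert condition_stability(S, pairs, "g")["G1"] == pytest.approx(
            condition_stability(S2, pairs2, "g")["G1"]
        )

    def test_all_nan_gives_nan(self):
        S = pd.DataFrame({"s0": [np.nan]}, index=pd.Index(["G1"], name="gene_id"))
        pairs = pd.DataFrame(
            {"pair_id": ["s0"], "subject_id": ["s0"], "replicate": 1, "group": "g"}
        )
        assert np.isnan(condition_stability(S, pairs, "g")["G1"])


class TestDifferentialStability:
    @pytest.mark.parametrize(
        "s_case,s_ctrl,ratio,cls",
        [
            (0.5, 1.0, 0.5, "destabilized"),
            (1.4, 1.0, 1.4, "unchanged"),
            (1.5, 1.0, 1.5, "stabilized"),  # inclusive boundary
            (2.0, 3.0, 2 / 3, "destabilized"),  # inclusive at 1/1.5
        ],
    )
    def test_classification(self, s_case, s_ctrl, ratio, cls):
        res = differential_stability(
            pd.Series({"G": s_case}), pd.Series({"G": s_ctrl})
        )
        assert res.loc["G", "ratio"] == pytest.approx(ratio)
        assert res.loc["G", "class"] == cls

    def test_zero_denominator_not_evaluable(self):
        res = differential_stability(pd.Series({"G": 1.0}), pd.Series({"G": 0.0}))
        assert res.loc["G", "class"] == "not_evaluable"

    def test_nan_not_evaluable(self):
        res = differential_stability(
            pd.Series({"G": np.nan}), pd.Series({"G": 1.0})
        )
        assert res.loc["G", "class"] == "not_evaluable"


class TestCompositionInvariance:
    def test_library_scaling_leaves_ratios(self, small_dataset):
        # multiplying all chase library sizes by c and pulse sizes by d
        # rescales every S by c/d... wait, by the same factor, leaving R fixed
        ds = small_dataset
        expr = compute_rpkm(ds.counts, ds.gene_models)
        sizes = ds.counts.sum(axis=0).astype(float)
        scaled = sizes.copy()
        chase_libs = ds.sample_sheet.loc[
            ds.sample_sheet["assay"] == "chase", "library_id"
        ]
        pulse_libs = ds.sample_sheet.loc[
            ds.sample_sheet["assay"] == "pulse", "library_id"
        ]
        scaled[list(chase_libs)] *= 3.0
        scaled[list(pulse_libs)] *= 0.5
        expr2 = compute_rpkm(ds.counts, ds.gene_models, scaled)
        r1 = stability_analysis(expr, ds.sample_sheet, "case", "control")
        r2 = stability_analysis(expr2, ds.sample_sheet, "case", "control")
        ok = r1["ratio"].notna() & r2["ratio"].notna()
        assert np.allclose(r1.loc[ok, "ratio"], r2.loc[ok, "ratio"])

    def test_class_counts_partition_universe(self, small_stability):
        from bruchase.stability import class_counts

        counts = class_counts(small_stability)
        assert sum(counts.values()) == len(small_stability)

    def test_planted_destabilization_direction(self, small_dataset, small_stability):
        planted = [
            g for g in small_dataset.gene_sets["planted"]
            if g in small_stability.index
        ]
        med_planted = small_stability.loc[planted, "ratio"].median()
        others = small_stability.index.difference(planted)
        med_other = small_stability.loc[others, "ratio"].median()
        assert med_planted < 0.8 * med_other

    def test_permutation_fdr_extension_flags_planted_genes(self, small_dataset):
        from bruchase.stability import permutation_stability_fdr

        expr = compute_rpkm(small_dataset.counts, small_dataset.gene_models)
        S, pairs = replicate_stability_index(expr, small_dataset.sample_sheet)
        res = permutation_stability_fdr(
            S, pairs, "case", "control", n_perm=60, seed=0
        )
        planted = [g for g in small_dataset.gene_sets["planted"] if g in res.index]
        others = res.index.difference(planted)
        assert (
            res.loc[planted, "perm_p_extension"].median()
            < res.loc[others, "perm_p_extension"].median()
        )

    def test_half_life_column_matches_decay_model(self):
        # S = 0.25 over a 6 h chase is two half-lives -> t1/2 = 3 h
        sheet = _paired_sheet(1)
        expr = pd.DataFrame(
            {"ctrl_r1_pulse": [8.0], "ctrl_r1_chase": [2.0]},
            index=pd.Index(["G1"], name="gene_id"),
        )
        sheet2 = _paired_sheet(1, groups=("case",))
        expr2 = expr.rename(
            columns={
                "ctrl_r1_pulse": "case_r1_pulse",
                "ctrl_r1_chase": "case_r1_chase",
            }
        )
        res = stability_analysis(
            expr.join(expr2), pd.concat([sheet, sheet2], ignore_index=True),
            "case", "ctrl",
        )
        assert res.loc["G1", "half_life_control_h"] == pytest.approx(3.0)
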