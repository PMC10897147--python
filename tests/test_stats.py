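"""Rollup, NSAF, group statistics and differential abundance."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from oracles import kruskal_h, permutation_anova_p, student_t
from turnoverms.matrix import FaMatrix, make_sample_table
from turnoverms.stats import (
    PROTEASOME_COMPLEXES,
    compare_groups,
    complex_compare,
    diff_abundance,
    median_adjust,
    nsaf,
    rollup,
)


def _peptide_df(rows):
    return pd.DataFrame(rows, columns=["protein", "sample", "i_old", "i_new"]).assign(
        flags=""
    )


class TestRollup:
    def test_single_peptide_passes_through(self):
        fa = rollup(_peptide_df([("A", "s1", 10.0, 90.0)]))
        assert fa.values.at["A", "s1"] == pytest.approx(0.1)

    def test_area_weighted_two_peptides(self):
        fa = rollup(_peptide_df([("A", "s1", 10.0, 90.0), ("A", "s1", 30.0, 70.0)]))
        assert fa.values.at["A", "s1"] == pytest.approx(40 / 200)

    def test_min_replicates_blanks_sparse_groups(self):
        rows = [("A", f"s{i}", 10.0, 90.0) for i in range(2)] + [
            ("B", f"s{i}", 10.0, 90.0) for i in range(4)
        ]
        meta = {
            f"s{i}": {"age": 12, "sex": "M", "fraction": "bulk",
                      "treatment": "none", "replicate": i}
            for i in range(4)
        }
        fa = rollup(_peptide_df(rows), sample_meta=meta, min_replicates=3)
        assert fa.values.loc["A"].isna().all()
        assert fa.values.loc["B"].notna().all()

    def test_rollup_within_peptide_fa_range(self):
        rng = np.random.default_rng(3)
        rows = []
        for _ in range(30):
            rows.append(("A", "s1", rng.uniform(1, 100), rng.uniform(1, 100)))
        fa = rollup(_peptide_df(rows))
        pep_fa = [o / (o + n) for _, _, o, n in rows]
        assert min(pep_fa) <= fa.values.at["A", "s1"] <= max(pep_fa)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no peptides"):
            rollup(_peptide_df([]))


class TestNsaf:
    def test_single_protein_is_one(self):
        out = nsaf(pd.Series({"A": 7}), pd.Series({"A": 300}))
        assert out["A"] == pytest.approx(1.0)

    def test_worked_two_protein_example(self):
        out = nsaf(pd.Series({"A": 10, "B": 20}), pd.Series({"A": 100, "B": 400}))
        assert out["A"] == pytest.approx(2 / 3)
        assert out["B"] == pytest.approx(1 / 3)

    def test_scale_invariance_and_unit_sum(self):
        rng = np.random.default_rng(0)
        counts = pd.Series(rng.integers(0, 500, size=50).astype(float))
        lengths = pd.Series(rng.integers(50, 2000, size=50).astype(float))
        counts.iloc[0] = 1.0  # keep at least one non-zero
        a = nsaf(counts, lengths)
        b = nsaf(counts * 2, lengths)
        assert np.allclose(a, b, atol=1e-15)
        assert a.sum() == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            nsaf(pd.Series({"A": 0, "B": 0}), pd.Series({"A": 10, "B": 10}))


class TestCompareGroups:
    def test_student_t_matches_hand_formula(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
        res = compare_groups({"a": a, "b": b}, method="student")
        assert res.statistic == pytest.approx(student_t(a, b), abs=1e-12)
        t_ref = student_t(a, b)
        p_ref = 2 * sps.t.sf(abs(t_ref), df=4)
        assert res.pvalue == pytest.approx(p_ref, abs=1e-12)

    def test_kruskal_matches_rank_formula(self):
        groups = [np.array([1.0, 2.0]), np.array([3.0, 4.0]), np.array([5.0, 6.0])]
        res = compare_groups(
            {"a": groups[0], "b": groups[1], "c": groups[2]}, method="kruskal"
        )
        assert res.statistic == pytest.approx(kruskal_h(groups), abs=1e-12)

    def test_identical_groups_kruskal_null(self):
        res = compare_groups(
            {"a": np.ones(4), "b": np.ones(4)}, method="kruskal"
        )
        assert res.statistic == 0.0
        assert res.pvalue == 1.0

    def test_anova_p_matches_permutation_oracle(self):
        groups = {
            "a": np.array([3.1, 2.8, 3.5, 3.0]),
            "b": np.array([3.6, 3.9, 3.4, 4.1]),
            "c": np.array([2.5, 2.9, 2.7, 2.4]),
        }
        res = compare_groups(groups, method="anova")
        p_perm = permutation_anova_p(list(groups.values()), n_perm=10_000, seed=2)
        # Monte-Carlo error ~ 3 * sqrt(p(1-p)/B)
        mc = 3 * np.sqrt(max(p_perm, 1e-4) * (1 - p_perm) / 10_000)
        assert abs(res.pvalue - p_perm) < mc + 0.003

    def test_posthoc_tables_present(self):
        groups = {
            "a": np.array([1.0, 2.0, 1.5]),
            "b": np.array([4.0, 5.0, 4.5]),
            "c": np.array([9.0, 8.0, 8.5]),
        }
        anova = compare_groups(groups, method="anova")
        assert len(anova.posthoc) == 3  # all pairs
        kw = compare_groups(groups, method="kruskal")
        assert {"group1", "group2", "adjusted_p"} <= set(kw.posthoc.columns)
        kw2 = compare_groups(groups, method="kruskal", posthoc="tukey_ranks")
        assert kw2.adjustment == "tukey_on_ranks"

    def test_single_observation_group_rejected(self):
        with pytest.raises(ValueError, match="two observations"):
            compare_groups({"a": np.array([1.0]), "b": np.array([1.0, 2.0])})


class TestMedianAdjust:
    def test_reference_group_centered_on_zero(self, toy_fa):
        out = median_adjust(toy_fa, 12)
        ref_cols = toy_fa.sample_ids(age=12)
        assert np.allclose(out.values[ref_cols].median(axis=1), 0.0, atol=1e-12)

    def test_worked_subtraction(self):
        records = [
            {"sample": f"s{i}", "age": a, "sex": "M", "fraction": "bulk",
             "treatment": "none", "replicate": 1}
            for i, a in enumerate([12, 15, 18])
        ]
        fa = FaMatrix(
            pd.DataFrame([[0.3, 0.2, 0.4]], index=["A"], columns=["s0", "s1", "s2"]),
            make_sample_table(records),
        )
        out = median_adjust(fa, 12)
        assert out.values.loc["A"].tolist() == pytest.approx([0.0, -0.1, 0.1])

    def test_pairwise_differences_preserved(self, toy_fa):
        out = median_adjust(toy_fa, 12)
        before = toy_fa.values.to_numpy()
        after = out.values.to_numpy()
        assert np.allclose(
            before[:, :1] - before, after[:, :1] - after, atol=1e-12
        )

    def test_missing_reference_rejected(self, toy_fa):
        with pytest.raises(ValueError, match="absent"):
            median_adjust(toy_fa, 99)


class TestComplexCompare:
    def _fa(self, offset=0.0, seed=0):
        rng = np.random.default_rng(seed)
        genes = sorted(PROTEASOME_COMPLEXES["19S"].members) + sorted(
            PROTEASOME_COMPLEXES["20S"].members
        )
        records = []
        cols = []
        for age in (12, 15, 18):
            for rep in (1, 2, 3):
                sid = f"M{age}_r{rep}"
                cols.append(sid)
                records.append(
                    {"sample": sid, "age": age, "sex": "M", "fraction": "proteasome",
                     "treatment": "none", "replicate": rep}
                )
        vals = rng.uniform(0.2, 0.4, size=(len(genes), len(cols)))
        for i, g in enumerate(genes):
            if g in PROTEASOME_COMPLEXES["19S"].members:
                vals[i] += offset
        return FaMatrix(
            pd.DataFrame(vals, index=genes, columns=cols), make_sample_table(records)
        )

    def test_identical_complexes_null(self):
        fa = self._fa()
        fa.values.iloc[:, :] = 0.3
        res = complex_compare(fa)
        assert res.pvalue == pytest.approx(1.0)
        assert res.extra["mean_difference"] == 0.0

    def test_planted_offset_detected_with_sign(self):
        res = complex_compare(self._fa(offset=0.1, seed=1))
        assert res.extra["mean_difference"] > 0.05
        assert (res.posthoc["statistic"] > 0).all()
        assert (res.posthoc["pvalue"] < 0.01).all()

    def test_single_member_complex_rejected(self):
        from turnoverms.stats import ComplexDefinition

        fa = self._fa()
        defs = {
            "19S": ComplexDefinition("19S", frozenset({"Psmc1"})),
            "20S": PROTEASOME_COMPLEXES["20S"],
        }
        with pytest.raises(ValueError, match="fewer than 2"):
            complex_compare(fa, defs)


class TestDiffAbundance:
    def test_identical_arms_all_ns(self):
        rng = np.random.default_rng(1)
        base = rng.lognormal(10, 1, size=20)
        df = pd.DataFrame(
            {f"a{i}": base for i in range(3)} | {f"b{i}": base for i in range(3)}
        )
        out = diff_abundance(df, ["a0", "a1", "a2"], ["b0", "b1", "b2"])
        assert (out["class"] == "ns").all()

    def test_planted_twofold_increase_recovered(self):
        rng = np.random.default_rng(7)
        n, n_up = 500, 50
        base = rng.lognormal(10, 1, size=n)
        arms = {}
        for arm, mult in (("a", 2.0), ("b", 1.0)):
            for r in range(4):
                noise = rng.lognormal(0, 0.1, size=n)
                vals = base * noise
                if arm == "a":
                    vals[:n_up] *= mult
                arms[f"{arm}{r}"] = vals
        df = pd.DataFrame(arms)
        out = diff_abundance(df, [f"a{r}" for r in range(4)],
                             [f"b{r}" for r in range(4)])
        assert (out.iloc[:n_up]["class"] == "up").sum() >= 45
        assert (out.iloc[n_up:]["class"] != "ns").sum() <= 2

    def test_exact_log2_fold_change(self):
        df = pd.DataFrame({"a0": [2.0], "a1": [2.0], "a2": [2.0],
                           "b0": [1.0], "b1": [1.0], "b2": [1.0]})
        out = diff_abundance(df, ["a0", "a1", "a2"], ["b0", "b1", "b2"])
        assert out["log2fc"].iloc[0] == pytest.approx(1.0)
        assert out["flag"].iloc[0] == "zero_variance"
        assert out["class"].iloc[0] == "ns"

    def test_too_few_replicates_rejected(self):
        df = pd.DataFrame({"a0": [1.0], "b0": [1.0], "b1": [1.0]})
        with pytest.raises(ValueError, match="replicates"):
            diff_abundance(df, ["a0"], ["b0", "b1"])
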