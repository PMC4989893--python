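"""Differential testing: textbook-formula oracles, degenerate markers,
chromosome rollups and the cross-comparison union."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from meth3way import (
    DataError,
    compare_groups,
    neg_log10_p,
    significance_rate,
    union_significant,
)
from conftest import make_comparison_table


def _beta_frame(fc_rows, kd1_rows, markers=None):
    """Beta matrix from per-group row lists, with a matching design."""
    fc = np.atleast_2d(np.asarray(fc_rows, dtype=float))
    kd1 = np.atleast_2d(np.asarray(kd1_rows, dtype=float))
    idx = markers or [f"m{i}" for i in range(fc.shape[0])]
    cols_fc = [f"FC_{i}" for i in range(1, fc.shape[1] + 1)]
    cols_kd1 = [f"KD1_{i}" for i in range(1, kd1.shape[1] + 1)]
    beta = pd.DataFrame(
        np.concatenate([fc, kd1], axis=1), index=idx, columns=cols_fc + cols_kd1
    )
    design = pd.Series(
        {**{c: "FC" for c in cols_fc}, **{c: "KD1" for c in cols_kd1}},
        name="group",
    ).rename_axis("sample_id")
    return beta, design


def _welch_oracle(a, b):
    """Textbook Welch t-test: statistic, Welch-Satterthwaite df, two-sided p."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (b.mean() - a.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, 2 * stats.t.sf(abs(t), df)


def _student_oracle(a, b):
    """Textbook pooled-variance t-test."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (b.mean() - a.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    return t, 2 * stats.t.sf(abs(t), na + nb - 2)


TOY_A = [0.2, 0.3, 0.25, 0.22]
TOY_B = [0.5, 0.55, 0.48, 0.52, 0.5, 0.53, 0.49]


class TestCompareGroups:
    def test_identical_groups_never_significant(self):
        values = [0.2, 0.4, 0.6, 0.8]
        beta, design = _beta_frame([values] * 3, [values] * 3)
        table = compare_groups(beta, design, "FC", "KD1")
        assert np.allclose(table["delta_beta"], 0.0)
        assert not table["significant"].any()

    def test_maximal_separation_is_significant(self):
        rng = np.random.default_rng(0)
        eps = rng.normal(0, 1e-12, size=(1, 3))
        beta, design = _beta_frame(
            np.full((1, 3), 0.1) + eps, np.full((1, 3), 0.9) + eps
        )
        table = compare_groups(beta, design, "FC", "KD1")
        assert table["p_value"].iloc[0] < 0.05
        assert bool(table["significant"].iloc[0])

    @pytest.mark.parametrize(
        "flavor,oracle", [("welch", _welch_oracle), ("student", _student_oracle)]
    )
    def test_toy_marker_matches_textbook_formula(self, flavor, oracle):
        beta, design = _beta_frame([TOY_A], [TOY_B])
        table = compare_groups(beta, design, "FC", "KD1", test=flavor)
        t_exp, p_exp = oracle(TOY_A, TOY_B)
        assert table["t_stat"].iloc[0] == pytest.approx(t_exp, abs=1e-10)
        assert table["p_value"].iloc[0] == pytest.approx(p_exp, abs=1e-10)
        assert table["delta_beta"].iloc[0] == pytest.approx(
            np.mean(TOY_B) - np.mean(TOY_A), abs=1e-12
        )

    def test_symmetry_between_group_orders(self, beta_design):
        beta, design = beta_design
        ab = compare_groups(beta, design, "FC", "KD1")
        ba = compare_groups(beta, design, "KD1", "FC")
        pd.testing.assert_series_equal(ab["p_value"], ba["p_value"])
        np.testing.assert_allclose(
            ab["delta_beta"], -ba["delta_beta"], atol=1e-12
        )

    def test_missing_dropped_pairwise_and_untestable_flagged(self):
        nan = np.nan
        beta, design = _beta_frame(
            [[0.2, 0.25, nan, nan], [0.2, nan, nan, nan]],
            [[0.5, 0.52, 0.51, 0.49, nan, 0.5, 0.53]] * 2,
        )
        table = compare_groups(beta, design, "FC", "KD1")
        assert table.loc["m0", "n_a"] == 2 and table.loc["m0", "n_b"] == 6
        assert not table.loc["m0", "untestable"]
        assert table.loc["m1", "untestable"]
        assert np.isnan(table.loc["m1", "p_value"])
        assert not table.loc["m1", "significant"]

    def test_zero_variance_equal_means_undefined(self):
        beta, design = _beta_frame([[0.3, 0.3, 0.3]], [[0.3, 0.3, 0.3]])
        table = compare_groups(beta, design, "FC", "KD1")
        assert np.isnan(table["p_value"].iloc[0])
        assert not table["significant"].iloc[0]

    def test_unknown_group_errors(self, beta_design):
        beta, design = beta_design
        with pytest.raises(DataError, match="unknown group"):
            compare_groups(beta, design, "FC", "KD9")


class TestSignificanceRate:
    @staticmethod
    def _toy(sig_flags, chroms):
        markers = [f"m{i}" for i in range(len(sig_flags))]
        table = make_comparison_table(
            markers,
            [0.01 if s else 0.5 for s in sig_flags],
            [0.1] * len(sig_flags),
        )
        manifest = pd.DataFrame(
            {
                "marker_id": markers,
                "chromosome": chroms,
                "gene": [f"G{i}" for i in range(len(markers))],
                "tss_offset": [-100] * len(markers),
            }
        )
        return table, manifest

    def test_hand_counted_rates(self):
        # chromosome 1: 6 markers / 3 significant; chromosome 2: 4 / 1
        flags = [1, 1, 1, 0, 0, 0, 1, 0, 0, 0]
        table, manifest = self._toy(flags, ["1"] * 6 + ["2"] * 4)
        result = significance_rate(table, manifest)
        assert result.per_chromosome.loc["1", "rate"] == 0.5
        assert result.per_chromosome.loc["2", "rate"] == 0.25
        assert result.mean_rate == pytest.approx(0.375)
        assert result.sd_rate == pytest.approx(np.std([0.5, 0.25], ddof=1))
        assert result.per_chromosome["n_total"].sum() == 10

    @pytest.mark.parametrize("all_sig,expected", [(True, 1.0), (False, 0.0)])
    def test_degenerate_all_or_none(self, all_sig, expected):
        table, manifest = self._toy([all_sig] * 8, ["3"] * 5 + ["X"] * 3)
        result = significance_rate(table, manifest)
        assert (result.per_chromosome["rate"] == expected).all()
        assert result.sd_rate == 0.0

    def test_totals_conserved_and_untestable_excluded(self, beta_design, manifest):
        beta, design = beta_design
        table = compare_groups(beta, design, "FC", "KD3")
        result = significance_rate(table, manifest)
        assert result.per_chromosome["n_total"].sum() == (~table["untestable"]).sum()

    def test_marker_missing_from_manifest_errors(self):
        table, manifest = self._toy([1, 0], ["1", "1"])
        with pytest.raises(DataError, match="missing from the manifest"):
            significance_rate(table, manifest.iloc[:1])


class TestUnionAndTransform:
    @staticmethod
    def _sig_table(markers, sig):
        return make_comparison_table(
            markers, [0.01 if m in sig else 0.9 for m in markers], [0.1] * len(markers)
        )

    @pytest.mark.parametrize(
        "sets,expected",
        [
            ((("a", "b"), ("c", "d", "e")), 5),  # disjoint
            ((("a", "b", "c"), ("a", "b", "c")), 3),  # identical
            ((("a", "b", "c"), ("b", "c", "d"), ("c",)), 4),  # overlapping
        ],
    )
    def test_union_sizes(self, sets, expected):
        universe = ["a", "b", "c", "d", "e"]
        tables = [self._sig_table(universe, set(s)) for s in sets]
        union = union_significant(tables)
        assert len(union) == expected
        assert union == set().union(*sets)

    def test_union_bounds(self, beta_design):
        beta, design = beta_design
        tables = [
            compare_groups(beta, design, a, b)
            for a, b in (("FC", "KD1"), ("FC", "KD3"), ("KD1", "KD3"))
        ]
        union = union_significant(tables)
        counts = [t["significant"].sum() for t in tables]
        assert max(counts) <= len(union) <= sum(counts)

    def test_neg_log10_transform(self):
        table = make_comparison_table(
            ["a", "b", "c", "d"], [1.0, 0.05, 0.0, np.nan], [0.1] * 4
        )
        out = neg_log10_p(table, cap=100.0)
        assert out["a"] == 0.0
        assert out["b"] == pytest.approx(1.3010299957, abs=1e-9)
        assert out["c"] == 100.0  # p = 0 capped
        assert np.isnan(out["d"])
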