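"""Median normalization, ANOVA/BH filtering, Welch tests and bipartition."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from graftnet.errors import DataError, ParameterError
from graftnet.filtering import (
    anova_filter,
    bh_adjust,
    bipartition_proteins,
    normalize_median,
    oneway_f,
    ttest_two_group,
    welch_t,
)

from conftest import make_table


class TestNormalizeMedian:
    def test_two_sample_worked_example(self):
        # sample medians 10 and 20, global median 15 -> factors 1.5 and 0.75
        table = make_table(np.array([[5.0, 10.0], [10.0, 20.0], [15.0, 30.0]]))
        out = normalize_median(table)
        np.testing.assert_allclose(out.data.median(axis=0), [15.0, 15.0])
        np.testing.assert_allclose(out.data["S0"], [7.5, 15.0, 22.5])

    def test_equal_medians_identity(self):
        table = make_table(np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]]))
        out = normalize_median(table)
        np.testing.assert_allclose(out.data, table.data)

    def test_single_sample_unchanged(self):
        table = make_table(np.array([[1.0], [5.0]]))
        np.testing.assert_allclose(normalize_median(table).data, table.data)

    def test_all_missing_sample_rejected(self):
        table = make_table(np.array([[np.nan, 1.0], [np.nan, 2.0]]))
        with pytest.raises(DataError, match="no observed values"):
            normalize_median(table)

    @given(st.lists(st.floats(1.0, 1e6), min_size=3, max_size=8))
    def test_rank_order_preserved(self, values):
        table = make_table(np.array([values, [v * 3 for v in values]]).T.reshape(len(values), 2))
        out = normalize_median(table)
        for col in out.data.columns:
            assert (
                out.data[col].rank(method="average") == table.data[col].rank(method="average")
            ).all()


class TestBhAdjust:
    def test_step_up_worked_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_identity(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_ones(self):
        assert (bh_adjust([1.0, 1.0, 1.0]) == 1.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_monotone_in_p(self, ps):
        q = bh_adjust(ps)
        order = np.argsort(ps)
        assert (np.diff(np.asarray(q)[order]) >= -1e-12).all()
        assert ((q >= np.asarray(ps) - 1e-12) & (q <= 1 + 1e-12)).all()


class TestOnewayF:
    def test_closed_form_worked_example(self):
        F, p = oneway_f([1, 2, 3], [2, 3, 4], [3, 4, 5])
        assert F == pytest.approx(3.0, abs=1e-12)
        from scipy.stats import f as fdist

        assert p == pytest.approx(fdist.sf(3.0, 2, 6), abs=1e-12)

    def test_matches_scipy_on_random_groups(self):
        from scipy.stats import f_oneway

        rng = np.random.default_rng(7)
        for _ in range(20):
            groups = [rng.normal(size=rng.integers(3, 7)) for _ in range(3)]
            F, p = oneway_f(*groups)
            ref = f_oneway(*groups)
            assert F == pytest.approx(ref.statistic, rel=1e-10)
            assert p == pytest.approx(ref.pvalue, rel=1e-10)


class TestAnovaFilter:
    @staticmethod
    def _table(values, conditions):
        return make_table(values, conditions=conditions)

    def test_constant_protein_dropped(self):
        values = np.array([[5.0] * 6, [1, 2, 3, 4, 5, 6]])
        table = self._table(values, ["A"] * 3 + ["B"] * 3)
        with pytest.warns(UserWarning, match="constant"):
            records, retained = anova_filter(table, fdr=0.05)
        assert "PROT0" not in set(records["protein_id"])
        assert "PROT0" not in retained

    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(10, 3))
        values = np.exp2(np.column_stack([base, base + 1.0]))  # equal within-group variance
        table = self._table(values, ["A"] * 3 + ["B"] * 3)
        records, _ = anova_filter(table, fdr=0.05)
        trec = ttest_two_group(
            table, {s: ("test" if c == "A" else "control") for s, c in table.condition_of().items()}
        )
        merged = records.merge(trec, on="protein_id", suffixes=("_f", "_t"))
        np.testing.assert_allclose(
            merged["statistic_f"], merged["statistic_t"] ** 2, rtol=1e-9
        )

    def test_planted_effect_detected(self):
        from graftnet.simulate import synth_static_proteome

        table, truth = synth_static_proteome(
            groups=[("IVC", 3), ("NEO", 3), ("ADV", 3)],
            n_proteins=300,
            frac_differential=0.1,
            effect_log2=2.0,
            noise_sd=0.25,
            seed=11,
        )
        records, retained = anova_filter(table, fdr=0.05)
        planted = truth.differential_set()
        sens = len(retained & planted) / len(planted)
        assert sens >= 0.9


class TestWelch:
    def test_worked_example(self):
        t, df, p = welch_t([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert df == pytest.approx(4.0)

    def test_identical_groups_t_zero_p_one(self):
        t, _, p = welch_t([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_label_swap_flips_sign(self):
        table = make_table(np.exp2(np.array([[1, 2, 3, 4, 5, 6.0], [2, 1, 3, 5, 4, 6.0]])))
        labels = {f"S{j}": ("test" if j < 3 else "control") for j in range(6)}
        swapped = {s: ("control" if v == "test" else "test") for s, v in labels.items()}
        a = ttest_two_group(table, labels)
        b = ttest_two_group(table, swapped)
        merged = a.merge(b, on="protein_id", suffixes=("_a", "_b"))
        np.testing.assert_allclose(merged["statistic_a"], -merged["statistic_b"])
        np.testing.assert_allclose(merged["p_a"], merged["p_b"])

    def test_zero_variance_both_groups_dropped(self):
        table = make_table(np.array([[2.0, 2.0, 2.0, 4.0, 4.0, 4.0], [1, 2, 3, 4, 5, 6.0]]))
        labels = {f"S{j}": ("test" if j < 3 else "control") for j in range(6)}
        with pytest.warns(UserWarning, match="zero variance"):
            records = ttest_two_group(table, labels)
        assert set(records["protein_id"]) == {"PROT1"}


class TestBipartition:
    @staticmethod
    def _separable_table(flip=False):
        high = np.exp2(np.array([[10.0] * 3 + [2.0] * 3] * 10))
        low = np.exp2(np.array([[2.0] * 3 + [10.0] * 3] * 10))
        values = np.vstack([high, low])
        rng = np.random.default_rng(0)
        values *= rng.uniform(0.95, 1.05, size=values.shape)
        conditions = (["NEO"] * 3 + ["IVC"] * 3) if flip else (["IVC"] * 3 + ["NEO"] * 3)
        return make_table(values, proteins=[f"P{i:02d}" for i in range(20)], conditions=conditions)

    def test_separable_split_with_orientation(self):
        table = self._separable_table()
        clusters = bipartition_proteins(table, set(table.proteins), control_condition="IVC")
        assert clusters.cluster1 == frozenset(f"P{i:02d}" for i in range(10))
        assert clusters.cluster2 == frozenset(f"P{i:02d}" for i in range(10, 20))

    def test_relabeling_conditions_swaps_clusters(self):
        t1 = self._separable_table()
        t2 = self._separable_table(flip=True)
        c1 = bipartition_proteins(t1, set(t1.proteins), control_condition="IVC")
        c2 = bipartition_proteins(t2, set(t2.proteins), control_condition="IVC")
        assert c1.cluster1 == c2.cluster2 and c1.cluster2 == c2.cluster1

    def test_partition_covers_retained(self):
        t = self._separable_table()
        c = bipartition_proteins(t, set(t.proteins), control_condition="IVC")
        assert c.cluster1 | c.cluster2 == set(t.proteins)
        assert not c.cluster1 & c.cluster2

    def test_too_few_proteins_rejected(self):
        t = self._separable_table()
        with pytest.raises(DataError):
            bipartition_proteins(t, {"P00"}, control_condition="IVC")
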