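"""Fractional profiles, EM mixture clustering, phase labels, condition sets."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from graftnet.errors import ParameterError
from graftnet.kinetics import (
    ClusterModel,
    classify_phase,
    condition_filter,
    fit_kinetic_clusters,
    fractional_normalize,
    profiles_from_table,
    set_concordance,
)
from graftnet.simulate import default_templates, synth_kinetic_proteome


class TestFractionalNormalize:
    def test_uniform(self):
        np.testing.assert_allclose(fractional_normalize([2, 2, 2, 2]), [0.25] * 4)

    def test_forced_arithmetic(self):
        np.testing.assert_allclose(fractional_normalize([1, 3, 4, 2]), [0.1, 0.3, 0.4, 0.2])

    def test_all_zero_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="all-zero"):
            assert fractional_normalize([0, 0, 0, 0]) is None

    @given(
        st.lists(st.floats(0.01, 1e4), min_size=2, max_size=8),
        st.floats(0.001, 1e5),
    )
    def test_scale_invariance(self, values, c):
        a = fractional_normalize(values)
        b = fractional_normalize([v * c for v in values])
        np.testing.assert_allclose(a, b, rtol=1e-9)


def _profiles_from_templates(templates, reps_per_template, conditions=("VG",)):
    rows = []
    for cond in conditions:
        i = 0
        for k, tpl in enumerate(templates):
            for _ in range(reps_per_template):
                rows.append((f"PR{i:04d}", cond, *tpl))
                i += 1
    cols = ["protein_id", "condition"] + [f"T{t}" for t in range(len(templates[0]))]
    return pd.DataFrame(rows, columns=cols)


class TestFitKineticClusters:
    def test_noiseless_templates_recovered_exactly(self):
        templates = default_templates(4, 10)
        profiles = _profiles_from_templates(templates, reps_per_template=8)
        model = fit_kinetic_clusters(profiles, K=10, seed=0, restarts=4)
        truth = np.repeat(np.arange(10), 8)
        assert adjusted_rand_score(truth, model.assignments["cluster"]) == 1.0

    def test_seeded_determinism(self):
        templates = default_templates(4, 6)
        rng = np.random.default_rng(5)
        profiles = _profiles_from_templates(templates, reps_per_template=6)
        tps = [c for c in profiles.columns if c.startswith("T")]
        noisy = profiles.copy()
        noisy[tps] = np.abs(noisy[tps].to_numpy() + rng.normal(0, 0.03, noisy[tps].shape))
        m1 = fit_kinetic_clusters(noisy, K=6, seed=42, restarts=3)
        m2 = fit_kinetic_clusters(noisy, K=6, seed=42, restarts=3)
        assert (m1.assignments["cluster"] == m2.assignments["cluster"]).all()
        np.testing.assert_array_equal(m1.centroids, m2.centroids)

    def test_loglik_monotone_within_run(self):
        templates = default_templates(4, 4)
        rng = np.random.default_rng(9)
        profiles = _profiles_from_templates(templates, reps_per_template=20)
        tps = [c for c in profiles.columns if c.startswith("T")]
        profiles[tps] = np.abs(profiles[tps].to_numpy() + rng.normal(0, 0.05, profiles[tps].shape))
        model = fit_kinetic_clusters(profiles, K=4, seed=1, restarts=1)
        path = np.asarray(model.loglik_path)
        assert (np.diff(path) >= -1e-6 * np.abs(path[:-1])).all()

    def test_parameter_validation(self):
        profiles = _profiles_from_templates(default_templates(4, 3), 1)
        with pytest.raises(ParameterError):
            fit_kinetic_clusters(profiles, K=1)
        with pytest.raises(ParameterError):
            fit_kinetic_clusters(profiles, K=50)


def _toy_model(centroids, assignments, phases=None):
    centroids = np.asarray(centroids, dtype=float)
    return ClusterModel(
        n_clusters=len(centroids),
        timepoints=("D1", "D3", "W2", "W4"),
        centroids=centroids,
        variances=np.full_like(centroids, 1e-3),
        weights=np.full(len(centroids), 1 / len(centroids)),
        assignments=pd.DataFrame(assignments, columns=["protein_id", "condition", "cluster"]),
        log_likelihood=0.0,
        loglik_path=(0.0,),
        converged=True,
        reseeded=False,
        phases=phases,
    )


class TestClassifyPhase:
    @pytest.mark.parametrize(
        "centroid,expected",
        [
            ((0.45, 0.35, 0.10, 0.10), "early"),
            ((0.25, 0.25, 0.25, 0.25), "flat"),
            ((0.10, 0.10, 0.30, 0.50), "late"),
        ],
    )
    def test_rule_application(self, centroid, expected):
        model = _toy_model([centroid], [("P1", "VG", 0)])
        out = classify_phase(model, ["D1", "D3"], ["W2", "W4"], flat_range=0.10)
        assert out.phases == (expected,)

    def test_sets_must_partition_timepoints(self):
        model = _toy_model([(0.4, 0.3, 0.2, 0.1)], [("P1", "VG", 0)])
        with pytest.raises(ParameterError):
            classify_phase(model, ["D1"], ["W2", "W4"])
        with pytest.raises(ParameterError):
            classify_phase(model, [], ["D1", "D3", "W2", "W4"])


class TestConditionFilter:
    @staticmethod
    def _model():
        centroids = [
            (0.45, 0.35, 0.10, 0.10),  # early
            (0.10, 0.10, 0.30, 0.50),  # late
            (0.25, 0.25, 0.25, 0.25),  # flat
        ]
        assignments = [
            ("P1", "VG", 0),
            ("P1", "IVC", 2),
            ("P2", "VG", 2),
            ("P2", "IVC", 0),
            ("P3", "IVC", 1),
            ("P4", "VG", 1),
        ]
        model = _toy_model(centroids, assignments)
        return classify_phase(model, ["D1", "D3"], ["W2", "W4"], flat_range=0.10)

    def test_kept_condition_drives_membership(self):
        sets = condition_filter(self._model(), "VG")
        # P1: VG profile early (IVC flat) -> early; P2: VG flat -> nowhere;
        # P3: IVC only -> nowhere; P4: VG late -> late
        assert sets["early"] == {"P1"}
        assert sets["late"] == {"P4"}

    def test_early_late_disjoint(self):
        sets = condition_filter(self._model(), "VG")
        assert not sets["early"] & sets["late"]

    def test_unknown_condition_rejected(self):
        with pytest.raises(ParameterError, match="unknown condition"):
            condition_filter(self._model(), "XXX")

    def test_phases_required(self):
        model = _toy_model([(0.4, 0.3, 0.2, 0.1)], [("P1", "VG", 0)])
        with pytest.raises(ParameterError, match="phases"):
            condition_filter(model, "VG")


class TestProfilesFromTable:
    def test_replicate_averaging_and_normalization(self):
        table, truth = synth_kinetic_proteome(n_proteins=20, noise_sd=0.0, seed=3)
        profiles, timepoints = profiles_from_table(table)
        assert timepoints == ["D1", "D3", "W2", "W4"]
        # noiseless: every profile equals its planted template exactly
        labels = truth.labels()
        for rec in profiles.itertuples(index=False):
            tpl = truth.templates[labels.loc[(rec.protein_id, rec.condition)] - 1]
            np.testing.assert_allclose([rec.D1, rec.D3, rec.W2, rec.W4], tpl, atol=1e-12)


class TestSetConcordance:
    def test_worked_example(self):
        c = set_concordance({"A", "B", "C"}, {"B", "C", "D"})
        assert (c.n_shared, c.n_only_a, c.n_only_b, c.jaccard) == (2, 1, 1, 0.5)

    def test_identical_and_disjoint(self):
        assert set_concordance({"A"}, {"A"}).jaccard == 1.0
        assert set_concordance({"A"}, {"B"}).jaccard == 0.0
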