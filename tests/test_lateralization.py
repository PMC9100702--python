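import numpy as np
import pytest

from rbfgcn import (
    BrainNetwork,
    MEASURES,
    SyntheticCohortConfig,
    detect_modules,
    generate_cohort,
    graph_measures,
    lateralization_report,
    paired_wilcoxon,
    regional_difference,
)

from _oracles import exact_wilcoxon_p, exhaustive_betweenness
from conftest import random_symmetric


def cohort_with_suvr(values, m=6):
    """One-subject cohorts with prescribed SUVR vectors."""
    A = np.zeros((m, m))
    return [BrainNetwork(A, np.asarray(v, dtype=float)[:, None]) for v in values]


class TestRegionalDifference:
    def test_identical_cohorts_give_zero_profile(self, rng):
        suvr = rng.random((3, 6)) + 1
        prof = regional_difference(cohort_with_suvr(suvr),
                                   cohort_with_suvr(suvr))
        np.testing.assert_allclose(prof.values, 0.0, atol=1e-15)

    def test_constructed_shift_recovered(self, rng):
        base = rng.random((4, 6)) + 1
        shifted = base.copy()
        shifted[:, 5] += 0.3
        prof = regional_difference(cohort_with_suvr(shifted),
                                   cohort_with_suvr(base))
        np.testing.assert_allclose(prof.values[5], 0.3, atol=1e-12)
        np.testing.assert_allclose(np.delete(prof.values, 5), 0.0, atol=1e-12)

    def test_antisymmetric_under_cohort_swap(self, rng):
        a = cohort_with_suvr(rng.random((3, 6)))
        b = cohort_with_suvr(rng.random((5, 6)))
        np.testing.assert_allclose(
            regional_difference(a, b).values,
            -regional_difference(b, a).values,
            atol=1e-15,
        )

    def test_empty_cohort_rejected(self, rng):
        with pytest.raises(ValueError, match="nonempty"):
            regional_difference([], cohort_with_suvr(rng.random((2, 6))))


class TestGraphMeasures:
    def test_unweighted_triangle(self):
        A = np.ones((3, 3)) - np.eye(3)
        table = graph_measures(A, modules=np.zeros(3, dtype=int))
        np.testing.assert_allclose(table["clustering"], 1.0)
        np.testing.assert_allclose(table["betweenness"], 0.0)
        np.testing.assert_allclose(table["strength"], 2.0)

    def test_star_hub_betweenness(self):
        A = np.zeros((5, 5))
        A[0, 1:] = A[1:, 0] = 1.0
        table = graph_measures(A, modules=np.zeros(5, dtype=int))
        assert table["betweenness"][0] == 6.0  # all C(4,2) leaf pairs
        np.testing.assert_allclose(table["betweenness"][1:], 0.0)

    def test_pagerank_stationarity_and_normalization(self, rng):
        A = random_symmetric(rng, 12, density=1.0)
        table = graph_measures(A, modules=np.zeros(12, dtype=int))
        p = table["pagerank"]
        assert abs(p.sum() - 1.0) < 1e-12
        # stationarity: p_i = (1-d)/n + d * sum_j p_j w_ji / s_j
        s = A.sum(axis=1)
        residual = (1 - 0.85) / 12 + 0.85 * (A / s[:, None]).T @ p - p
        assert np.abs(residual).max() < 1e-10

    def test_strength_is_row_sum_and_bounds_hold(self, rng):
        A = random_symmetric(rng, 10)
        modules = detect_modules(A, seed=0)
        table = graph_measures(A, modules=modules)
        np.testing.assert_array_equal(table["strength"], A.sum(axis=1))
        assert np.all((table["clustering"] >= 0) & (table["clustering"] <= 1))
        assert np.all((table["participation"] >= 0) & (table["participation"] <= 1))

    def test_betweenness_matches_exhaustive_enumeration(self, rng):
        for m in (4, 5, 6, 7):
            A = random_symmetric(rng, m, density=0.8)
            table = graph_measures(A, modules=np.zeros(m, dtype=int))
            np.testing.assert_allclose(
                table["betweenness"], exhaustive_betweenness(A), atol=1e-9
            )

    def test_isolated_node_conventions(self):
        A = np.zeros((4, 4))
        A[0, 1] = A[1, 0] = 2.0
        table = graph_measures(A, modules=np.array([0, 0, 1, 2]))
        assert table["strength"][3] == 0.0
        assert table["clustering"][3] == 0.0
        assert table["participation"][3] == 0.0

    def test_within_module_z_standardized_per_module(self, rng):
        A = random_symmetric(rng, 20, density=1.0)
        modules = np.repeat([0, 1], 10)
        z = graph_measures(A, modules=modules)["within_module_z"]
        for s in (0, 1):
            vals = z[modules == s]
            assert abs(vals.mean()) < 1e-12
            assert abs(vals.std() - 1.0) < 1e-12


class TestModules:
    def test_two_disconnected_cliques(self):
        A = np.zeros((8, 8))
        A[:4, :4] = 1.0
        A[4:, 4:] = 1.0
        np.fill_diagonal(A, 0.0)
        modules = detect_modules(A, seed=0)
        assert len(set(modules)) == 2
        assert len(set(modules[:4])) == 1 and len(set(modules[4:])) == 1
        assert modules[0] != modules[4]

    def test_complete_graph_single_module(self):
        A = np.ones((6, 6)) - np.eye(6)
        assert len(set(detect_modules(A, seed=0))) == 1

    def test_seeded_determinism(self, rng):
        A = random_symmetric(rng, 15)
        np.testing.assert_array_equal(detect_modules(A, seed=5),
                                      detect_modules(A, seed=5))


class TestPairedWilcoxon:
    def test_identical_sides_degenerate(self):
        res = paired_wilcoxon(np.ones(10), np.ones(10))
        assert res.p_value == 1.0
        assert res.n_pairs == 0

    def test_large_constant_shift_is_overwhelming(self, rng):
        right = rng.random(74)
        res = paired_wilcoxon(right + 5.0, right)
        assert res.p_value < 1e-6

    def test_matches_exact_enumeration_small_n(self, rng):
        for n in (5, 6, 8, 10):
            for _ in range(5):
                left = rng.standard_normal(n) * 2
                right = rng.standard_normal(n)
                res = paired_wilcoxon(left, right)
                expected = exact_wilcoxon_p(left - right)
                assert res.p_value == pytest.approx(expected, abs=1e-12)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            paired_wilcoxon(rng.random(5), rng.random(6))


class TestLateralizationReport:
    def test_known_effect_flags_all_six_measures(self):
        """With hub-concentrated topological asymmetry and an amyloid offset,
        every paired test rejects at 0.05."""
        config = SyntheticCohortConfig(
            lateralization_effect=1.5, lateralization_hubs=7, seed=42,
        )
        networks, _ = generate_cohort(config)
        report = lateralization_report(networks, seed=0)
        assert report.amyloid_test.p_value < 0.05
        for name in MEASURES:
            assert report.measure_tests[name].p_value < 0.05, name

    def test_symmetric_generator_amyloid_null_calibration(self):
        """Under a fully symmetric generator the amyloid left/right pairs are
        iid, so the paired test rejects at roughly the nominal 5% rate."""
        rejections = 0
        reps = 40
        for r in range(reps):
            config = SyntheticCohortConfig(
                n_per_class=(15, 15, 15), m=40,
                lateralization_effect=1.0, asymmetry_shift=0.0,
                asymmetry_stage_gain=0.0, seed=5000 + r,
            )
            networks, _ = generate_cohort(config)
            report = lateralization_report(networks, seed=r)
            rejections += report.amyloid_test.p_value < 0.05
        assert rejections / reps <= 0.15

    def test_symmetric_network_zero_difference_matrix(self):
        half = np.array([[0.0, 2.0], [2.0, 0.0]])
        A = np.block([[half, np.ones((2, 2))], [np.ones((2, 2)), half]])
        np.fill_diagonal(A, 0.0)
        net = BrainNetwork(A, np.ones((4, 1)))
        report = lateralization_report([net, net], seed=0)
        np.testing.assert_allclose(report.difference_matrix, 0.0, atol=1e-15)

    def test_subject_mode_runs_and_pairs_match(self, worked_cohort):
        report = lateralization_report(worked_cohort, mode="subject", seed=0)
        assert report.amyloid_test.n_pairs <= 3
        assert set(report.measure_tests) == set(MEASURES)
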