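import numpy as np
import pytest

from gmmresid import (
    DegenerateClassError,
    EnumerationConfig,
    GrowthModelSpec,
    LongitudinalData,
    SimulationDesign,
    assign_classes,
    closeness_from_numerators,
    closeness_measure,
    fit_growth_model,
    initialize_partition,
    iterate,
    residual_bundle,
    select_num_classes,
    simulate,
)
from gmmresid.class_enumerator import _repair_small_classes, _stop_iteration
from gmmresid.residual_engine import ResidualBundle


def rand_index_perfect(a, b):
    """True when two labelings induce the same partition of individuals."""
    pairs_a = np.equal.outer(a, a)
    pairs_b = np.equal.outer(b, b)
    return np.array_equal(pairs_a, pairs_b)


class TestClosenessMeasure:
    def test_three_individual_hand_value(self):
        cm = closeness_from_numerators(np.array([[1.0], [1.0], [4.0]]))
        # denominator = (1+1+4)/(3-2) = 6
        assert np.allclose(cm.cm[:, 0], [1 / 6, 1 / 6, 4 / 6])

    def test_zero_residual_gives_zero_cm(self):
        cm = closeness_from_numerators(np.array([[0.0], [2.0], [3.0]]))
        assert cm.cm[0, 0] == 0.0

    def test_columns_sum_to_n_minus_2_random(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n, k = rng.integers(3, 40), rng.integers(1, 5)
            raw = rng.exponential(size=(n, k)) + 1e-12
            cm = closeness_from_numerators(raw)
            assert np.allclose(cm.cm.sum(axis=0), n - 2, atol=1e-9)

    def test_matches_brute_force_formula(self, linear_spec):
        # build bundles from a real fit and re-evaluate the formula by loops
        d = simulate(SimulationDesign(k=1, n=40), seed=3)
        model = fit_growth_model(d.data, linear_spec)
        b = residual_bundle(model, d.data, class_id=1)
        cm = closeness_measure([b], d.data)
        n = d.data.n
        a_brute = np.zeros(n)
        for i in range(n):
            for t in range(4):
                for j in range(2):
                    a_brute[i] += b.icr[i, t, j] ** 2 / b.communality[t, j]
        cm_brute = a_brute / (a_brute.sum() / (n - 2))
        assert np.allclose(cm.cm[:, 0], cm_brute, atol=1e-10)

    def test_too_few_individuals_rejected(self):
        with pytest.raises(ValueError):
            closeness_from_numerators(np.ones((2, 1)))

    def test_zero_communality_rejected(self):
        bundle = ResidualBundle(
            scores=np.zeros((5, 2)), icr=np.ones((5, 4, 2)),
            communality=np.zeros((4, 2)), class_id=1,
        )
        with pytest.raises(DegenerateClassError):
            bundle.closeness_numerator()


class TestAssignClasses:
    def test_argmin_row(self):
        assert assign_classes(np.array([[0.2, 0.9]]))[0] == 1
        assert assign_classes(np.array([[0.9, 0.2]]))[0] == 2

    def test_tie_breaks_to_lowest_index(self):
        assert assign_classes(np.array([[0.5, 0.5]]))[0] == 1

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(8)
        cm = rng.uniform(size=(60, 4))
        labels = assign_classes(cm)
        for i in range(60):
            best, best_k = np.inf, 0
            for k in range(4):
                if cm[i, k] < best:
                    best, best_k = cm[i, k], k + 1
            assert labels[i] == best_k

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            assign_classes(np.array([[np.nan, 1.0]]))


class TestStoppingRule:
    def test_strictly_below_five_percent_stops(self):
        assert _stop_iteration(0.049, 0.05)
        assert not _stop_iteration(0.05, 0.05)
        assert not _stop_iteration(0.051, 0.05)
        assert _stop_iteration(0.0, 0.05)


class TestRepair:
    def test_small_class_dissolved_and_reassigned(self):
        labels = np.array([1] * 20 + [2] * 3)
        cm = np.zeros((23, 2))
        cm[:, 1] = 0.1  # class 2 slightly worse for everyone
        new_labels, survivors, dissolved = _repair_small_classes(labels, cm, 10)
        assert dissolved
        assert np.array_equal(survivors, [1])
        assert np.all(new_labels == 1)

    def test_no_change_when_all_large(self):
        labels = np.array([1] * 15 + [2] * 15)
        cm = np.tile([0.0, 1.0], (30, 1))
        new_labels, survivors, dissolved = _repair_small_classes(labels, cm, 10)
        assert not dissolved
        assert np.array_equal(new_labels, labels)


class TestInitialization:
    def test_k_one_is_all_ones(self, linear_spec, two_class_separated):
        model = fit_growth_model(two_class_separated.data, linear_spec)
        labels = initialize_partition(model, two_class_separated.data, 1)
        assert np.all(labels == 1)

    def test_deterministic(self, linear_spec, two_class_separated):
        model = fit_growth_model(two_class_separated.data, linear_spec)
        a = initialize_partition(model, two_class_separated.data, 2)
        b = initialize_partition(model, two_class_separated.data, 2)
        assert np.array_equal(a, b)

    def test_separates_well_separated_blobs(self, linear_spec, two_class_separated):
        from sklearn.metrics import adjusted_rand_score

        model = fit_growth_model(two_class_separated.data, linear_spec)
        labels = initialize_partition(model, two_class_separated.data, 2)
        assert adjusted_rand_score(two_class_separated.true_labels, labels) > 0.5

    def test_too_many_classes_rejected(self, linear_spec, two_class_separated):
        model = fit_growth_model(two_class_separated.data, linear_spec)
        with pytest.raises(ValueError):
            initialize_partition(model, two_class_separated.data, 50)


class TestIterate:
    def test_converges_fast_from_truth_when_separated(self, linear_spec,
                                                      two_class_separated):
        part = iterate(two_class_separated.data, linear_spec,
                       two_class_separated.true_labels)
        assert part.converged
        assert part.n_iterations <= 2
        assert part.history[-1] < 0.05

    def test_label_permutation_equivariance(self, linear_spec, two_class_separated):
        init = two_class_separated.true_labels
        a = iterate(two_class_separated.data, linear_spec, init)
        b = iterate(two_class_separated.data, linear_spec, 3 - init)
        assert rand_index_perfect(a.labels, b.labels)

    def test_history_and_sizes_consistent(self, linear_spec, two_class_separated):
        part = iterate(two_class_separated.data, linear_spec,
                       two_class_separated.true_labels)
        assert len(part.history) == part.n_iterations
        assert part.class_sizes.sum() == two_class_separated.data.n
        assert all(s > 0 for s in part.class_sizes)

    def test_closeness_attached_to_final_models(self, linear_spec,
                                                two_class_separated):
        part = iterate(two_class_separated.data, linear_spec,
                       two_class_separated.true_labels)
        assert part.closeness is not None
        n = two_class_separated.data.n
        assert np.allclose(part.closeness.cm.sum(axis=0), n - 2, atol=1e-8)


class TestSelection:
    def test_well_separated_two_classes_found(self, linear_spec):
        from sklearn.metrics import adjusted_rand_score

        d = simulate(SimulationDesign(k=2, n=540, model=1, md=5.0), seed=31)
        res = select_num_classes(d.data, linear_spec, k_max=5)
        assert res.k_hat == 2
        assert adjusted_rand_score(d.true_labels, res.partition.labels) > 0.85

    def test_k_hat_bounded_by_k_max(self, linear_spec):
        d = simulate(SimulationDesign(k=4, n=360, model=1, md=5.0), seed=17)
        res = select_num_classes(d.data, linear_spec, k_max=2)
        assert 1 <= res.k_hat <= 2

    def test_diagnostics_cover_scanned_candidates(self, linear_spec):
        d = simulate(SimulationDesign(k=2, n=360, model=1, md=5.0), seed=23)
        res = select_num_classes(
            d.data, linear_spec, k_max=4, config=EnumerationConfig(exhaustive=True)
        )
        ks = [c.k for c in res.diagnostics]
        assert ks[0] == 1
        assert res.k_hat in ks
        accepted = [c.k for c in res.diagnostics if c.accepted]
        assert max(accepted) == res.k_hat

    def test_report_is_json_serialisable(self, linear_spec, two_class_separated):
        import json

        res = select_num_classes(two_class_separated.data, linear_spec, k_max=3)
        payload = json.dumps(res.to_report())
        assert '"k_hat"' in payload
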