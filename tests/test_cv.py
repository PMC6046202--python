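from collections import Counter

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gsiscan import (
    ConfusionCounts,
    CostSpec,
    CvSpec,
    LabelMap,
    cv_error,
    gsi,
    make_stratified_folds,
    misclassification_rate,
    repeated_cv_error,
    total_prob_misclassification,
)
from gsiscan.synthetic import generate_two_class, spherical_two_class_spec


def _label_map(n1, n2):
    genes = [f"g{i}" for i in range(n1 + n2)]
    return LabelMap({g: ("ET" if i < n1 else "JA") for i, g in enumerate(genes)})


class TestStratifiedFolds:
    def test_pathway_sized_classes(self):
        lm = _label_map(86, 48)
        folds = make_stratified_folds(lm, K=10, seed=3)
        per_fold = Counter()
        for g, f in folds.items():
            per_fold[(f, lm.assignments[g])] += 1
        for f in range(10):
            assert per_fold[(f, "ET")] in (8, 9)
            assert per_fold[(f, "JA")] in (4, 5)
        assert sum(per_fold.values()) == 134

    def test_exact_division(self):
        folds = make_stratified_folds(_label_map(20, 20), K=10, seed=1)
        lm = _label_map(20, 20)
        per_fold = Counter((f, lm.assignments[g]) for g, f in folds.items())
        assert all(v == 2 for v in per_fold.values())

    def test_class_smaller_than_k_rejected(self):
        with pytest.raises(ValueError, match="smaller K"):
            make_stratified_folds(_label_map(30, 7), K=10, seed=0)

    def test_deterministic_and_seed_sensitive(self):
        lm = _label_map(30, 20)
        a = make_stratified_folds(lm, 5, seed=42)
        b = make_stratified_folds(lm, 5, seed=42)
        c = make_stratified_folds(lm, 5, seed=43)
        assert a == b
        assert a != c


class TestErrorRates:
    def test_mer_example(self):
        assert misclassification_rate(ConfusionCounts(50, 50, 5, 10)) == pytest.approx(0.15)

    def test_perfect_classification(self):
        assert misclassification_rate(ConfusionCounts(30, 20, 0, 0)) == 0.0

    @given(
        st.integers(1, 200), st.integers(1, 200),
        st.floats(0, 1), st.floats(0, 1),
    )
    def test_mer_equals_prior_weighted_form(self, N1, N2, f1, f2):
        # the pooled-count and prior-weighted forms of the error rate coincide
        n_21, n_12 = int(f1 * N1), int(f2 * N2)
        cc = ConfusionCounts(N1, N2, n_21, n_12)
        pooled = misclassification_rate(cc)
        p1, p2 = N1 / (N1 + N2), N2 / (N1 + N2)
        weighted = p1 * (n_21 / N1) + p2 * (n_12 / N2)
        assert abs(pooled - weighted) < 1e-12

    def test_tpm_example_and_linearity_in_costs(self):
        assert total_prob_misclassification(0.5, 0.1, 0.5, 0.3) == pytest.approx(0.2)
        assert total_prob_misclassification(0.5, 0.0, 0.5, 0.0) == 0.0
        double = CostSpec(2.0, 2.0)
        assert total_prob_misclassification(0.3, 0.2, 0.7, 0.4, double) == pytest.approx(
            2 * total_prob_misclassification(0.3, 0.2, 0.7, 0.4)
        )

    def test_invalid_confusion_counts(self):
        with pytest.raises(ValueError):
            ConfusionCounts(5, 5, 6, 0)

    def test_gsi_values(self):
        assert gsi(0.302) == pytest.approx(0.698)
        assert gsi(0.0) == 1.0
        assert gsi(0.5) == 0.5
        with pytest.raises(ValueError):
            gsi(1.2)


class TestCvError:
    def test_deterministic_given_seed(self, fast_cv_spec):
        fm, lm = generate_two_class(spherical_two_class_spec(n_per_class=(40, 40), seed=2))
        a = cv_error(fm, lm, fast_cv_spec, seed=9)
        b = cv_error(fm, lm, fast_cv_spec, seed=9)
        assert a == b

    def test_indistinguishable_classes_near_half(self, fast_cv_spec):
        fm, lm = generate_two_class(
            spherical_two_class_spec(delta=0.0, n_per_class=(200, 200), seed=3)
        )
        err = cv_error(fm, lm, fast_cv_spec, seed=1)
        assert err == pytest.approx(0.5, abs=0.05)

    def test_widely_separated_classes_near_zero(self, fast_cv_spec):
        fm, lm = generate_two_class(
            spherical_two_class_spec(delta=10.0, n_per_class=(100, 100), seed=4)
        )
        assert cv_error(fm, lm, fast_cv_spec, seed=1) <= 0.02

    def test_lda_classifier_path(self, fast_cv_spec):
        fm, lm = generate_two_class(spherical_two_class_spec(n_per_class=(60, 60), seed=5))
        spec = CvSpec(C=1, seeds=(1,), classifier="lda")
        err = cv_error(fm, lm, spec, seed=1)
        assert 0.0 <= err <= 0.5


class TestRepeatedCv:
    def test_constant_error_maps_to_table_gsi(self, monkeypatch):
        # if every per-seed CV returns 0.302 each run GSI must be 0.698
        import gsiscan.cv as cvmod

        fm, lm = generate_two_class(spherical_two_class_spec(n_per_class=(30, 30), seed=6))
        monkeypatch.setattr(cvmod, "cv_error", lambda *a, **k: 0.302)
        res = cvmod.repeated_cv_error(fm, lm, CvSpec())
        assert np.allclose(res.run_gsi, 0.698)
        assert res.mean_gsi == pytest.approx(0.698)

    def test_seed_permutation_within_batch_invariant(self):
        fm, lm = generate_two_class(spherical_two_class_spec(n_per_class=(40, 40), seed=7))
        base = CvSpec(C=5, seeds=(1, 2, 3, 4, 5), tol=1e-6)
        perm = CvSpec(C=5, seeds=(4, 1, 5, 3, 2), tol=1e-6)
        a = repeated_cv_error(fm, lm, base)
        b = repeated_cv_error(fm, lm, perm)
        assert np.allclose(a.run_errors, b.run_errors)

    def test_gsi_error_duality(self, fast_cv_spec):
        fm, lm = generate_two_class(spherical_two_class_spec(n_per_class=(40, 40), seed=8))
        res = repeated_cv_error(fm, lm, fast_cv_spec)
        assert np.allclose(res.run_gsi, 1.0 - res.run_errors)
        assert res.mean_gsi == pytest.approx(res.run_gsi.mean())
        assert np.all((0 <= res.run_gsi) & (res.run_gsi <= 1))

    def test_low_variance_across_runs_when_separated(self):
        fm, lm = generate_two_class(spherical_two_class_spec(delta=6.0, n_per_class=(80, 80), seed=9))
        res = repeated_cv_error(fm, lm, CvSpec(C=2, seeds=tuple(range(1, 11)), tol=1e-6))
        assert np.std(res.run_gsi) <= 0.02

    def test_spec_validation(self):
        with pytest.raises(ValueError, match="multiple of C"):
            CvSpec(C=10, seeds=(1, 2, 3))
        with pytest.raises(ValueError, match="classifier"):
            CvSpec(classifier="svm")
        with pytest.raises(ValueError, match="K"):
            CvSpec(K=1)
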