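import math
from dataclasses import replace

import numpy as np
import pytest

from gsiscan import (
    ClassMixture,
    FeatureMatrix,
    GmdaModel,
    LabelMap,
    MixtureComponent,
    bic_score,
    class_posterior,
    em_fit,
    fit_gmda,
    select_class_model,
)
from gsiscan.gmda import PARAMETERIZATIONS, n_free_params
from gsiscan.synthetic import default_pathway_spec, generate_two_class


def _single_gaussian_model(means, sds, priors, labels=("A", "B")):
    mixtures = []
    for m, s in zip(means, sds):
        comp = MixtureComponent(1.0, np.atleast_1d(float(m)), np.atleast_2d(float(s) ** 2))
        mixtures.append(ClassMixture([comp], "full-varying", 0.0, 0.0, 3))
    return GmdaModel(tuple(labels), tuple(mixtures), np.asarray(priors, float))


class TestParameterCounts:
    @pytest.mark.parametrize(
        "param,G,d,expected",
        [
            ("full-varying", 2, 2, 11),  # 1 weight + 4 means + 6 covariance terms
            ("full-equal", 2, 2, 8),
            ("diagonal-varying", 2, 2, 9),
            ("diagonal-equal", 2, 2, 7),
            ("spherical-varying", 2, 2, 7),
            ("spherical-equal", 2, 2, 6),
            ("full-varying", 1, 3, 9),
            ("spherical-equal", 3, 4, 15),
        ],
    )
    def test_hand_counts(self, param, G, d, expected):
        assert n_free_params(param, G, d) == expected


class TestBic:
    def test_log_e_case(self):
        assert bic_score(0.0, 3, math.e) == pytest.approx(-3.0)

    def test_arithmetic(self):
        assert bic_score(-100.0, 10, 100) == pytest.approx(-200 - 10 * math.log(100))

    def test_more_params_always_worse_at_fixed_loglik(self):
        assert bic_score(-5.0, 4, 50) < bic_score(-5.0, 3, 50)


class TestEmFit:
    def test_single_component_closed_form(self, rng):
        X = rng.normal(size=(40, 2))
        fit = em_fit(X, 1, "full-varying")
        assert np.allclose(fit.components[0].mean, X.mean(axis=0))
        ml_cov = (X - X.mean(axis=0)).T @ (X - X.mean(axis=0)) / len(X)
        assert np.allclose(fit.components[0].covariance, ml_cov)

    def test_recovers_separated_cluster_means(self, rng):
        X = np.vstack([rng.normal(0, 1, (200, 2)), rng.normal(10, 1, (200, 2))])
        fit = em_fit(X, 2, "spherical-varying", seed=3)
        means = sorted(fit.means.tolist())
        assert np.allclose(means[0], [0, 0], atol=0.2)
        assert np.allclose(means[1], [10, 10], atol=0.2)

    @pytest.mark.parametrize("param", PARAMETERIZATIONS)
    def test_loglik_monotone_nondecreasing(self, param, rng):
        X = rng.normal(size=(60, 2)) * [1.0, 2.5]
        fit = em_fit(X, 2, param, seed=7)
        trace = np.array(fit.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-7 * (1 + np.abs(trace[:-1])))

    def test_equal_variant_shares_covariance_across_components(self, rng):
        X = np.vstack([rng.normal(0, 1, (80, 2)), rng.normal(6, 1, (80, 2))])
        fit = em_fit(X, 2, "full-equal", seed=1)
        assert np.allclose(fit.components[0].covariance, fit.components[1].covariance)

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(100, 2))
        a = em_fit(X, 2, "full-varying", seed=11)
        b = em_fit(X, 2, "full-varying", seed=11)
        assert a.log_likelihood == b.log_likelihood
        assert np.array_equal(a.means, b.means)
        assert np.array_equal(a.covariances, b.covariances)
        assert np.array_equal(a.weights, b.weights)

    def test_too_few_points_rejected(self, rng):
        with pytest.raises(ValueError, match="G=3"):
            em_fit(rng.normal(size=(2, 2)), 3, "full-varying")


class TestModelSelection:
    def test_unimodal_cloud_selects_one_component(self, rng):
        X = rng.normal(size=(300, 2))
        assert select_class_model(X, G_max=2, seed=2).n_components == 1

    def test_bimodal_cloud_selects_two_components(self, rng):
        X = np.vstack([rng.normal(0, 1, (200, 2)), rng.normal(8, 1, (200, 2))])
        assert select_class_model(X, G_max=2, seed=2).n_components == 2

    def test_gmax_one_boundary(self, rng):
        fit = select_class_model(rng.normal(size=(50, 2)), G_max=1, seed=2)
        assert fit.n_components == 1


class TestPosterior:
    def test_identical_densities_give_priors(self):
        model = _single_gaussian_model([0, 0], [1, 1], [0.5, 0.5])
        assert class_posterior(model, [0.3]) == pytest.approx((0.5, 0.5))

    def test_degenerate_prior_dominates(self):
        model = _single_gaussian_model([-1, 1], [1, 1], [1.0, 0.0])
        for x in (-5.0, 0.0, 5.0):
            assert class_posterior(model, [x]) == pytest.approx((1.0, 0.0))

    def test_one_dimensional_log_ratio(self):
        # classes N(-1,1), N(1,1), equal priors: midpoint 0.5/0.5; at x=1 the
        # density ratio is exp(2) in favor of the second class
        model = _single_gaussian_model([-1, 1], [1, 1], [0.5, 0.5])
        assert class_posterior(model, [0.0]) == pytest.approx((0.5, 0.5), abs=1e-12)
        p1, p2 = class_posterior(model, [1.0])
        assert p2 / p1 == pytest.approx(math.exp(2), rel=1e-9)

    def test_normalization_at_random_points(self, rng):
        model = _single_gaussian_model([-2, 3], [1.5, 0.7], [0.3, 0.7])
        pts = rng.normal(scale=4, size=20)
        for x in pts:
            p = class_posterior(model, [x])
            assert abs(sum(p) - 1.0) < 1e-12


class TestFitGmda:
    def test_priors_are_class_proportions(self, pathway_data):
        fm, lm = pathway_data
        model = fit_gmda(fm, lm, family=("spherical-varying",))
        assert model.class_labels == ("JA", "ET")
        assert model.class_priors == pytest.approx([48 / 134, 86 / 134])

    def test_recovers_two_pathway_component_structure(self):
        # At 10x the default sizes the JA class should resolve into its
        # near-origin and displaced components; ET stays a single component.
        spec = replace(default_pathway_spec(seed=21), n_per_class=(480, 860))
        fm, lm = generate_two_class(spec)
        sub = fm.to_frame()[["4-7", "4-8"]]
        model = fit_gmda(FeatureMatrix(fm.gene_ids, ["4-7", "4-8"], sub.to_numpy()), lm)
        ja, et = model.class_mixtures
        assert ja.n_components == 2
        assert et.n_components == 1
        ja_means = sorted(ja.means.tolist(), key=lambda m: np.hypot(*m))
        assert np.allclose(ja_means[0], [0.0, 0.0], atol=0.3)
        assert np.allclose(ja_means[1], [2.276, 1.663], atol=0.3)
        assert np.allclose(et.components[0].mean, [0.537, 0.406], atol=0.2)

    def test_same_distribution_posterior_near_priors(self, rng):
        X = rng.normal(size=(1000, 2))
        genes = [f"g{i}" for i in range(1000)]
        lm = LabelMap({g: ("A" if i < 500 else "B") for i, g in enumerate(genes)})
        model = fit_gmda(FeatureMatrix(genes, ["a", "b"], X), lm, seed=4)
        post = model.predict_proba(rng.normal(size=(400, 2)))
        assert np.median(np.abs(post[:, 0] - 0.5)) < 0.1

    def test_small_class_rejected(self, rng):
        genes = ["g1", "g2", "g3", "g4", "g5", "g6"]
        lm = LabelMap({g: ("A" if i < 3 else "B") for i, g in enumerate(genes)})
        fm = FeatureMatrix(genes, ["a", "b"], rng.normal(size=(6, 2)))
        with pytest.raises(ValueError, match="at least 2\\*d"):
            fit_gmda(fm, lm)

    def test_json_round_trip_preserves_predictions(self, pathway_data, rng):
        fm, lm = pathway_data
        model = fit_gmda(fm, lm, family=("diagonal-varying", "full-varying"))
        back = GmdaModel.from_json(model.to_json())
        pts = rng.normal(size=(50, fm.n_features))
        assert np.allclose(model.predict_proba(pts), back.predict_proba(pts), atol=1e-12)
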