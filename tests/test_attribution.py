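"""LDA classifier, LOOCV screening, pruning, and bootstrap attribution.

Independent oracles: a brute-force pooled-covariance Gaussian Bayes rule
coded from the definition, and scikit-learn's LDA as a cross-implementation
check of hard labels.
"""

import numpy as np
import pandas as pd
import pytest

import fatrophic as ft
from fatrophic.attribution import (
    SourceLibrary,
    aggregate_contributions,
    bootstrap_attribution,
    classify,
    classify_matrix,
    drop_unshared_pufa,
    fit_lda,
    loocv,
    prune_sources,
)


def random_library(seed, k=3, d=7, n=15, spread=4.0):
    rng = np.random.default_rng(seed)
    groups = {}
    for c in range(k):
        mean = rng.normal(scale=spread, size=d)
        groups[f"g{c}"] = rng.normal(size=(n, d)) + mean
    return SourceLibrary(groups, tuple(f"v{j}" for j in range(d))), rng


def bayes_rule_oracle(groups, x, ridge):
    """Brute-force pooled-covariance Gaussian Bayes rule, equal priors."""
    names = list(groups)
    means = {n: g.mean(axis=0) for n, g in groups.items()}
    d = x.shape[1]
    scatter = np.zeros((d, d))
    n_tot = 0
    for g in groups.values():
        c = g - g.mean(axis=0)
        scatter += c.T @ c
        n_tot += len(g)
    cov = scatter / (n_tot - len(groups)) + ridge * np.eye(d)
    inv = np.linalg.inv(cov)
    labels = []
    for row in x:
        scores = [-(row - means[n]) @ inv @ (row - means[n]) / 2 for n in names]
        labels.append(names[int(np.argmax(scores))])
    return labels


class TestFitAndClassify:
    def test_two_1d_classes_boundary_at_midpoint(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, size=(50, 1))
        b = rng.normal(2, 1, size=(50, 1))
        # center so the empirical class means are exactly 0 and 2
        a, b = a - a.mean(), b - b.mean() + 2.0
        lib = SourceLibrary({"a": a, "b": b}, ("v0",))
        m = fit_lda(lib, ridge=0.0)
        np.testing.assert_allclose(classify(m, [1.0])[1], [0.5, 0.5], atol=1e-12)
        assert classify(m, [0.9])[0] == "a"
        assert classify(m, [1.1])[0] == "b"

    def test_sample_at_class_mean_classified_with_high_posterior(self, source_library):
        m = fit_lda(source_library)
        for k, name in enumerate(m.class_names):
            pred, post = classify(m, m.means[k])
            assert pred == name
            assert post[k] > 0.99

    def test_equidistant_sample_splits_posterior(self):
        a = np.array([[0.0, 0.0], [0.0, 2.0], [0.0, -2.0]])
        b = a + np.array([2.0, 0.0])
        lib = SourceLibrary({"a": a, "b": b}, ("v0", "v1"))
        m = fit_lda(lib)
        _, post = classify(m, [1.0, 0.0])
        np.testing.assert_allclose(post, [0.5, 0.5], atol=1e-9)

    def test_posteriors_sum_to_one(self, source_library):
        m = fit_lda(source_library)
        x = source_library.groups["diatom"]
        _, post = classify_matrix(m, x)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-12)

    def test_dimension_mismatch_rejected(self, source_library):
        m = fit_lda(source_library)
        with pytest.raises(ValueError, match="dimension"):
            classify(m, [1.0, 2.0])

    def test_singular_covariance_without_ridge_instructs_ridge(self):
        x = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]])  # rank-1 scatter
        lib = SourceLibrary({"a": x, "b": x + 5}, ("v0", "v1"))
        with pytest.raises(ValueError, match="ridge"):
            fit_lda(lib, ridge=0.0)

    def test_uniform_vs_proportional_priors(self):
        lib, _ = random_library(1, k=2, n=10)
        big = SourceLibrary(
            {"g0": lib.groups["g0"], "g1": np.vstack([lib.groups["g1"]] * 3)},
            lib.pufa_labels,
        )
        m_u = fit_lda(big, priors="uniform")
        m_p = fit_lda(big, priors="proportional")
        np.testing.assert_allclose(m_u.priors, [0.5, 0.5])
        np.testing.assert_allclose(m_p.priors, [0.25, 0.75])

    def test_hard_labels_match_bayes_oracle_and_sklearn(self):
        """Hard classifications agree with a from-definition Gaussian Bayes
        rule and with an independent reference implementation."""
        sklearn_lda = pytest.importorskip(
            "sklearn.discriminant_analysis"
        ).LinearDiscriminantAnalysis
        rng = np.random.default_rng(2)
        for rep in range(20):
            lib, _ = random_library(100 + rep)
            m = fit_lda(lib, ridge=0.0)
            x = rng.normal(scale=4.0, size=(30, 7))
            pred_idx, _ = classify_matrix(m, x)
            pred = [m.class_names[i] for i in pred_idx]
            assert pred == bayes_rule_oracle(lib.groups, x, ridge=0.0)

            xs = np.vstack(list(lib.groups.values()))
            ys = np.concatenate(
                [[n] * len(g) for n, g in lib.groups.items()]
            )
            ref = sklearn_lda(priors=[1 / 3] * 3).fit(xs, ys)
            assert list(ref.predict(x)) == pred


class TestLoocv:
    def test_separated_clusters_classified_perfectly(self, source_library):
        rep = loocv(source_library)
        assert all(r == 1.0 for r in rep.rates.values())

    def test_confusion_rows_sum_to_group_sizes(self, source_library):
        rep = loocv(source_library)
        sizes = source_library.sizes
        for name in source_library.names:
            assert rep.confusion.loc[name].sum() == sizes[name]

    def test_indistinguishable_classes_near_chance(self):
        rng = np.random.default_rng(3)
        pool = rng.normal(size=(40, 5))
        lib = SourceLibrary({"a": pool[:20], "b": pool[20:]}, tuple(f"v{j}" for j in range(5)))
        rep = loocv(lib)
        mean_rate = np.mean(list(rep.rates.values()))
        assert 0.2 < mean_rate < 0.8

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            SourceLibrary(
                {"a": np.zeros((2, 3)), "b": np.ones((5, 3))}, ("v0", "v1", "v2")
            )


class TestPruning:
    def test_all_above_threshold_unchanged(self, source_library):
        rep = loocv(source_library)
        pruned = prune_sources(source_library, rep)
        assert pruned.names == source_library.names

    def test_low_rate_group_removed(self, source_library):
        rep = loocv(source_library)
        rates = dict(rep.rates)
        rates["copepod"] = 0.5
        forced = type(rep)(rates=rates, confusion=rep.confusion)
        pruned = prune_sources(source_library, forced)
        assert "copepod" not in pruned.names

    def test_under_two_survivors_rejected(self, source_library):
        rep = loocv(source_library)
        rates = {n: 0.1 for n in source_library.names}
        forced = type(rep)(rates=rates, confusion=rep.confusion)
        with pytest.raises(ValueError, match="fewer than 2"):
            prune_sources(source_library, forced)


class TestDropUnsharedPufa:
    def test_source_absent_acid_removed_from_model(self, source_library):
        hosts, _ = ft.simulate_host_memberships(
            ft.default_source_specs(["diatom", "copepod", "symbiont"]),
            {"diatom": 1.0}, 5, seed=0,
        )
        lib2, hosts2 = drop_unshared_pufa(source_library, hosts)
        assert "18:5n-3" not in lib2.pufa_labels
        assert "18:5n-3" not in hosts2.fa_labels
        assert lib2.pufa_labels == (
            "18:2n-6", "18:3n-3", "18:3n-6", "18:4n-3",
            "20:4n-6", "20:5n-3", "22:6n-3",
        )

    def test_no_allzero_acid_is_identity(self):
        lib, _ = random_library(4)
        lib2, _ = drop_unshared_pufa(lib, None)
        assert lib2.pufa_labels == lib.pufa_labels


@pytest.fixture(scope="module")
def attributed(source_library):
    specs = ft.default_source_specs(["diatom", "copepod", "symbiont"])
    hosts, truth = ft.simulate_host_memberships(
        specs, {"diatom": 0.7, "copepod": 0.2, "symbiont": 0.1}, 10, seed=5
    )
    lib, hosts = drop_unshared_pufa(source_library, hosts)
    dist = bootstrap_attribution(lib, hosts, n_iter=400, seed=6)
    return dist, truth


class TestBootstrapAttribution:
    def test_iterations_are_multiples_of_inverse_host_count(self, attributed):
        dist, _ = attributed
        arr = dist.samples["synthetic_host"]
        np.testing.assert_allclose(arr.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(arr * 10, np.round(arr * 10), atol=1e-9)

    def test_bit_reproducible_under_seed(self, source_library):
        specs = ft.default_source_specs(["diatom", "copepod", "symbiont"])
        hosts, _ = ft.simulate_host_memberships(
            specs, {"diatom": 0.5, "copepod": 0.5}, 6, seed=7
        )
        lib, hosts = drop_unshared_pufa(source_library, hosts)
        a = bootstrap_attribution(lib, hosts, n_iter=150, seed=8)
        b = bootstrap_attribution(lib, hosts, n_iter=150, seed=8)
        for sp in a.samples:
            np.testing.assert_array_equal(a.samples[sp], b.samples[sp])

    def test_order_invariance_of_means(self, source_library):
        specs = ft.default_source_specs(["diatom", "copepod", "symbiont"])
        hosts, _ = ft.simulate_host_memberships(
            specs, {"diatom": 0.7, "copepod": 0.3}, 10, seed=9
        )
        lib, hosts = drop_unshared_pufa(source_library, hosts)
        rev = SourceLibrary(
            {n: lib.groups[n] for n in reversed(lib.names)}, lib.pufa_labels
        )
        a = bootstrap_attribution(lib, hosts, n_iter=300, seed=10).summary()
        b = bootstrap_attribution(rev, hosts, n_iter=300, seed=10).summary()
        am = a.set_index("source")["mean"]
        bm = b.set_index("source")["mean"]
        for name in lib.names:
            assert am[name] == pytest.approx(bm[name], abs=0.05)

    def test_degenerate_attribution_concentrates_on_true_source(self, source_library):
        specs = ft.default_source_specs(["diatom", "copepod", "symbiont"])
        hosts, _ = ft.simulate_host_memberships(specs, {"diatom": 1.0}, 8, seed=11)
        lib, hosts = drop_unshared_pufa(source_library, hosts)
        dist = bootstrap_attribution(lib, hosts, n_iter=300, seed=12)
        s = dist.summary().set_index("source")
        assert s.loc["diatom", "mean"] > 0.95
        assert s.loc["diatom", "ci_lo"] > 0.5

    def test_small_n_iter_warns(self, source_library):
        specs = ft.default_source_specs(["diatom", "copepod", "symbiont"])
        hosts, _ = ft.simulate_host_memberships(specs, {"diatom": 1.0}, 4, seed=13)
        lib, hosts = drop_unshared_pufa(source_library, hosts)
        with pytest.warns(UserWarning, match="n_iter"):
            bootstrap_attribution(lib, hosts, n_iter=50, seed=14)


class TestAggregate:
    def test_single_category_interval_is_one(self, source_library):
        specs = ft.default_source_specs(["diatom", "copepod", "symbiont"])
        hosts, _ = ft.simulate_host_memberships(
            specs, {"diatom": 0.5, "copepod": 0.5}, 6, seed=15
        )
        lib, hosts = drop_unshared_pufa(source_library, hosts)
        dist = bootstrap_attribution(lib, hosts, n_iter=150, seed=16)
        agg = aggregate_contributions(dist, {n: "all" for n in lib.names})
        assert agg["ci_lo"].iloc[0] == pytest.approx(1.0)
        assert agg["ci_hi"].iloc[0] == pytest.approx(1.0)

    def test_categories_close_within_iteration(self, source_library):
        specs = ft.default_source_specs(["diatom", "copepod", "symbiont"])
        hosts, _ = ft.simulate_host_memberships(
            specs, {"diatom": 0.6, "symbiont": 0.4}, 5, seed=17
        )
        lib, hosts = drop_unshared_pufa(source_library, hosts)
        dist = bootstrap_attribution(lib, hosts, n_iter=150, seed=18)
        mapping = {"diatom": "particulate", "copepod": "particulate",
                   "symbiont": "symbiont"}
        agg = aggregate_contributions(dist, mapping).set_index("category")
        assert agg.loc["particulate", "mean"] + agg.loc["symbiont", "mean"] == \
            pytest.approx(1.0, abs=1e-12)

    def test_unmapped_source_rejected(self, source_library):
        specs = ft.default_source_specs(["diatom", "copepod", "symbiont"])
        hosts, _ = ft.simulate_host_memberships(specs, {"diatom": 1.0}, 4, seed=19)
        lib, hosts = drop_unshared_pufa(source_library, hosts)
        dist = bootstrap_attribution(lib, hosts, n_iter=120, seed=20)
        with pytest.raises(ValueError, match="unmapped"):
            aggregate_contributions(dist, {"diatom": "particulate"})
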