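"""Distance matrices, crossed-factor permutation tests, dispersion, PCA.

Independent oracles: the classical sums-of-squared-distances formulation
of the one-way pseudo-F, classical per-coordinate ANOVA pooling under
Euclidean distance, direct distances-to-mean for dispersion, and the
scikit-bio permanova statistic as a cross-implementation check.
"""

import itertools

import numpy as np
import pytest

import fatrophic as ft
from fatrophic import multivariate as mv
from fatrophic.profiles import validate_profile


def _profile_set(matrix, labels=("16:0", "18:0", "22:6n-3")):
    rows = np.asarray(matrix, dtype=float)
    profiles = [
        validate_profile(
            dict(zip(labels, r)), sample_id=f"s{i}", renormalize=True
        )
        for i, r in enumerate(rows)
    ]
    return ft.ProfileSet(profiles, fa_labels=labels)


def random_compositions(n, p, seed):
    rng = np.random.default_rng(seed)
    x = rng.dirichlet(np.ones(p), size=n) * 100
    return x


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


def test_identical_profiles_have_zero_distance():
    ps = _profile_set([[50, 30, 20], [50, 30, 20]])
    d = mv.distance_matrix(ps, "bray_curtis")
    assert d.values[0, 1] == pytest.approx(0.0, abs=1e-12)


def test_disjoint_compositions_are_maximally_dissimilar():
    ps = _profile_set([[100, 0, 0], [0, 100, 0]])
    d = mv.distance_matrix(ps, "bray_curtis")
    assert d.values[0, 1] == pytest.approx(1.0)


def test_bray_curtis_matches_hand_formula():
    x = random_compositions(2, 5, seed=0)
    labels = ("16:0", "18:0", "20:5n-3", "22:6n-3", "18:1n-9")
    ps = _profile_set(x, labels)
    m = ps.matrix()
    expected = np.abs(m[0] - m[1]).sum() / (m[0] + m[1]).sum()
    d = mv.distance_matrix(ps, "bray_curtis")
    assert d.values[0, 1] == pytest.approx(expected, abs=1e-12)


def test_all_zero_profile_rejected_under_bray_curtis():
    a = validate_profile({"16:0": 100}, sample_id="a")
    b = ft.FAProfile("b", {"16:0": 0.0})
    ps = ft.ProfileSet([a, b])
    with pytest.raises(ValueError, match="all-zero"):
        mv.distance_matrix(ps, "bray_curtis")


# ---------------------------------------------------------------------------
# permanova
# ---------------------------------------------------------------------------


def _oneway_pseudo_f_from_distances(d, labels):
    """Sums-of-squared-distances one-way pseudo-F (independent formula)."""
    labels = np.asarray(labels, dtype=object)
    n = len(labels)
    iu = np.triu_indices(n, 1)
    ss_total = (d[iu] ** 2).sum() / n
    ss_within = 0.0
    groups = sorted(set(labels), key=str)
    for g in groups:
        idx = np.where(labels == g)[0]
        sub = d[np.ix_(idx, idx)]
        ss_within += (sub[np.triu_indices(len(idx), 1)] ** 2).sum() / len(idx)
    ss_between = ss_total - ss_within
    a = len(groups)
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def test_identical_samples_give_zero_pseudo_f():
    ps = _profile_set([[50, 30, 20]] * 6)
    d = mv.distance_matrix(ps)
    res = mv.permanova(d, {"g": ["a"] * 3 + ["b"] * 3}, ["g"], n_perm=99)
    assert res.terms[0].pseudo_f == pytest.approx(0.0, abs=1e-9)
    assert res.terms[0].ss == pytest.approx(0.0, abs=1e-9)


def test_oneway_pseudo_f_matches_distance_formula():
    x = random_compositions(12, 4, seed=1)
    ps = _profile_set(x, ("16:0", "18:0", "20:5n-3", "22:6n-3"))
    labels = ["a"] * 6 + ["b"] * 6
    d = mv.distance_matrix(ps)
    res = mv.permanova(d, {"g": labels}, ["g"], n_perm=99, seed=0)
    expected = _oneway_pseudo_f_from_distances(d.values, labels)
    assert res.terms[0].pseudo_f == pytest.approx(expected, rel=1e-10)


def test_exhaustive_p_matches_bruteforce_enumeration():
    """With two small groups the permutation p equals the exact p from
    enumerating every group relabeling."""
    x = random_compositions(7, 4, seed=2)
    ps = _profile_set(x, ("16:0", "18:0", "20:5n-3", "22:6n-3"))
    labels = np.asarray(["a"] * 3 + ["b"] * 4, dtype=object)
    d = mv.distance_matrix(ps)
    res = mv.permanova(d, {"g": labels}, ["g"], n_perm=9999, seed=0)
    assert res.exhaustive

    f_obs = _oneway_pseudo_f_from_distances(d.values, labels)
    count = total = 0
    for pos_a in itertools.combinations(range(7), 3):
        relabel = np.asarray(
            ["a" if i in pos_a else "b" for i in range(7)], dtype=object
        )
        f = _oneway_pseudo_f_from_distances(d.values, relabel)
        total += 1
        if f >= f_obs - 1e-9:
            count += 1
    assert res.n_perm == total == 35
    assert res.terms[0].p_perm == pytest.approx(count / total, abs=1e-12)


def test_euclidean_pseudo_f_equals_pooled_classical_anova_f():
    """With Euclidean distance the one-way pseudo-F equals the classical
    per-coordinate ANOVA F with numerator and denominator SS pooled over
    coordinates."""
    rng = np.random.default_rng(3)
    x = rng.normal(size=(14, 5)) + 10
    x = 100 * x / x.sum(axis=1, keepdims=True)
    labels = ["a"] * 7 + ["b"] * 7
    ps = _profile_set(x, ("16:0", "18:0", "20:5n-3", "22:6n-3", "18:1n-9"))
    d = mv.distance_matrix(ps, "euclidean")
    res = mv.permanova(d, {"g": labels}, ["g"], n_perm=99, seed=0)

    m = ps.matrix()
    g = np.asarray(labels, dtype=object)
    ssb = ssw = 0.0
    for j in range(m.shape[1]):
        col = m[:, j]
        grand = col.mean()
        for lev in ("a", "b"):
            v = col[g == lev]
            ssb += len(v) * (v.mean() - grand) ** 2
            ssw += ((v - v.mean()) ** 2).sum()
    f_classical = (ssb / 1) / (ssw / 12)
    assert res.terms[0].pseudo_f == pytest.approx(f_classical, rel=1e-10)


def test_permanova_matches_skbio_statistic():
    skbio_stats = pytest.importorskip("skbio.stats.distance")
    x = random_compositions(15, 4, seed=4)
    ps = _profile_set(x, ("16:0", "18:0", "20:5n-3", "22:6n-3"))
    labels = ["a"] * 5 + ["b"] * 5 + ["c"] * 5
    d = mv.distance_matrix(ps)
    res = mv.permanova(d, {"g": labels}, ["g"], n_perm=99, seed=0)
    dm = skbio_stats.DistanceMatrix(d.values, ids=list(ps.sample_ids))
    ref = skbio_stats.permanova(dm, grouping=labels, permutations=0)
    assert res.terms[0].pseudo_f == pytest.approx(ref["test statistic"], rel=1e-8)


def test_crossed_design_df_partition(factorial_set):
    d = mv.distance_matrix(factorial_set)
    fac = {
        "species": factorial_set.factor("species"),
        "tissue": factorial_set.factor("tissue"),
    }
    res = mv.permanova(
        d, fac, ["species", "tissue", "species:tissue"], n_perm=99, seed=0
    )
    assert [t.df for t in res.terms] == [2, 1, 2]
    assert sum(t.df for t in res.terms) + res.residual_df == len(factorial_set) - 1


def test_permanova_invariant_to_sample_order():
    x = random_compositions(12, 4, seed=5)
    labels = np.asarray(["a"] * 6 + ["b"] * 6, dtype=object)
    ps = _profile_set(x, ("16:0", "18:0", "20:5n-3", "22:6n-3"))
    d = mv.distance_matrix(ps)
    res1 = mv.permanova(d, {"g": labels}, ["g"], n_perm=99, seed=0)
    perm = np.random.default_rng(0).permutation(12)
    ps2 = ft.ProfileSet([ps.profiles[i] for i in perm], fa_labels=ps.fa_labels)
    d2 = mv.distance_matrix(ps2)
    res2 = mv.permanova(d2, {"g": labels[perm]}, ["g"], n_perm=99, seed=0)
    assert res1.terms[0].pseudo_f == pytest.approx(res2.terms[0].pseudo_f, rel=1e-10)


def test_unknown_factor_in_term_rejected(factorial_set):
    d = mv.distance_matrix(factorial_set)
    with pytest.raises(KeyError, match="unknown factor"):
        mv.permanova(d, {"species": factorial_set.factor("species")},
                     ["species", "colour"], n_perm=99)


def test_pairwise_equals_fresh_two_level_test():
    x = random_compositions(15, 4, seed=6)
    labels = np.asarray(["a"] * 5 + ["b"] * 5 + ["c"] * 5, dtype=object)
    ps = _profile_set(x, ("16:0", "18:0", "20:5n-3", "22:6n-3"))
    d = mv.distance_matrix(ps)
    pw = mv.pairwise_permanova(d, labels, n_perm=199, seed=3)
    assert [c.pair for c in pw] == [("a", "b"), ("a", "c"), ("b", "c")]
    idx = np.where(labels != "c")[0]
    fresh = mv.permanova(
        d.submatrix(idx), {"g": labels[idx]}, ["g"], n_perm=199, seed=3
    )
    assert pw[0].pseudo_f == pytest.approx(fresh.terms[0].pseudo_f, rel=1e-10)
    assert pw[0].p_perm == pytest.approx(fresh.terms[0].p_perm)


def test_pairwise_shifted_group_detected(three_sources):
    """Only pairs involving a strongly shifted group reach significance."""
    ps = ft.simulate_sources(three_sources, 8, seed=7)
    # diatom/copepod differ strongly from symbiont and from one another
    d = mv.distance_matrix(ps)
    pw = mv.pairwise_permanova(d, ps.factor("source_group"), n_perm=199, seed=1)
    assert all(c.p_perm <= 0.05 for c in pw)


# ---------------------------------------------------------------------------
# permdisp
# ---------------------------------------------------------------------------


def test_permdisp_equal_geometry_not_significant():
    base = random_compositions(8, 4, seed=8)
    x = np.vstack([base, base])  # two groups with identical internal geometry
    ps = _profile_set(x, ("16:0", "18:0", "20:5n-3", "22:6n-3"))
    d = mv.distance_matrix(ps, "euclidean")
    res = mv.permdisp(d, ["a"] * 8 + ["b"] * 8, n_perm=199, seed=0)
    assert res.f_stat == pytest.approx(0.0, abs=1e-9)
    assert res.p_perm > 0.5


def test_permdisp_detects_inflated_dispersion():
    rng = np.random.default_rng(9)
    tight = rng.normal(scale=1.0, size=(10, 4))
    wide = rng.normal(scale=3.0, size=(10, 4))
    x = np.vstack([tight, wide]) + 20
    x = 100 * x / x.sum(axis=1, keepdims=True)
    ps = _profile_set(x, ("16:0", "18:0", "20:5n-3", "22:6n-3"))
    d = mv.distance_matrix(ps, "euclidean")
    res = mv.permdisp(d, ["a"] * 10 + ["b"] * 10, n_perm=499, seed=0)
    assert res.p_perm <= 0.05
    assert res.group_dispersions["b"] > res.group_dispersions["a"]


def test_permdisp_euclidean_matches_direct_distances_to_mean():
    x = random_compositions(12, 4, seed=10)
    ps = _profile_set(x, ("16:0", "18:0", "20:5n-3", "22:6n-3"))
    labels = np.asarray(["a"] * 6 + ["b"] * 6, dtype=object)
    d = mv.distance_matrix(ps, "euclidean")
    res = mv.permdisp(d, labels, n_perm=199, seed=0)
    m = ps.matrix()
    expected = np.empty(12)
    for lev in ("a", "b"):
        idx = labels == lev
        centroid = m[idx].mean(axis=0)
        expected[idx] = np.linalg.norm(m[idx] - centroid, axis=1)
    np.testing.assert_allclose(res.distances_to_centroid, expected, atol=1e-8)


# ---------------------------------------------------------------------------
# pca
# ---------------------------------------------------------------------------


def test_collinear_points_put_all_variance_on_dim1():
    t = np.linspace(0, 1, 8)
    x = np.column_stack([t, 2 * t, -t])
    r = mv.pca(x, standardize=False)
    assert r.explained_pct[0] == pytest.approx(100.0)


def test_variance_percentages_and_contributions_close_to_100(factorial_set):
    sub = factorial_set.subset_labels(
        [l for l in factorial_set.fa_labels
         if factorial_set.matrix([l]).std() > 0]
    )
    r = mv.pca(sub, standardize=True)
    assert r.explained_pct.sum() == pytest.approx(100.0)
    np.testing.assert_allclose(r.contributions.sum(axis=0), 100.0)


def test_scores_covariance_is_diagonal_eigenvalues():
    rng = np.random.default_rng(11)
    x = rng.normal(size=(30, 5))
    r = mv.pca(x, standardize=False)
    cov = np.cov(r.scores.T)
    np.testing.assert_allclose(cov, np.diag(r.eigenvalues), atol=1e-10)


def test_reconstruction_from_scores_and_loadings():
    rng = np.random.default_rng(12)
    x = rng.normal(size=(20, 6))
    r = mv.pca(x, standardize=False)
    recon = r.scores @ r.loadings.T + r.center
    np.testing.assert_allclose(recon, x, atol=1e-8)


def test_sign_convention_largest_loading_positive():
    rng = np.random.default_rng(13)
    x = rng.normal(size=(25, 4))
    r = mv.pca(x, standardize=True)
    for k in range(r.loadings.shape[1]):
        j = np.argmax(np.abs(r.loadings[:, k]))
        assert r.loadings[j, k] > 0


def test_constant_variable_named_in_error():
    x = np.column_stack([np.ones(5), np.arange(5.0)])
    with pytest.raises(ValueError, match="v0"):
        mv.pca(x, standardize=True)
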