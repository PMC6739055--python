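"""Distance-based permutation statistics and ordination.

Implements the multivariate toolkit used on percent fatty-acid
compositions:

* :func:`distance_matrix` — Bray-Curtis (the conventional resemblance for
  percent-composition data) or Euclidean dissimilarities;
* :func:`permanova` — distance-based multivariate ANOVA for crossed fixed
  factors, with the sum of squares partitioned through the Gower-centered
  inner-product matrix and sequential projection (hat) matrices, and
  per-term pseudo-F significance assessed by unrestricted permutation of
  raw observations;
* :func:`pairwise_permanova` — two-level follow-up tests on sub-matrices;
* :func:`permdisp` — homogeneity of multivariate dispersion via distances
  to group centroids in principal-coordinate space (negative eigenvalues
  handled by the imaginary-part correction);
* :func:`pca` — principal component analysis with percent variance per
  axis and per-variable contributions.

The permutation p-value uses the add-one estimator
``p = (1 + #{F* >= F}) / (1 + n_perm)`` so it is never zero; when a single
one-way factor admits fewer distinct relabelings than requested the test
switches to exhaustive enumeration and reports the exact p.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .profiles import ProfileSet

__all__ = [
    "DistanceMatrix",
    "PermanovaResult",
    "PermdispResult",
    "PCAResult",
    "distance_matrix",
    "permanova",
    "pairwise_permanova",
    "permdisp",
    "pca",
]

log = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with zero diagonal."""

    values: np.ndarray
    metric: str
    sample_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if np.abs(np.diag(v)).max(initial=0.0) > 1e-10:
            raise ValueError("distance matrix must have a zero diagonal")
        if v.min(initial=0.0) < -1e-10:
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.shape[0]

    def submatrix(self, idx: Sequence[int]) -> "DistanceMatrix":
        idx = np.asarray(idx)
        ids = tuple(np.asarray(self.sample_ids)[idx]) if self.sample_ids else ()
        return DistanceMatrix(self.values[np.ix_(idx, idx)], self.metric, ids)


def distance_matrix(ps: ProfileSet, metric: str = "bray_curtis") -> DistanceMatrix:
    """Pairwise dissimilarities between sample compositions.

    Bray-Curtis on percent data is ``sum|x_i - y_i| / sum(x_i + y_i)``;
    it is undefined for an all-zero profile, which raises.
    """
    if len(ps) < 2:
        raise ValueError("need at least 2 samples")
    x = ps.matrix()
    if metric == "bray_curtis":
        if (x.sum(axis=1) <= 0).any():
            bad = [ps.sample_ids[i] for i in np.where(x.sum(axis=1) <= 0)[0]]
            raise ValueError(f"all-zero profiles under Bray-Curtis: {bad}")
        d = squareform(pdist(x, metric="braycurtis"))
    elif metric == "euclidean":
        d = squareform(pdist(x, metric="euclidean"))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(d, metric, tuple(ps.sample_ids))


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PermanovaTerm:
    name: str
    df: int
    ss: float
    ms: float
    pseudo_f: float
    p_perm: float


@dataclass(frozen=True)
class PermanovaResult:
    terms: tuple[PermanovaTerm, ...]
    residual_df: int
    residual_ss: float
    total_ss: float
    n_perm: int
    seed: int | None
    exhaustive: bool = False

    def term(self, name: str) -> PermanovaTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _dummy_columns(labels: np.ndarray) -> np.ndarray:
    levels = pd_unique_stable(labels)
    return (labels[:, None] == np.asarray(levels, dtype=object)[None, :]).astype(float)


def pd_unique_stable(labels: np.ndarray) -> list:
    seen: dict = {}
    for l in labels:
        seen.setdefault(l, None)
    return list(seen)


def _term_columns(factors: Mapping[str, np.ndarray], term: str, n: int) -> np.ndarray:
    cols: np.ndarray | None = None
    for f in term.split(":"):
        if f not in factors:
            raise KeyError(f"term {term!r} references unknown factor {f!r}")
        d = _dummy_columns(np.asarray(factors[f], dtype=object))
        if cols is None:
            cols = d
        else:
            cols = (cols[:, :, None] * d[:, None, :]).reshape(n, -1)
    assert cols is not None
    return cols


def _orthonormal_basis(x: np.ndarray) -> np.ndarray:
    """Columns spanning col(x), via SVD with a rank tolerance."""
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    tol = max(x.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    return u[:, s > tol]


def _projectors(
    factors: Mapping[str, np.ndarray], terms: Sequence[str], n: int
) -> tuple[list[np.ndarray], list[int], np.ndarray]:
    """Sequential-term projection matrices, term dfs, and the full-model hat.

    Term k's projector is H_k - H_{k-1} where H_k projects onto the column
    space of intercept + terms 1..k. For a balanced crossed design the
    decomposition is orthogonal and order-free; for unbalanced data it is
    sequential in the order given.
    """
    x = np.ones((n, 1))
    basis_prev = _orthonormal_basis(x)
    projectors: list[np.ndarray] = []
    dfs: list[int] = []
    for term in terms:
        x = np.hstack([x, _term_columns(factors, term, n)])
        basis = _orthonormal_basis(x)
        df = basis.shape[1] - basis_prev.shape[1]
        if df == 0:
            raise ValueError(f"term {term!r} adds no degrees of freedom")
        h_prev = basis_prev @ basis_prev.T
        h = basis @ basis.T
        projectors.append(h - h_prev)
        dfs.append(df)
        basis_prev = basis
    h_full = basis_prev @ basis_prev.T
    return projectors, dfs, h_full


def _term_stats(
    g: np.ndarray,
    projectors: Sequence[np.ndarray],
    dfs: Sequence[int],
    resid_proj: np.ndarray,
    resid_df: int,
) -> tuple[np.ndarray, float]:
    ss_res = float(np.sum(resid_proj * g))
    ms_res = ss_res / resid_df
    fs = np.empty(len(projectors))
    for k, (p, df) in enumerate(zip(projectors, dfs)):
        ss = float(np.sum(p * g))
        fs[k] = 0.0 if ms_res <= _EPS and ss <= _EPS else (ss / df) / max(ms_res, _EPS)
    return fs, ss_res


def _multiset_permutations(labels: tuple) -> "itertools.chain":
    """Distinct orderings of a label multiset."""
    seen_cache: set = set()

    def rec(remaining: tuple, prefix: tuple):
        if not remaining:
            yield prefix
            return
        used = set()
        for i, l in enumerate(remaining):
            if l in used:
                continue
            used.add(l)
            yield from rec(remaining[:i] + remaining[i + 1 :], prefix + (l,))

    return rec(tuple(labels), ())


def _n_distinct_arrangements(labels: Sequence) -> int:
    counts: dict = {}
    for l in labels:
        counts[l] = counts.get(l, 0) + 1
    total = math.factorial(len(labels))
    for c in counts.values():
        total //= math.factorial(c)
    return total


def permanova(
    d: DistanceMatrix,
    factors: Mapping[str, Sequence],
    terms: Sequence[str],
    n_perm: int = 9999,
    seed: int | None = None,
) -> PermanovaResult:
    """Distance-based multivariate ANOVA for crossed fixed factors.

    Parameters
    ----------
    d : DistanceMatrix
    factors : mapping of factor name to per-sample labels.
    terms : model terms in order, e.g. ``["species", "tissue",
        "species:tissue"]``; interactions use ``a:b`` syntax.
    n_perm : number of unrestricted permutations of raw observations
        (9999 is the conventional choice for these data sizes).
    seed : permutation RNG seed; the observed statistics themselves are
        deterministic.

    A single one-way term with fewer distinct group relabelings than
    ``n_perm`` is evaluated exhaustively (exact p, identity included).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    n = len(d)
    for name, labels in factors.items():
        if len(labels) != n:
            raise ValueError(f"factor {name!r} has {len(labels)} labels for {n} samples")
    fac = {k: np.asarray(v, dtype=object) for k, v in factors.items()}
    projectors, dfs, h_full = _projectors(fac, terms, n)
    resid_proj = np.eye(n) - h_full
    resid_df = n - int(round(np.trace(h_full)))
    if resid_df <= 0:
        raise ValueError("model saturates the data: no residual degrees of freedom")
    g = _gower_center(d.values)
    f_obs, ss_res = _term_stats(g, projectors, dfs, resid_proj, resid_df)
    ss_terms = [float(np.sum(p * g)) for p in projectors]
    total_ss = float(np.trace(g))

    exhaustive = False
    single_oneway = len(terms) == 1 and ":" not in terms[0]
    if single_oneway:
        labels = tuple(fac[terms[0]])
        n_distinct = _n_distinct_arrangements(labels)
        exhaustive = n_distinct <= n_perm
    tol = 1e-9 * max(1.0, float(np.max(np.abs(f_obs))))
    if exhaustive:
        log.info(
            "permanova: %d distinct relabelings <= n_perm=%d; exhaustive enumeration",
            n_distinct,
            n_perm,
        )
        count = 0
        total = 0
        for arrangement in _multiset_permutations(labels):
            projs, adfs, ah = _projectors({terms[0]: np.asarray(arrangement, dtype=object)}, terms, n)
            fs, _ = _term_stats(g, projs, adfs, np.eye(n) - ah, n - int(round(np.trace(ah))))
            total += 1
            if fs[0] >= f_obs[0] - tol:
                count += 1
        p_vals = np.asarray([count / total])
        n_perm_used = total
    else:
        rng = np.random.default_rng(seed)
        counts = np.zeros(len(terms), dtype=int)
        for _ in range(n_perm):
            idx = rng.permutation(n)
            g_perm = g[np.ix_(idx, idx)]
            fs, _ = _term_stats(g_perm, projectors, dfs, resid_proj, resid_df)
            counts += fs >= f_obs - tol
        p_vals = (1 + counts) / (1 + n_perm)
        n_perm_used = n_perm

    result_terms = tuple(
        PermanovaTerm(
            name=t,
            df=dfs[k],
            ss=ss_terms[k],
            ms=ss_terms[k] / dfs[k],
            pseudo_f=float(f_obs[k]),
            p_perm=float(p_vals[k]),
        )
        for k, t in enumerate(terms)
    )
    return PermanovaResult(
        terms=result_terms,
        residual_df=resid_df,
        residual_ss=ss_res,
        total_ss=total_ss,
        n_perm=n_perm_used,
        seed=seed,
        exhaustive=exhaustive,
    )


@dataclass(frozen=True)
class PairwiseComparison:
    pair: tuple[str, str]
    pseudo_f: float
    p_perm: float
    n: int


def pairwise_permanova(
    d: DistanceMatrix,
    factor: Sequence,
    n_perm: int = 9999,
    seed: int | None = None,
) -> list[PairwiseComparison]:
    """Two-level follow-up tests for each pair of factor levels.

    Each pair is tested on the distance sub-matrix restricted to its own
    samples, which is identical to running a fresh one-way test on that
    subset. Levels with fewer than 2 samples are skipped with a warning.
    """
    labels = np.asarray(factor, dtype=object)
    if len(labels) != len(d):
        raise ValueError("factor length does not match distance matrix")
    levels = pd_unique_stable(labels)
    if len(levels) < 2:
        raise ValueError("factor needs at least 2 levels")
    ss = seed if seed is not None else 0
    out: list[PairwiseComparison] = []
    for i, (a, b) in enumerate(itertools.combinations(levels, 2)):
        idx = np.where((labels == a) | (labels == b))[0]
        if (labels == a).sum() < 2 or (labels == b).sum() < 2:
            log.warning("pairwise_permanova: level pair (%s, %s) skipped (<2 samples)", a, b)
            continue
        sub = d.submatrix(idx)
        res = permanova(
            sub,
            {"group": labels[idx]},
            ["group"],
            n_perm=n_perm,
            seed=None if seed is None else ss + i,
        )
        t = res.terms[0]
        out.append(PairwiseComparison((str(a), str(b)), t.pseudo_f, t.p_perm, len(idx)))
    return out


# ---------------------------------------------------------------------------
# PERMDISP
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PermdispResult:
    group_dispersions: Mapping[str, float]
    distances_to_centroid: np.ndarray
    f_stat: float
    p_perm: float
    n_perm: int
    seed: int | None


def _oneway_f(values: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = values.size
    grand = values.mean()
    ss_total = float(((values - grand) ** 2).sum())
    ss_within = 0.0
    for g in range(n_groups):
        v = values[codes == g]
        ss_within += float(((v - v.mean()) ** 2).sum())
    ss_between = ss_total - ss_within
    df_b, df_w = n_groups - 1, n - n_groups
    if ss_within <= _EPS and ss_between <= _EPS:
        return 0.0
    return (ss_between / df_b) / max(ss_within / df_w, _EPS)


def _pcoa_coords(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal-coordinate embedding split into real and imaginary parts.

    Negative eigenvalues of the Gower-centered matrix (possible for
    semi-metric dissimilarities like Bray-Curtis) yield 'imaginary' axes
    whose squared contributions are subtracted when computing distances.
    """
    g = _gower_center(d)
    vals, vecs = np.linalg.eigh(g)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    scale = np.abs(vals).max(initial=0.0)
    keep = np.abs(vals) > 1e-8 * max(scale, 1.0)
    vals, vecs = vals[keep], vecs[:, keep]
    if vals.size == 0:
        raise ValueError("degenerate embedding: all eigenvalues are zero")
    real = vecs[:, vals > 0] * np.sqrt(vals[vals > 0])
    imag = vecs[:, vals < 0] * np.sqrt(-vals[vals < 0])
    return real, imag


def permdisp(
    d: DistanceMatrix,
    grouping: Sequence,
    n_perm: int = 9999,
    seed: int | None = None,
) -> PermdispResult:
    """Test homogeneity of multivariate dispersion among groups.

    Each sample's distance to its group centroid is computed in
    principal-coordinate space (real-part squared distances minus
    imaginary-part squared distances, clamped at zero); the F statistic of
    a one-way ANOVA on those distances is assessed by permuting the
    distance values across group labels.
    """
    labels = np.asarray(grouping, dtype=object)
    if len(labels) != len(d):
        raise ValueError("grouping length does not match distance matrix")
    levels = pd_unique_stable(labels)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    codes = np.asarray([levels.index(l) for l in labels])
    counts = np.bincount(codes, minlength=len(levels))
    if (counts < 2).any():
        raise ValueError("every group needs at least 2 samples")
    real, imag = _pcoa_coords(d.values)
    dist2 = np.zeros(len(d))
    for g in range(len(levels)):
        member = codes == g
        c_real = real[member].mean(axis=0)
        d2 = ((real[member] - c_real) ** 2).sum(axis=1)
        if imag.shape[1]:
            c_imag = imag[member].mean(axis=0)
            d2 = d2 - ((imag[member] - c_imag) ** 2).sum(axis=1)
        dist2[member] = np.clip(d2, 0.0, None)
    dists = np.sqrt(dist2)
    f_obs = _oneway_f(dists, codes, len(levels))
    rng = np.random.default_rng(seed)
    count = 0
    tol = 1e-9 * max(1.0, f_obs)
    for _ in range(n_perm):
        perm = rng.permutation(len(dists))
        if _oneway_f(dists[perm], codes, len(levels)) >= f_obs - tol:
            count += 1
    p = (1 + count) / (1 + n_perm)
    dispersions = {
        str(levels[g]): float(dists[codes == g].mean()) for g in range(len(levels))
    }
    return PermdispResult(dispersions, dists, float(f_obs), float(p), n_perm, seed)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PCAResult:
    """Eigendecomposition of the (co)variance or correlation structure.

    ``loadings`` are unit-norm eigenvectors (variables × axes);
    ``contributions`` give each variable's percent share of an axis
    (100 × loading² / Σ loading², summing to 100 per axis). Axis signs are
    fixed so the largest-magnitude loading on each axis is positive.
    """

    eigenvalues: np.ndarray
    explained_pct: np.ndarray
    scores: np.ndarray
    loadings: np.ndarray
    contributions: np.ndarray
    variables: tuple[str, ...]
    standardized: bool
    center: np.ndarray
    scale: np.ndarray


def pca(
    data: ProfileSet | np.ndarray,
    standardize: bool = True,
    variables: Sequence[str] | None = None,
) -> PCAResult:
    """Principal component analysis of centered (optionally standardized) data.

    With ``standardize`` the correlation matrix is decomposed (each
    variable scaled to unit variance), the convention under which variable
    contributions are usually read; without it the covariance matrix is
    used. A constant variable under standardization raises, naming the
    variable.
    """
    if isinstance(data, ProfileSet):
        x = data.matrix()
        names = tuple(data.fa_labels)
    else:
        x = np.asarray(data, dtype=float)
        names = tuple(variables) if variables is not None else tuple(
            f"v{j}" for j in range(x.shape[1])
        )
    n, p = x.shape
    if n < 3:
        raise ValueError("need at least 3 samples")
    if p < 2:
        raise ValueError("need at least 2 variables")
    center = x.mean(axis=0)
    xc = x - center
    if standardize:
        sd = xc.std(axis=0, ddof=1)
        constant = np.where(sd <= 0)[0]
        if constant.size:
            raise ValueError(
                f"constant variables under standardize: {[names[j] for j in constant]}"
            )
        scale = sd
    else:
        scale = np.ones(p)
    xs = xc / scale
    u, s, vt = np.linalg.svd(xs, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    loadings = vt.T
    # sign convention: largest-magnitude loading on each axis is positive
    for k in range(loadings.shape[1]):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
            u[:, k] *= -1
    scores = u * s
    total = eigenvalues.sum()
    explained = 100.0 * eigenvalues / total if total > 0 else np.zeros_like(eigenvalues)
    contrib = 100.0 * loadings**2 / (loadings**2).sum(axis=0)
    return PCAResult(
        eigenvalues=eigenvalues,
        explained_pct=explained,
        scores=scores,
        loadings=loadings,
        contributions=contrib,
        variables=names,
        standardized=standardize,
        center=center,
        scale=scale,
    )
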