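"""Bootstrap-LDA attribution of host PUFA to candidate diet sources.

The core inference of the package. Candidate sources of polyunsaturated
fatty acids (plankton groups and host-associated symbionts) form a labelled
training library of PUFA compositions. A linear discriminant analysis —
a Gaussian classifier with per-class means and a pooled within-class
covariance — is trained on the sources; its reliability is screened with
leave-one-out cross-validation, sources classified below a threshold rate
(default 85%) are pruned, and PUFA absent from every retained source are
removed from the variable set. Coral host samples are then classified, and
the sampling variability of the source library is propagated by a
bootstrap: in each of ``n_iter`` iterations every source group is resampled
with replacement to its own size, the classifier is refit, and the fraction
of a host species' samples assigned to each source is recorded as that
iteration's "diet combination". The resulting distribution yields the mean,
SD and percentile 95% interval of each source's contribution, and the
contributions aggregate into particulate-derived versus symbiont-derived
categories.

Host samples are never resampled and their labels never enter fitting:
sources are the training set, hosts are prediction targets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .profiles import ProfileSet

__all__ = [
    "SourceLibrary",
    "LDAModel",
    "LOOCVReport",
    "ContributionDistribution",
    "fit_lda",
    "classify",
    "loocv",
    "prune_sources",
    "drop_unshared_pufa",
    "bootstrap_attribution",
    "aggregate_contributions",
]

log = logging.getLogger(__name__)

#: Default ridge scale: λ = RIDGE_SCALE × trace(Σ)/dim added to the pooled
#: covariance diagonal, guaranteeing invertibility on closed (collinear)
#: percent data while perturbing the discriminant rule negligibly.
RIDGE_SCALE = 1e-6


@dataclass(frozen=True)
class SourceLibrary:
    """Labelled groups of PUFA compositions serving as candidate sources.

    ``groups`` maps a source name to an (n_i × p) array of percent
    compositions over ``pufa_labels``.
    """

    groups: Mapping[str, np.ndarray]
    pufa_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ValueError("need at least 2 source groups")
        p = len(self.pufa_labels)
        clean = {}
        for name, x in self.groups.items():
            arr = np.asarray(x, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != p:
                raise ValueError(
                    f"group {name!r}: expected shape (n, {p}), got {arr.shape}"
                )
            if arr.shape[0] < 3:
                raise ValueError(f"group {name!r}: need at least 3 samples")
            clean[name] = arr
        object.__setattr__(self, "groups", clean)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.groups)

    @property
    def sizes(self) -> dict[str, int]:
        return {k: v.shape[0] for k, v in self.groups.items()}

    @classmethod
    def from_profiles(
        cls, ps: ProfileSet, pufa_labels: Sequence[str]
    ) -> "SourceLibrary":
        """Build a library from profiles grouped by ``source_group``."""
        labels = tuple(pufa_labels)
        groups: dict[str, list[np.ndarray]] = {}
        for p in ps:
            if p.source_group is None:
                raise ValueError(f"sample {p.sample_id!r} has no source_group")
            row = np.asarray([p.get(l) for l in labels])
            groups.setdefault(p.source_group, []).append(row)
        return cls({k: np.vstack(v) for k, v in groups.items()}, labels)


@dataclass(frozen=True)
class LDAModel:
    """Gaussian class-conditional classifier with shared covariance."""

    class_names: tuple[str, ...]
    means: np.ndarray  # (K, p)
    cov: np.ndarray  # (p, p), pooled within-class, ridge included
    cov_inv: np.ndarray
    priors: np.ndarray  # (K,)
    ridge: float
    labels: tuple[str, ...]


def _pooled_cov(xs: Sequence[np.ndarray]) -> np.ndarray:
    p = xs[0].shape[1]
    scatter = np.zeros((p, p))
    n_total = 0
    for x in xs:
        c = x - x.mean(axis=0)
        scatter += c.T @ c
        n_total += x.shape[0]
    return scatter / (n_total - len(xs))


def fit_lda(
    lib: SourceLibrary,
    priors: str | Mapping[str, float] = "uniform",
    ridge: float | None = None,
) -> LDAModel:
    """Fit the pooled-covariance Gaussian discriminant to a source library.

    ``priors`` is ``"uniform"`` (default: group sizes reflect literature
    availability, not prey availability), ``"proportional"`` (group sizes),
    or an explicit name → weight mapping. ``ridge`` is the absolute
    diagonal regularizer λ; ``None`` selects λ = 1e-6 × trace/dim. With
    ``ridge = 0`` a singular pooled covariance raises with instructions to
    use a positive ridge.
    """
    names = lib.names
    xs = [lib.groups[n] for n in names]
    for n, x in zip(names, xs):
        if x.shape[0] < 2:
            raise ValueError(f"group {n!r}: need at least 2 samples to fit")
    means = np.vstack([x.mean(axis=0) for x in xs])
    cov = _pooled_cov(xs)
    p = cov.shape[0]
    lam = RIDGE_SCALE * np.trace(cov) / p if ridge is None else float(ridge)
    if lam < 0:
        raise ValueError("ridge must be >= 0")
    cov_r = cov + lam * np.eye(p)
    try:
        cov_inv = np.linalg.inv(cov_r)
        if np.linalg.cond(cov_r) > 1e12:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        raise ValueError(
            "pooled within-class covariance is singular; pass a positive ridge "
            "(or ridge=None for the automatic trace-scaled value)"
        ) from None
    if priors == "uniform":
        pri = np.full(len(names), 1.0 / len(names))
    elif priors == "proportional":
        sizes = np.asarray([x.shape[0] for x in xs], dtype=float)
        pri = sizes / sizes.sum()
    else:
        pri = np.asarray([priors[n] for n in names], dtype=float)
        if (pri < 0).any() or pri.sum() <= 0:
            raise ValueError("priors must be non-negative with positive sum")
        pri = pri / pri.sum()
    return LDAModel(
        class_names=names,
        means=means,
        cov=cov_r,
        cov_inv=cov_inv,
        priors=pri,
        ridge=lam,
        labels=lib.pufa_labels,
    )


def _log_posteriors(m: LDAModel, x: np.ndarray) -> np.ndarray:
    """Unnormalized log posteriors for rows of x; shape (n, K)."""
    diffs = x[:, None, :] - m.means[None, :, :]  # (n, K, p)
    maha = np.einsum("nkp,pq,nkq->nk", diffs, m.cov_inv, diffs)
    return -0.5 * maha + np.log(m.priors)[None, :]


def classify_matrix(m: LDAModel, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hard class indices and posterior matrix for rows of x.

    Ties in the arg-max are broken toward the lexicographically smallest
    class name and logged.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[1] != m.means.shape[1]:
        raise ValueError(
            f"dimension mismatch: model has {m.means.shape[1]} variables, "
            f"input has {x.shape[1]}"
        )
    lp = _log_posteriors(m, x)
    lp_shift = lp - lp.max(axis=1, keepdims=True)
    post = np.exp(lp_shift)
    post /= post.sum(axis=1, keepdims=True)
    # lexicographic tie-break: scan classes in sorted-name order
    order = np.argsort(np.asarray(m.class_names, dtype=object))
    best = order[np.argmax(lp[:, order], axis=1)]
    n_ties = int((np.sum(np.isclose(lp, lp.max(axis=1, keepdims=True), atol=1e-12), axis=1) > 1).sum())
    if n_ties:
        log.info("classify: %d tied arg-max posteriors broken lexicographically", n_ties)
    return best, post


def classify(m: LDAModel, profile_values: Sequence[float]) -> tuple[str, np.ndarray]:
    """Classify one PUFA composition; returns (class name, posterior vector)."""
    idx, post = classify_matrix(m, np.asarray(profile_values, dtype=float)[None, :])
    return m.class_names[idx[0]], post[0]


@dataclass(frozen=True)
class LOOCVReport:
    """Per-class leave-one-out classification rates and confusion counts."""

    rates: Mapping[str, float]
    confusion: pd.DataFrame  # rows: true class, columns: predicted


def loocv(lib: SourceLibrary, ridge: float | None = None) -> LOOCVReport:
    """Leave-one-out cross-validated classification of the source library.

    Each source sample is classified by a model fit on all remaining
    samples; the per-class rate is the fraction of that class's samples
    correctly re-classified.
    """
    names = lib.names
    confusion = pd.DataFrame(0, index=list(names), columns=list(names), dtype=int)
    for name in names:
        x = lib.groups[name]
        for i in range(x.shape[0]):
            held = x[i]
            reduced_groups = {
                n: (np.delete(g, i, axis=0) if n == name else g)
                for n, g in lib.groups.items()
            }
            reduced = SourceLibrary.__new__(SourceLibrary)
            object.__setattr__(reduced, "groups", reduced_groups)
            object.__setattr__(reduced, "pufa_labels", lib.pufa_labels)
            m = fit_lda(reduced, ridge=ridge)
            pred, _ = classify(m, held)
            confusion.loc[name, pred] += 1
    rates = {
        name: float(confusion.loc[name, name]) / lib.groups[name].shape[0]
        for name in names
    }
    return LOOCVReport(rates=rates, confusion=confusion)


def prune_sources(
    lib: SourceLibrary,
    report: LOOCVReport,
    threshold: float = 0.85,
    iterate: bool = False,
    ridge: float | None = None,
) -> SourceLibrary:
    """Drop source groups whose LOOCV classification rate is below threshold.

    A single evaluation pass by default; ``iterate=True`` re-fits and
    re-screens until the retained set is stable. Raises if fewer than two
    groups survive.
    """
    if set(report.rates) != set(lib.names):
        raise ValueError("LOOCV report does not match library groups")
    keep = [n for n in lib.names if report.rates[n] >= threshold]
    dropped = [n for n in lib.names if n not in keep]
    if dropped:
        log.info("prune_sources: removed %s (LOOCV rate < %.2f)", dropped, threshold)
    if len(keep) < 2:
        raise ValueError(
            f"fewer than 2 sources survive pruning at threshold {threshold}"
        )
    pruned = SourceLibrary({n: lib.groups[n] for n in keep}, lib.pufa_labels)
    if iterate and dropped:
        return prune_sources(pruned, loocv(pruned, ridge=ridge), threshold, True, ridge)
    return pruned


def drop_unshared_pufa(
    lib: SourceLibrary, hosts: ProfileSet | None = None
) -> tuple[SourceLibrary, ProfileSet | None]:
    """Remove PUFA absent (all-zero) from every source group.

    An acid that no candidate source contains cannot inform attribution
    (e.g. 18:5n-3 occurs in coral tissue but not in the sources), so it is
    dropped from the model's variable set — and from the host profiles, if
    given. Retained labels are logged.
    """
    stacked = np.vstack([lib.groups[n] for n in lib.names])
    present = (stacked != 0).any(axis=0)
    if present.all():
        return lib, hosts
    kept = tuple(l for l, k in zip(lib.pufa_labels, present) if k)
    removed = [l for l, k in zip(lib.pufa_labels, present) if not k]
    log.info("drop_unshared_pufa: removed %s; retained %s", removed, list(kept))
    new_lib = SourceLibrary(
        {n: lib.groups[n][:, present] for n in lib.names}, kept
    )
    new_hosts = hosts.subset_labels(kept) if hosts is not None else None
    return new_lib, new_hosts


@dataclass(frozen=True)
class ContributionDistribution:
    """Bootstrap distribution of per-source diet proportions.

    ``samples[species]`` is an (n_iter × K) array whose rows are diet
    combinations: the fraction of that species' host samples assigned to
    each source in one bootstrap iteration (rows sum to 1, entries are
    multiples of 1/n_hosts).
    """

    source_names: tuple[str, ...]
    samples: Mapping[str, np.ndarray]
    n_iter: int
    seed: int | None
    n_redraws: int
    posterior_mode: bool = False

    def summary(self) -> pd.DataFrame:
        """Mean, SD and percentile 95% CI of each source's contribution."""
        rows = []
        for species, arr in self.samples.items():
            lo, hi = np.percentile(arr, [2.5, 97.5], axis=0)
            for k, name in enumerate(self.source_names):
                rows.append(
                    {
                        "species": species,
                        "source": name,
                        "mean": float(arr[:, k].mean()),
                        "sd": float(arr[:, k].std(ddof=1)),
                        "ci_lo": float(lo[k]),
                        "ci_hi": float(hi[k]),
                    }
                )
        return pd.DataFrame(rows)


def _resample_library(
    lib: SourceLibrary, rng: np.random.Generator, max_redraws: int = 100
) -> tuple[dict[str, np.ndarray], int]:
    """Resample each group with replacement to its own size.

    A resample in which a group collapses to a single distinct point would
    make the within-group scatter degenerate, so it is redrawn (counted).
    """
    redraws = 0
    out: dict[str, np.ndarray] = {}
    for name, x in lib.groups.items():
        n = x.shape[0]
        for _ in range(max_redraws):
            idx = rng.integers(0, n, size=n)
            draw = x[idx]
            if not (draw == draw[0]).all():
                out[name] = draw
                break
            redraws += 1
        else:
            raise RuntimeError(
                f"group {name!r}: could not draw a non-degenerate bootstrap resample"
            )
    return out, redraws


def bootstrap_attribution(
    lib: SourceLibrary,
    hosts: ProfileSet,
    n_iter: int = 10000,
    ridge: float | None = None,
    seed: int | None = None,
    posterior_mode: bool = False,
) -> ContributionDistribution:
    """Bootstrap distribution of source contributions to each host species.

    Per iteration, every source group is resampled with replacement
    (preserving its size), the discriminant is refit, and all host samples
    are classified; a species' diet combination is the fraction of its
    samples hard-assigned to each source. ``posterior_mode=True`` instead
    averages soft posteriors over a species' hosts (an alternative, not the
    default definition). With a fixed seed the full distribution is
    reproducible.
    """
    if n_iter < 100:
        warnings.warn(f"n_iter={n_iter} is small; contributions will be noisy")
    host_profiles = [p for p in hosts if p.tissue == "host"]
    if not host_profiles:
        raise ValueError("no host-tissue profiles to attribute")
    labels = lib.pufa_labels
    species_order: list[str] = []
    for p in host_profiles:
        if p.species not in species_order:
            species_order.append(p.species)
    x_host = np.asarray([[p.get(l) for l in labels] for p in host_profiles])
    sp = np.asarray([p.species for p in host_profiles], dtype=object)
    masks = {s: sp == s for s in species_order}
    k = len(lib.names)
    acc = {s: np.zeros((n_iter, k)) for s in species_order}
    rng = np.random.default_rng(seed)
    total_redraws = 0
    for it in range(n_iter):
        groups, redraws = _resample_library(lib, rng)
        total_redraws += redraws
        boot = SourceLibrary.__new__(SourceLibrary)
        object.__setattr__(boot, "groups", groups)
        object.__setattr__(boot, "pufa_labels", labels)
        m = fit_lda(boot, ridge=ridge)
        if posterior_mode:
            _, post = classify_matrix(m, x_host)
            for s in species_order:
                acc[s][it] = post[masks[s]].mean(axis=0)
        else:
            pred, _ = classify_matrix(m, x_host)
            for s in species_order:
                idx = pred[masks[s]]
                counts = np.bincount(idx, minlength=k)
                acc[s][it] = counts / counts.sum()
    if total_redraws:
        log.info("bootstrap_attribution: %d degenerate resamples redrawn", total_redraws)
    return ContributionDistribution(
        source_names=lib.names,
        samples=acc,
        n_iter=n_iter,
        seed=seed,
        n_redraws=total_redraws,
        posterior_mode=posterior_mode,
    )


def aggregate_contributions(
    c: ContributionDistribution, mapping: Mapping[str, str]
) -> pd.DataFrame:
    """Aggregate per-source contributions into categories per iteration.

    ``mapping`` assigns every retained source to a category (typically
    ``particulate`` vs ``symbiont``). Category sums are formed within each
    bootstrap iteration, so they close to 1, and are summarized with mean,
    SD and the percentile 95% interval per host species.
    """
    unmapped = set(c.source_names) - set(mapping)
    if unmapped:
        raise ValueError(f"unmapped sources: {sorted(unmapped)}")
    categories: list[str] = []
    for name in c.source_names:
        if mapping[name] not in categories:
            categories.append(mapping[name])
    rows = []
    for species, arr in c.samples.items():
        for cat in categories:
            cols = [k for k, n in enumerate(c.source_names) if mapping[n] == cat]
            sums = arr[:, cols].sum(axis=1)
            lo, hi = np.percentile(sums, [2.5, 97.5])
            rows.append(
                {
                    "species": species,
                    "category": cat,
                    "mean": float(sums.mean()),
                    "sd": float(sums.std(ddof=1)),
                    "ci_lo": float(lo),
                    "ci_hi": float(hi),
                }
            )
    return pd.DataFrame(rows)
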