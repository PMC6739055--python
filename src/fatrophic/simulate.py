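"""Synthetic fatty-acid data with the statistical structure the analyses assume.

The generator exists so that every downstream stage — indices, permutation
statistics, ordination and the bootstrap-LDA attribution — can be exercised
and validated without access to measured coral data. Three generators are
provided:

* :func:`simulate_sources` — candidate diet groups (plankton, symbionts)
  drawn around group mean compositions,
* :func:`simulate_host_mixture` / :func:`simulate_host_memberships` — host
  samples built either as noisy convex blends of source means or as draws
  from single sources with known membership fractions (the estimand of the
  attribution procedure),
* :func:`simulate_factorial` — a crossed species × tissue × depth design for
  the permutation and univariate statistics.

Within-group variation is modelled as a Dirichlet draw parameterized by a
mean composition and a concentration (larger = tighter around the mean);
structural zeros in the mean stay exactly zero in every draw, matching the
treatment of absent fatty acids as true zeros. The Dirichlet is a modelling
convenience for closed percent data, not a mechanistic claim about lipid
metabolism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .nomenclature import LDA_PUFA_LABELS, STANDARD_LABELS
from .profiles import FAProfile, ProfileSet, concat_profile_sets

__all__ = [
    "SourceSpec",
    "MixtureSpec",
    "FactorialSpec",
    "simulate_sources",
    "simulate_host_mixture",
    "simulate_host_memberships",
    "simulate_factorial",
    "default_source_specs",
    "study_factorial_spec",
]


@dataclass(frozen=True)
class SourceSpec:
    """One candidate diet source group.

    ``mean_composition`` maps fatty-acid labels to percent (summing to 100
    over its support); ``concentration`` is the Dirichlet concentration
    controlling within-group dispersion (larger = tighter).
    """

    name: str
    mean_composition: Mapping[str, float]
    concentration: float = 150.0

    def __post_init__(self) -> None:
        total = sum(self.mean_composition.values())
        if not math.isclose(total, 100.0, abs_tol=1e-6):
            raise ValueError(
                f"source {self.name!r}: mean composition sums to {total}, not 100"
            )
        if any(v < 0 for v in self.mean_composition.values()):
            raise ValueError(f"source {self.name!r}: negative mean proportion")
        if self.concentration <= 0:
            raise ValueError(f"source {self.name!r}: concentration must be positive")


@dataclass(frozen=True)
class MixtureSpec:
    """Ground-truth convex mixture defining synthetic host samples."""

    weights: Mapping[str, float]
    noise_concentration: float = math.inf
    n_samples: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(list(self.weights.values()), dtype=float)
        if (w < 0).any():
            raise ValueError("mixture weights must be non-negative")
        if not math.isclose(w.sum(), 1.0, abs_tol=1e-9):
            raise ValueError(f"mixture weights sum to {w.sum()}, not 1")
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if self.noise_concentration <= 0:
            raise ValueError("noise_concentration must be positive")


def _dirichlet_percent(
    mean_pct: np.ndarray, concentration: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n compositions (percent, rows sum to 100) around a mean.

    Zero entries of the mean are structural zeros: they stay exactly zero.
    An infinite concentration degenerates to the mean itself.
    """
    mean_pct = np.asarray(mean_pct, dtype=float)
    if not math.isfinite(concentration):
        return np.tile(mean_pct, (n, 1))
    support = mean_pct > 0
    alpha = concentration * mean_pct[support] / 100.0
    draws = rng.dirichlet(alpha, size=n)
    out = np.zeros((n, mean_pct.size))
    out[:, support] = draws * 100.0
    return out


def _labels_union(specs: Sequence[SourceSpec]) -> tuple[str, ...]:
    seen: dict[str, None] = {}
    for s in specs:
        for l in s.mean_composition:
            seen.setdefault(l, None)
    return tuple(seen)


def _mean_vector(spec: SourceSpec, labels: Sequence[str]) -> np.ndarray:
    return np.asarray([spec.mean_composition.get(l, 0.0) for l in labels])


def simulate_sources(
    specs: Sequence[SourceSpec],
    n_per_source: int | Mapping[str, int],
    seed: int,
) -> ProfileSet:
    """Draw source-group profiles (tissue ``source``) around each group mean."""
    rng = np.random.default_rng(seed)
    labels = _labels_union(specs)
    sets = []
    for spec in specs:
        n = n_per_source if isinstance(n_per_source, int) else n_per_source[spec.name]
        if n < 2:
            raise ValueError(f"source {spec.name!r}: need at least 2 samples")
        draws = _dirichlet_percent(_mean_vector(spec, labels), spec.concentration, n, rng)
        profiles = [
            FAProfile(
                sample_id=f"{spec.name}_{i + 1:03d}",
                proportions=dict(zip(labels, row)),
                species=spec.name,
                tissue="source",
                source_group=spec.name,
            )
            for i, row in enumerate(draws)
        ]
        sets.append(ProfileSet(profiles, fa_labels=labels))
    return concat_profile_sets(sets)


def simulate_host_mixture(
    sources: Sequence[SourceSpec],
    mix: MixtureSpec,
    *,
    species: str = "synthetic_host",
) -> tuple[ProfileSet, dict[str, float]]:
    """Host samples as noisy convex blends of the source mean compositions.

    The blend is formed first (sum of weight × source mean) and Dirichlet
    noise is applied around the blended mean, so the returned ``weights``
    remain the estimand. With infinite ``noise_concentration`` every host
    equals the blend exactly.
    """
    unknown = set(mix.weights) - {s.name for s in sources}
    if unknown:
        raise ValueError(f"mixture references unknown sources: {sorted(unknown)}")
    labels = _labels_union(sources)
    by_name = {s.name: s for s in sources}
    blend = np.zeros(len(labels))
    for name, w in mix.weights.items():
        blend += w * _mean_vector(by_name[name], labels)
    rng = np.random.default_rng(mix.seed)
    draws = _dirichlet_percent(blend, mix.noise_concentration, mix.n_samples, rng)
    profiles = [
        FAProfile(
            sample_id=f"{species}_{i + 1:03d}",
            proportions=dict(zip(labels, row)),
            species=species,
            tissue="host",
        )
        for i, row in enumerate(draws)
    ]
    return ProfileSet(profiles, fa_labels=labels), dict(mix.weights)


def _exact_counts(weights: Mapping[str, float], n: int) -> dict[str, int]:
    """Largest-remainder rounding of weight × n to integer counts."""
    names = list(weights)
    raw = np.asarray([weights[k] * n for k in names], dtype=float)
    base = np.floor(raw).astype(int)
    rem = raw - base
    short = n - int(base.sum())
    for idx in np.argsort(-rem)[:short]:
        base[idx] += 1
    return dict(zip(names, (int(b) for b in base)))


def simulate_host_memberships(
    sources: Sequence[SourceSpec],
    weights: Mapping[str, float],
    n_samples: int,
    seed: int,
    *,
    species: str = "synthetic_host",
) -> tuple[ProfileSet, dict[str, float]]:
    """Host samples each drawn from a single source, with known memberships.

    Membership counts are fixed by largest-remainder rounding of
    ``weights × n_samples`` so the returned true fractions are exact
    multiples of ``1/n_samples`` — the same resolution at which the
    attribution procedure reports per-iteration diet combinations.
    """
    w = np.asarray(list(weights.values()), dtype=float)
    if (w < 0).any() or not math.isclose(w.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("membership weights must be non-negative and sum to 1")
    by_name = {s.name: s for s in sources}
    unknown = set(weights) - set(by_name)
    if unknown:
        raise ValueError(f"membership references unknown sources: {sorted(unknown)}")
    labels = _labels_union(sources)
    counts = _exact_counts(weights, n_samples)
    rng = np.random.default_rng(seed)
    profiles: list[FAProfile] = []
    i = 0
    for name, k in counts.items():
        spec = by_name[name]
        draws = _dirichlet_percent(_mean_vector(spec, labels), spec.concentration, k, rng)
        for row in draws:
            i += 1
            profiles.append(
                FAProfile(
                    sample_id=f"{species}_{i:03d}",
                    proportions=dict(zip(labels, row)),
                    species=species,
                    tissue="host",
                )
            )
    true_fracs = {name: counts[name] / n_samples for name in weights}
    return ProfileSet(profiles, fa_labels=labels), true_fracs


@dataclass(frozen=True)
class FactorialSpec:
    """A crossed species × tissue × depth design.

    ``cell_means`` maps ``(species, tissue, depth_m)`` to a mean composition
    (label → percent, summing to 100). ``n_per_cell`` samples are drawn per
    cell with the given Dirichlet concentration.
    """

    cell_means: Mapping[tuple[str, str, float], Mapping[str, float]]
    n_per_cell: int = 5
    concentration: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.cell_means) < 2:
            raise ValueError("need at least 2 cells")
        if self.n_per_cell < 2:
            raise ValueError("need at least 2 samples per cell")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        for key, mean in self.cell_means.items():
            total = sum(mean.values())
            if not math.isclose(total, 100.0, abs_tol=1e-6):
                raise ValueError(f"cell {key}: mean sums to {total}, not 100")


def simulate_factorial(spec: FactorialSpec) -> ProfileSet:
    """Draw a labelled factorial dataset from per-cell mean compositions."""
    rng = np.random.default_rng(spec.seed)
    seen: dict[str, None] = {}
    for mean in spec.cell_means.values():
        for l in mean:
            seen.setdefault(l, None)
    labels = tuple(seen)
    profiles: list[FAProfile] = []
    for (species, tissue, depth), mean in spec.cell_means.items():
        mean_vec = np.asarray([mean.get(l, 0.0) for l in labels])
        draws = _dirichlet_percent(mean_vec, spec.concentration, spec.n_per_cell, rng)
        for i, row in enumerate(draws):
            profiles.append(
                FAProfile(
                    sample_id=f"{species}_{tissue}_{depth:g}m_{i + 1:02d}",
                    proportions=dict(zip(labels, row)),
                    species=species,
                    tissue=tissue,
                    depth_m=float(depth),
                )
            )
    return ProfileSet(profiles, fa_labels=labels)


# ---------------------------------------------------------------------------
# Default fixtures
# ---------------------------------------------------------------------------

#: Source mean PUFA compositions (percent of the 8-acid PUFA subset) loosely
#: patterned on published group contrasts: diatoms rich in 20:5n-3 (EPA),
#: copepods rich in 22:6n-3 (DHA) and EPA, cyanobacteria dominated by C18
#: n-6/n-3 acids, cryptophytes rich in 18:3n-3/18:4n-3, dinoflagellates and
#: coral symbionts rich in 18:4n-3 and DHA with symbionts carrying the
#: 18:3n-6 signal. 18:5n-3 is zero in every source (it occurs in coral
#: tissue but not in the candidate sources, so the attribution model
#: discards it).
_SOURCE_MEANS: dict[str, dict[str, float]] = {
    "diatom": {
        "18:2n-6": 3.0, "18:3n-3": 1.0, "18:3n-6": 1.0, "18:4n-3": 9.0,
        "18:5n-3": 0.0, "20:4n-6": 3.0, "20:5n-3": 58.0, "22:6n-3": 25.0,
    },
    "copepod": {
        "18:2n-6": 4.0, "18:3n-3": 3.0, "18:3n-6": 1.0, "18:4n-3": 7.0,
        "18:5n-3": 0.0, "20:4n-6": 3.0, "20:5n-3": 30.0, "22:6n-3": 52.0,
    },
    "cyanobacteria": {
        "18:2n-6": 36.0, "18:3n-3": 26.0, "18:3n-6": 12.0, "18:4n-3": 10.0,
        "18:5n-3": 0.0, "20:4n-6": 4.0, "20:5n-3": 8.0, "22:6n-3": 4.0,
    },
    "cryptophyte": {
        "18:2n-6": 8.0, "18:3n-3": 27.0, "18:3n-6": 2.0, "18:4n-3": 30.0,
        "18:5n-3": 0.0, "20:4n-6": 1.0, "20:5n-3": 17.0, "22:6n-3": 15.0,
    },
    "dinoflagellate": {
        "18:2n-6": 5.0, "18:3n-3": 2.0, "18:3n-6": 3.0, "18:4n-3": 25.0,
        "18:5n-3": 0.0, "20:4n-6": 1.0, "20:5n-3": 14.0, "22:6n-3": 50.0,
    },
    "symbiont": {
        "18:2n-6": 13.0, "18:3n-3": 1.0, "18:3n-6": 20.0, "18:4n-3": 26.0,
        "18:5n-3": 0.0, "20:4n-6": 6.0, "20:5n-3": 10.0, "22:6n-3": 24.0,
    },
}

#: Literature-style group sizes for the candidate sources.
DEFAULT_SOURCE_N: dict[str, int] = {
    "diatom": 14,
    "cyanobacteria": 11,
    "dinoflagellate": 12,
    "cryptophyte": 16,
    "copepod": 19,
    "symbiont": 10,
}


def default_source_specs(
    names: Sequence[str] | None = None, *, concentration: float = 150.0
) -> list[SourceSpec]:
    """Built-in source groups over the 8-acid attribution PUFA set."""
    names = list(names) if names is not None else list(_SOURCE_MEANS)
    unknown = set(names) - set(_SOURCE_MEANS)
    if unknown:
        raise ValueError(f"no built-in mean for: {sorted(unknown)}")
    return [
        SourceSpec(n, dict(_SOURCE_MEANS[n]), concentration=concentration)
        for n in names
    ]


# Base 30-acid compositions for the factorial generator. Host tissue is
# dominated by 16:0/18:0 with abundant 22:4n-6; symbiont tissue carries the
# C18 PUFA (18:3n-6, 18:4n-3) and less 18:0. Values are percent, sum 100.
_HOST_BASE: dict[str, float] = {
    "14:0": 1.0, "15:0": 0.4, "16:0": 34.0, "17:0": 0.6, "18:0": 25.0,
    "20:0": 0.6, "22:0": 0.5, "24:0": 0.5,
    "16:1n-7": 2.5, "18:1n-7": 2.5, "18:1n-9": 4.5,
    "20:1n-11": 0.4, "20:1n-9": 0.8, "20:1n-7": 0.3,
    "22:1n-11": 0.4, "22:1n-9": 0.3, "22:1n-7": 0.2,
    "18:2n-6": 1.6, "18:3n-3": 0.0, "18:3n-6": 1.4, "18:4n-3": 1.8,
    "18:5n-3": 0.5, "20:2n-6": 0.5, "20:3n-6": 0.4, "20:4n-3": 0.6,
    "20:4n-6": 3.8, "20:5n-3": 3.4, "22:4n-6": 6.0, "22:5n-3": 1.5,
    "22:6n-3": 4.0,
}
_SYMBIONT_BASE: dict[str, float] = {
    "14:0": 2.0, "15:0": 0.4, "16:0": 38.0, "17:0": 0.5, "18:0": 10.0,
    "20:0": 0.5, "22:0": 0.4, "24:0": 0.4,
    "16:1n-7": 4.5, "18:1n-7": 3.5, "18:1n-9": 3.0,
    "20:1n-11": 0.2, "20:1n-9": 0.3, "20:1n-7": 0.1,
    "22:1n-11": 0.2, "22:1n-9": 0.1, "22:1n-7": 0.1,
    "18:2n-6": 2.8, "18:3n-3": 0.1, "18:3n-6": 6.0, "18:4n-3": 6.0,
    "18:5n-3": 1.5, "20:2n-6": 0.4, "20:3n-6": 0.5, "20:4n-3": 0.7,
    "20:4n-6": 2.6, "20:5n-3": 5.2, "22:4n-6": 2.0, "22:5n-3": 1.0,
    "22:6n-3": 6.9,
}

# Per-species multiplicative tweaks applied to selected acids before
# re-closing to 100 (species_effect scales the tweak strength): the more
# heterotrophic species is enriched in LC-MUFA and 22:5n-3, the more
# autotrophic in 18:1n-7.
_SPECIES_TWEAKS: dict[str, dict[str, float]] = {
    "sp_hetero": {"20:1n-9": 3.0, "22:1n-11": 2.5, "22:5n-3": 1.8, "18:1n-7": 0.7},
    "sp_auto": {"18:1n-7": 1.8, "16:1n-7": 1.4, "18:1n-9": 0.7},
    "sp_mixed": {},
}


def _tweaked(base: Mapping[str, float], tweaks: Mapping[str, float], effect: float) -> dict[str, float]:
    out = {l: v * (1.0 + effect * (tweaks.get(l, 1.0) - 1.0)) for l, v in base.items()}
    total = sum(out.values())
    return {l: 100.0 * v / total for l, v in out.items()}


def study_factorial_spec(
    *,
    species: Sequence[str] = ("sp_hetero", "sp_auto", "sp_mixed"),
    depths: Sequence[float] = (10.0, 30.0),
    n_per_species_tissue: int = 10,
    species_effect: float = 1.0,
    depth_effect: float = 0.0,
    concentration: float = 300.0,
    seed: int = 0,
) -> FactorialSpec:
    """Study-shaped crossed design: 3 species × {host, symbiont} × 2 depths.

    ``n_per_species_tissue`` samples per species/tissue cell are split
    evenly over depths (10 per cell at two depths → 5 per depth cell; 60
    host + 60 symbiont samples in total with the defaults). Setting
    ``species_effect=0`` and ``depth_effect=0`` collapses the corresponding
    factor to the null. ``depth_effect`` shifts 16:0 against 22:6n-3 with
    depth, a simple proxy for a light-driven compositional gradient.
    """
    if n_per_species_tissue % len(depths) != 0:
        raise ValueError("n_per_species_tissue must divide evenly over depths")
    cell_means: dict[tuple[str, str, float], dict[str, float]] = {}
    for i, sp in enumerate(species):
        tweaks = _SPECIES_TWEAKS.get(sp, {})
        for tissue, base in (("host", _HOST_BASE), ("symbiont", _SYMBIONT_BASE)):
            mean = _tweaked(base, tweaks, species_effect)
            for d in depths:
                m = dict(mean)
                if depth_effect:
                    shift = depth_effect * (d - np.mean(depths)) / 10.0
                    m["16:0"] = max(m["16:0"] - shift, 0.0)
                    m["22:6n-3"] = max(m["22:6n-3"] + shift, 0.0)
                    total = sum(m.values())
                    m = {l: 100.0 * v / total for l, v in m.items()}
                cell_means[(sp, tissue, d)] = m
    return FactorialSpec(
        cell_means=cell_means,
        n_per_cell=n_per_species_tissue // len(depths),
        concentration=concentration,
        seed=seed,
    )
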