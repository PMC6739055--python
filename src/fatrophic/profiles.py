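"""Fatty-acid profiles, profile collections, and peak-area mass conversion.

A profile stores one sample's fatty-acid composition as percent of total
fatty acids (the 0–100 scale used in published composition tables).
Compositions are kept untransformed — no log-ratio transform and no
zero imputation — so that minor acids are not artificially inflated; an
absent acid is semantically 0%.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .nomenclature import canonicalize_label, parse_fatty_acid_label

__all__ = [
    "FAProfile",
    "ProfileSet",
    "MassResult",
    "validate_profile",
    "subset_profile",
    "mass_from_peaks",
]

#: Allowed tissue values. "source" marks candidate diet items (plankton
#: groups, symbionts treated as a PUFA source).
TISSUES = ("host", "symbiont", "source")


@dataclass(frozen=True)
class FAProfile:
    """One sample's fatty-acid composition plus factor metadata.

    ``proportions`` maps canonical fatty-acid labels to percent of total
    fatty acids. Labels not present are treated as exactly zero.
    """

    sample_id: str
    proportions: Mapping[str, float]
    species: str = ""
    tissue: str = "host"
    depth_m: float | None = None
    source_group: str | None = None

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValueError(
                f"tissue must be one of {TISSUES}, got {self.tissue!r}"
            )

    def get(self, label: str) -> float:
        """Proportion of ``label`` in percent; 0.0 if the acid is absent."""
        return float(self.proportions.get(canonicalize_label(label), 0.0))

    def total(self) -> float:
        return float(sum(self.proportions.values()))

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.proportions)


def validate_profile(
    raw: Mapping[str, float],
    *,
    sample_id: str,
    species: str = "",
    tissue: str = "host",
    depth_m: float | None = None,
    source_group: str | None = None,
    renormalize: bool = False,
    tol: float = 1.0,
) -> FAProfile:
    """Validate a raw label→percent mapping and build an :class:`FAProfile`.

    Labels are canonicalized and checked against the ``C:Dn-x`` grammar.
    All values must be non-negative with at least one positive. Unless
    ``renormalize`` is set the total must lie within ``tol`` percentage
    points of 100 (the default 1.0 absorbs rounding in published tables);
    with ``renormalize`` the proportions are rescaled to sum to exactly 100.
    """
    clean: dict[str, float] = {}
    for label, value in raw.items():
        fa = parse_fatty_acid_label(label)
        v = float(value)
        if not np.isfinite(v):
            raise ValueError(f"sample {sample_id!r}: non-finite value for {fa.label}")
        if v < 0:
            raise ValueError(
                f"sample {sample_id!r}: negative proportion {v} for {fa.label}"
            )
        if fa.label in clean:
            raise ValueError(f"sample {sample_id!r}: duplicate label {fa.label}")
        clean[fa.label] = v
    total = sum(clean.values())
    if total <= 0:
        raise ValueError(f"sample {sample_id!r}: all proportions are zero")
    if renormalize:
        clean = {k: 100.0 * v / total for k, v in clean.items()}
    elif abs(total - 100.0) > tol:
        raise ValueError(
            f"sample {sample_id!r}: proportions sum to {total:.4f}, "
            f"outside 100 ± {tol} (set renormalize=True to rescale)"
        )
    return FAProfile(
        sample_id=sample_id,
        proportions=clean,
        species=species,
        tissue=tissue,
        depth_m=depth_m,
        source_group=source_group,
    )


def subset_profile(
    p: FAProfile, labels: Sequence[str], *, renormalize: bool = False
) -> FAProfile:
    """Restrict a profile to ``labels`` (absent acids become explicit zeros).

    With ``renormalize`` the retained proportions are rescaled to sum to
    100, turning e.g. a 30-acid profile into a closed 12-PUFA composition.
    """
    if not labels:
        raise ValueError("labels must be non-empty")
    canon = [parse_fatty_acid_label(l).label for l in labels]
    sub = {l: p.get(l) for l in canon}
    if renormalize:
        total = sum(sub.values())
        if total <= 0:
            raise ValueError(
                f"sample {p.sample_id!r}: subset has zero total, cannot renormalize"
            )
        sub = {k: 100.0 * v / total for k, v in sub.items()}
    return replace(p, proportions=sub)


@dataclass
class ProfileSet:
    """An ordered collection of profiles with a shared label universe.

    ``fa_labels`` is the union of labels across profiles in first-seen
    order (or an explicit order passed by the caller); the matrix view is
    complete, with missing entries filled with 0.
    """

    profiles: list[FAProfile]
    fa_labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        ids = [p.sample_id for p in self.profiles]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample_ids: {dupes}")
        if not self.fa_labels:
            seen: dict[str, None] = {}
            for p in self.profiles:
                for l in p.labels:
                    seen.setdefault(l, None)
            self.fa_labels = tuple(seen)
        else:
            self.fa_labels = tuple(
                parse_fatty_acid_label(l).label for l in self.fa_labels
            )

    def __len__(self) -> int:
        return len(self.profiles)

    def __iter__(self) -> Iterator[FAProfile]:
        return iter(self.profiles)

    @property
    def sample_ids(self) -> list[str]:
        return [p.sample_id for p in self.profiles]

    def matrix(self, labels: Sequence[str] | None = None) -> np.ndarray:
        """(n_samples, n_labels) array of percent proportions."""
        labels = tuple(labels) if labels is not None else self.fa_labels
        out = np.zeros((len(self.profiles), len(labels)))
        for i, p in enumerate(self.profiles):
            for j, l in enumerate(labels):
                out[i, j] = p.get(l)
        return out

    def metadata(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [p.sample_id for p in self.profiles],
                "species": [p.species for p in self.profiles],
                "tissue": [p.tissue for p in self.profiles],
                "depth_m": [p.depth_m for p in self.profiles],
                "source_group": [p.source_group for p in self.profiles],
            }
        )

    def to_frame(self) -> pd.DataFrame:
        """One row per sample: metadata columns then one column per label."""
        meta = self.metadata()
        comp = pd.DataFrame(self.matrix(), columns=list(self.fa_labels))
        return pd.concat([meta, comp], axis=1)

    def select(self, predicate: Callable[[FAProfile], bool]) -> "ProfileSet":
        return ProfileSet(
            [p for p in self.profiles if predicate(p)], fa_labels=self.fa_labels
        )

    def subset_labels(
        self, labels: Sequence[str], *, renormalize: bool = False
    ) -> "ProfileSet":
        canon = tuple(parse_fatty_acid_label(l).label for l in labels)
        return ProfileSet(
            [subset_profile(p, canon, renormalize=renormalize) for p in self.profiles],
            fa_labels=canon,
        )

    def factor(self, name: str) -> np.ndarray:
        """Metadata column as an array of labels (for permutation designs)."""
        if name not in ("species", "tissue", "depth_m", "source_group"):
            raise KeyError(f"unknown factor {name!r}")
        return np.asarray([getattr(p, name) for p in self.profiles], dtype=object)


@dataclass(frozen=True)
class MassResult:
    """Per-acid and total fatty-acid mass, in µg per mg dry tissue."""

    masses: Mapping[str, float]
    total_mass: float


def mass_from_peaks(
    peak_areas: Mapping[str, float],
    *,
    slope: float,
    hexane_volume_ml: float,
    tissue_mass_mg: float,
) -> MassResult:
    """Convert GC-FID peak areas to fatty-acid mass per dry tissue weight.

    A standard-curve calibration gives a common slope (peak area per µg);
    each acid's mass is then ``(area / slope) * hexane_volume / tissue_mass``,
    in µg per mg dry tissue. The conversion is linear in peak area.
    """
    if slope <= 0:
        raise ValueError("slope must be positive")
    if hexane_volume_ml <= 0:
        raise ValueError("hexane_volume_ml must be positive")
    if tissue_mass_mg <= 0:
        raise ValueError("tissue_mass_mg must be positive")
    masses: dict[str, float] = {}
    for label, area in peak_areas.items():
        fa = parse_fatty_acid_label(label)
        a = float(area)
        if a < 0:
            raise ValueError(f"negative peak area for {fa.label}")
        masses[fa.label] = (a / slope) * hexane_volume_ml / tissue_mass_mg
    return MassResult(masses=masses, total_mass=float(sum(masses.values())))


def concat_profile_sets(sets: Iterable[ProfileSet]) -> ProfileSet:
    """Concatenate profile sets, merging their label universes in order."""
    profiles: list[FAProfile] = []
    labels: dict[str, None] = {}
    for ps in sets:
        profiles.extend(ps.profiles)
        for l in ps.fa_labels:
            labels.setdefault(l, None)
    return ProfileSet(profiles, fa_labels=tuple(labels))
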