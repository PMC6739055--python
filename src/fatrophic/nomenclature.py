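"""Fatty-acid shorthand nomenclature.

Fatty acids are named in the ``C:Dn-x`` convention used throughout marine
lipid ecology: ``C`` carbons in the chain, ``D`` double bonds, and — for
unsaturated acids — the position ``x`` of the first double bond counted from
the methyl (omega) end, e.g. ``20:5n-3`` (EPA) or ``22:6n-3`` (DHA).
Saturated acids carry no omega suffix (``16:0``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = [
    "FattyAcid",
    "parse_fatty_acid_label",
    "canonicalize_label",
    "PUFA_LABELS",
    "LDA_PUFA_LABELS",
    "LC_MUFA_LABELS",
    "STANDARD_LABELS",
]

_LABEL_RE = re.compile(r"^(\d+):(\d+)(?:n-(\d+))?$")

#: Unicode dashes that appear in published tables in place of ASCII "-".
_DASHES = {"−": "-", "–": "-", "—": "-"}


def canonicalize_label(label: str) -> str:
    """Strip whitespace and normalize unicode dashes in a fatty-acid label."""
    s = str(label)
    for bad, good in _DASHES.items():
        s = s.replace(bad, good)
    return re.sub(r"\s+", "", s)


@dataclass(frozen=True)
class FattyAcid:
    """A parsed fatty-acid identity.

    Attributes
    ----------
    label : str
        Canonical ``C:Dn-x`` shorthand.
    carbons : int
        Chain length (> 0).
    double_bonds : int
        Number of double bonds (>= 0).
    omega_series : int or None
        Position of the first double bond from the methyl end; ``None``
        exactly when the acid is saturated.
    """

    label: str
    carbons: int
    double_bonds: int
    omega_series: int | None

    @property
    def fa_class(self) -> str:
        """Saturation class: SFA (0 double bonds), MUFA (1) or PUFA (>= 2)."""
        if self.double_bonds == 0:
            return "SFA"
        if self.double_bonds == 1:
            return "MUFA"
        return "PUFA"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def parse_fatty_acid_label(label: str) -> FattyAcid:
    """Parse a ``C:Dn-x`` shorthand label into a :class:`FattyAcid`.

    Raises
    ------
    ValueError
        If the label is malformed, if an omega suffix accompanies a
        saturated acid, or if an unsaturated acid lacks its omega suffix.
    """
    canon = canonicalize_label(label)
    m = _LABEL_RE.match(canon)
    if m is None:
        raise ValueError(f"malformed fatty-acid label: {label!r}")
    carbons = int(m.group(1))
    double_bonds = int(m.group(2))
    omega = int(m.group(3)) if m.group(3) is not None else None
    if carbons <= 0:
        raise ValueError(f"fatty-acid label {label!r}: carbons must be positive")
    if double_bonds == 0 and omega is not None:
        raise ValueError(
            f"fatty-acid label {label!r}: omega series given for a saturated acid"
        )
    if double_bonds > 0 and omega is None:
        raise ValueError(
            f"fatty-acid label {label!r}: unsaturated acid missing its n-x omega series"
        )
    if omega is not None and omega <= 0:
        raise ValueError(f"fatty-acid label {label!r}: omega series must be positive")
    return FattyAcid(canon, carbons, double_bonds, omega)


def format_fatty_acid(fa: FattyAcid) -> str:
    """Render a :class:`FattyAcid` back to canonical shorthand."""
    if fa.double_bonds == 0:
        return f"{fa.carbons}:{fa.double_bonds}"
    return f"{fa.carbons}:{fa.double_bonds}n-{fa.omega_series}"


#: The 12 polyunsaturated fatty acids used for PUFA ordination.
PUFA_LABELS: tuple[str, ...] = (
    "18:2n-6", "18:3n-3", "18:3n-6", "18:4n-3", "20:2n-6", "20:3n-6",
    "20:4n-3", "20:4n-6", "20:5n-3", "22:4n-6", "22:5n-3", "22:6n-3",
)

#: The metabolically important PUFA compared between hosts and candidate
#: diet sources before the model prunes acids absent from every source.
LDA_PUFA_LABELS: tuple[str, ...] = (
    "18:2n-6", "18:3n-3", "18:3n-6", "18:4n-3", "18:5n-3",
    "20:4n-6", "20:5n-3", "22:6n-3",
)

#: The six long-chain monounsaturated isomers summed by the copepod-feeding
#: index. Exactly these six; other 20:1/22:1 isomers do not enter the sum.
LC_MUFA_LABELS: tuple[str, ...] = (
    "20:1n-11", "20:1n-9", "20:1n-7", "22:1n-11", "22:1n-9", "22:1n-7",
)

#: A 30-acid reporting panel typical of coral GC-FID profiles: 8 saturated,
#: 9 monounsaturated (including the six LC-MUFA) and 13 polyunsaturated
#: (the 12 ordination PUFA plus 18:5n-3).
STANDARD_LABELS: tuple[str, ...] = (
    "14:0", "15:0", "16:0", "17:0", "18:0", "20:0", "22:0", "24:0",
    "16:1n-7", "18:1n-7", "18:1n-9",
    "20:1n-11", "20:1n-9", "20:1n-7", "22:1n-11", "22:1n-9", "22:1n-7",
    "18:2n-6", "18:3n-3", "18:3n-6", "18:4n-3", "18:5n-3",
    "20:2n-6", "20:3n-6", "20:4n-3", "20:4n-6", "20:5n-3",
    "22:4n-6", "22:5n-3", "22:6n-3",
)
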