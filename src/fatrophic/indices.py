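"""Trophic fatty-acid biomarker indices.

Three established indices are computed per sample, as proxies for the
relative contribution of photosynthesis-derived versus animal-derived
nutrition and for feeding on herbivorous copepods:

1. ``ratio_18_1`` — 18:1n-7 / 18:1n-9. The vaccenic isomer derives from
   elongation of photosynthetically produced 16:1n-7, while the oleic
   isomer is a major acid of most marine animals; a higher ratio indicates
   more photosynthesis-derived input.
2. ``photo_animal`` — (16:1n-7 + 18:1n-7) / (18:1n-9 + 20:1n-9 + 22:1n-11),
   a related photosynthetic-vs-animal input ratio.
3. ``lc_mufa_sum`` — the sum of the six long-chain monounsaturated isomers
   20:1n-11, 20:1n-9, 20:1n-7, 22:1n-11, 22:1n-9, 22:1n-7 (percent of total
   fatty acids), elevated in corals feeding on calanoid copepods.

Ratios with a zero denominator are undefined; they are recorded as NaN and
counted, never raised, so downstream ANOVA can drop them pairwise.
"""

from __future__ import annotations

import logging
import math

import pandas as pd

from .nomenclature import LC_MUFA_LABELS
from .profiles import FAProfile, ProfileSet

__all__ = [
    "ratio_18_1n7_to_18_1n9",
    "photosynthetic_animal_index",
    "sum_lc_mufa",
    "index_table",
]

log = logging.getLogger(__name__)

PHOTO_LABELS = ("16:1n-7", "18:1n-7")
ANIMAL_LABELS = ("18:1n-9", "20:1n-9", "22:1n-11")


def ratio_18_1n7_to_18_1n9(p: FAProfile) -> float:
    """18:1n-7 / 18:1n-9; NaN if 18:1n-9 is absent."""
    denom = p.get("18:1n-9")
    if denom == 0:
        return math.nan
    return p.get("18:1n-7") / denom


def photosynthetic_animal_index(p: FAProfile) -> float:
    """(16:1n-7 + 18:1n-7) / (18:1n-9 + 20:1n-9 + 22:1n-11); NaN if the
    animal-derived denominator is zero."""
    denom = sum(p.get(l) for l in ANIMAL_LABELS)
    if denom == 0:
        return math.nan
    return sum(p.get(l) for l in PHOTO_LABELS) / denom


def sum_lc_mufa(p: FAProfile) -> float:
    """Sum of the six LC-MUFA isomers, percent of total fatty acids."""
    return sum(p.get(l) for l in LC_MUFA_LABELS)


def index_table(ps: ProfileSet) -> pd.DataFrame:
    """Per-sample table of the three indices plus factor metadata.

    Rows keep the input sample order. Undefined ratios appear as NaN; their
    count is logged so analyses that drop them do so visibly.
    """
    if len(ps) == 0:
        raise ValueError("need at least one profile")
    table = ps.metadata()
    table["ratio_18_1"] = [ratio_18_1n7_to_18_1n9(p) for p in ps]
    table["photo_animal"] = [photosynthetic_animal_index(p) for p in ps]
    table["lc_mufa_sum"] = [sum_lc_mufa(p) for p in ps]
    n_undef = int(table[["ratio_18_1", "photo_animal"]].isna().sum().sum())
    if n_undef:
        log.info("index_table: %d undefined ratio values (zero denominators)", n_undef)
    return table
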