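"""Reading and writing tabular fatty-acid profiles.

The standard layout is one row per sample: metadata columns
(``sample_id``, ``species``, ``tissue``, ``depth_m``, ``source_group``)
followed by one column per fatty-acid label in ``C:Dn-x`` shorthand.
CSV, TSV and XLSX (supplementary-table style) are supported. Unicode
dashes in column labels are normalized; columns that are neither metadata
nor parseable fatty-acid labels are reported and skipped.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .nomenclature import canonicalize_label, parse_fatty_acid_label
from .profiles import FAProfile, ProfileSet, validate_profile

__all__ = ["read_profiles", "write_profiles"]

log = logging.getLogger(__name__)

META_COLUMNS = ("sample_id", "species", "tissue", "depth_m", "source_group")


def _read_table(path: Path, fmt: str | None) -> pd.DataFrame:
    if fmt is None:
        fmt = {".csv": "csv", ".tsv": "tsv", ".xlsx": "xlsx"}.get(
            path.suffix.lower(), "csv"
        )
    if fmt == "csv":
        return pd.read_csv(path)
    if fmt == "tsv":
        return pd.read_csv(path, sep="\t")
    if fmt == "xlsx":
        return pd.read_excel(path)
    raise ValueError(f"unknown format {fmt!r}")


def read_profiles(
    path: str | Path,
    fmt: str | None = None,
    *,
    renormalize: bool = False,
    tol: float = 1.0,
) -> ProfileSet:
    """Read a profile table into a validated :class:`ProfileSet`.

    ``fmt`` is inferred from the suffix when not given. Missing proportion
    cells are treated as zero. Raises on duplicate sample_ids or when no
    fatty-acid column can be parsed.
    """
    path = Path(path)
    df = _read_table(path, fmt)
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'sample_id'")
    fa_columns: list[tuple[str, str]] = []  # (original, canonical)
    skipped: list[str] = []
    for col in df.columns:
        if col in META_COLUMNS:
            continue
        try:
            canon = parse_fatty_acid_label(str(col)).label
        except ValueError:
            skipped.append(str(col))
            continue
        fa_columns.append((col, canon))
    if skipped:
        log.warning("%s: skipping unparseable fatty-acid columns %s", path, skipped)
    if not fa_columns:
        raise ValueError(f"{path}: no fatty-acid columns found")
    profiles: list[FAProfile] = []
    for _, row in df.iterrows():
        raw = {}
        for col, canon in fa_columns:
            v = row[col]
            raw[canon] = 0.0 if pd.isna(v) else float(v)
        depth = row.get("depth_m")
        depth = None if depth is None or pd.isna(depth) else float(depth)
        group = row.get("source_group")
        group = None if group is None or (isinstance(group, float) and np.isnan(group)) or group == "" else str(group)
        profiles.append(
            validate_profile(
                raw,
                sample_id=str(row["sample_id"]),
                species=str(row.get("species", "") or ""),
                tissue=str(row.get("tissue", "host") or "host"),
                depth_m=depth,
                source_group=group,
                renormalize=renormalize,
                tol=tol,
            )
        )
    labels = tuple(canon for _, canon in fa_columns)
    # preserve column order, deduplicated
    seen: dict[str, None] = {}
    for l in labels:
        seen.setdefault(l, None)
    return ProfileSet(profiles, fa_labels=tuple(seen))


def write_profiles(ps: ProfileSet, path: str | Path, fmt: str | None = None) -> None:
    """Write a ProfileSet in the standard one-row-per-sample layout."""
    path = Path(path)
    if fmt is None:
        fmt = {".csv": "csv", ".tsv": "tsv", ".xlsx": "xlsx"}.get(
            path.suffix.lower(), "csv"
        )
    df = ps.to_frame()
    if fmt == "csv":
        df.to_csv(path, index=False)
    elif fmt == "tsv":
        df.to_csv(path, sep="\t", index=False)
    elif fmt == "xlsx":
        df.to_excel(path, index=False)
    else:
        raise ValueError(f"unknown format {fmt!r}")
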