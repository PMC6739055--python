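"""Univariate statistics: ANOVA with TukeyHSD, and host-vs-symbiont OLS.

ANOVA uses the classical fixed-effects decomposition (sequential, type-I
sums of squares, matching a balanced crossed design) via statsmodels;
TukeyHSD adjusted p-values come from the studentized-range distribution.
Per-fatty-acid regressions relate the host proportion of an acid to the
symbiont proportion in the same colony, reporting slope, intercept,
adjusted R² and the slope p-value. No multiple-testing correction is
applied across the per-acid regressions; the table reports raw p-values
with a significance flag at α = 0.05.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .indices import sum_lc_mufa
from .profiles import ProfileSet

__all__ = [
    "AnovaResult",
    "TukeyResult",
    "RegressionResult",
    "anova",
    "tukey_hsd",
    "linear_fit",
    "host_symbiont_regressions",
    "cell_labels",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnovaTerm:
    name: str
    df: int
    ss: float
    ms: float
    f: float
    p: float


@dataclass(frozen=True)
class AnovaResult:
    terms: tuple[AnovaTerm, ...]
    residual_df: int
    residual_ss: float

    def term(self, name: str) -> AnovaTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)


def _drop_missing(
    response: Sequence[float], factor_sets: list[np.ndarray]
) -> tuple[np.ndarray, list[np.ndarray]]:
    y = np.asarray(response, dtype=float)
    keep = np.isfinite(y)
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("anova: dropping %d undefined response values", n_drop)
    return y[keep], [f[keep] for f in factor_sets]


def anova(
    response: Sequence[float],
    factors: Mapping[str, Sequence],
    interaction: bool = False,
) -> AnovaResult:
    """Fixed-effects one- or two-way ANOVA (sequential decomposition).

    ``factors`` maps one or two factor names to per-observation labels.
    NaN responses (e.g. undefined index ratios) are dropped pairwise with a
    logged count. A completely constant response returns F = 0, p = 1 for
    every term.
    """
    if not 1 <= len(factors) <= 2:
        raise ValueError("anova supports one or two factors")
    names = list(factors)
    arrays = [np.asarray(factors[n], dtype=object) for n in names]
    y, arrays = _drop_missing(response, arrays)
    if y.size < 3:
        raise ValueError("too few observations after dropping undefined values")
    for name, arr in zip(names, arrays):
        if len(set(arr)) < 2:
            raise ValueError(f"factor {name!r} needs at least 2 levels")
    if interaction:
        if len(names) != 2:
            raise ValueError("interaction requires two factors")
        cells = pd.crosstab(pd.Series(arrays[0]), pd.Series(arrays[1]))
        if (cells < 2).to_numpy().any():
            raise ValueError("interaction model requires >= 2 observations per cell")
    df = pd.DataFrame({"y": y})
    for name, arr in zip(names, arrays):
        df[name] = [str(v) for v in arr]
    rhs = " * ".join(f"C({n})" for n in names) if interaction and len(names) == 2 \
        else " + ".join(f"C({n})" for n in names)
    fit = smf.ols(f"y ~ {rhs}", data=df).fit()
    table = sm.stats.anova_lm(fit, typ=1)

    def _clean_name(raw: str) -> str:
        s = re.sub(r"C\((\w+)\)", r"\1", raw)
        return s.replace(":", ":")

    # scale-relative floor: a constant response yields SS that are pure
    # floating-point dust, for which F is meaningless
    ss_floor = 1e-12 * max(1.0, float(np.sum(y**2)))
    resid_ss = float(table.loc["Residual", "sum_sq"])
    terms: list[AnovaTerm] = []
    resid_df = int(table.loc["Residual", "df"])
    for raw, row in table.iterrows():
        if raw == "Residual":
            continue
        ss = float(row["sum_sq"])
        dfi = int(row["df"])
        f = float(row["F"])
        p = float(row["PR(>F)"])
        if not math.isfinite(f) or (ss < ss_floor and resid_ss < ss_floor):
            f, p = 0.0, 1.0
        terms.append(AnovaTerm(_clean_name(raw), dfi, ss, ss / dfi, f, p))
    return AnovaResult(tuple(terms), resid_df, resid_ss)


@dataclass(frozen=True)
class TukeyPair:
    pair: tuple[str, str]
    mean_diff: float
    p_adj: float


@dataclass(frozen=True)
class TukeyResult:
    pairs: tuple[TukeyPair, ...]

    def p_adj(self, a: str, b: str) -> float:
        for pr in self.pairs:
            if set(pr.pair) == {a, b}:
                return pr.p_adj
        raise KeyError((a, b))


def tukey_hsd(
    response: Sequence[float], groups: Sequence, alpha: float = 0.05
) -> TukeyResult:
    """TukeyHSD pairwise comparisons (studentized-range adjusted p-values).

    For a significant interaction, pass combined cell labels (see
    :func:`cell_labels`) to compare cell means, or subset to one factor
    level to compare within-factor slices.
    """
    y = np.asarray(response, dtype=float)
    g = np.asarray([str(v) for v in groups], dtype=object)
    keep = np.isfinite(y)
    y, g = y[keep], g[keep]
    if len(set(g)) < 2:
        raise ValueError("need at least 2 groups")
    res = pairwise_tukeyhsd(y, g, alpha=alpha)
    ii, jj = np.triu_indices(len(res.groupsunique), 1)
    pairs = tuple(
        TukeyPair(
            (str(res.groupsunique[i]), str(res.groupsunique[j])),
            float(res.meandiffs[k]),
            float(res.pvalues[k]),
        )
        for k, (i, j) in enumerate(zip(ii, jj))
    )
    return TukeyResult(pairs)


def cell_labels(f1: Sequence, f2: Sequence, sep: str = "/") -> list[str]:
    """Combine two factor label vectors into cell labels for TukeyHSD."""
    return [f"{a}{sep}{b}" for a, b in zip(f1, f2)]


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    adj_r_squared: float
    p_slope: float
    n: int


def linear_fit(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Ordinary least squares of y on x with adjusted R².

    ``adj R² = 1 − (1 − R²)(n − 1)/(n − 2)`` for the single-predictor model.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; regression undefined")
    res = stats.linregress(x, y)
    r2 = res.rvalue**2
    n = x.size
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(r2),
        adj_r_squared=float(adj),
        p_slope=float(res.pvalue),
        n=int(n),
    )


_TISSUE_SUFFIX = re.compile(r"[_-](host|symbiont)$", re.IGNORECASE)


def _default_colony(sample_id: str) -> str:
    return _TISSUE_SUFFIX.sub("", sample_id)


def host_symbiont_regressions(
    ps: ProfileSet,
    colony_of: Callable[[str], str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-fatty-acid OLS of host proportion on symbiont proportion.

    Host and symbiont rows are paired by colony: by default the trailing
    ``_host``/``_symbiont`` (or ``-host``/``-symbiont``) token of the
    sample_id is stripped; pass ``colony_of`` to override. Every host must
    have exactly one symbiont partner and vice versa, else the orphans are
    reported. One row per fatty-acid label with non-constant symbiont
    values, plus a final ``lc_mufa_sum`` row for the LC-MUFA index.
    """
    colony_of = colony_of or _default_colony
    hosts = {colony_of(p.sample_id): p for p in ps if p.tissue == "host"}
    symbionts = {colony_of(p.sample_id): p for p in ps if p.tissue == "symbiont"}
    orphans = sorted(set(hosts) ^ set(symbionts))
    if orphans:
        raise ValueError(f"unpaired colonies (host xor symbiont): {orphans}")
    if len(hosts) < 3:
        raise ValueError("need at least 3 host/symbiont pairs")
    colonies = sorted(hosts)
    rows = []

    def _fit_row(label: str, xs: np.ndarray, ys: np.ndarray) -> None:
        if np.ptp(xs) == 0:
            log.info("host_symbiont_regressions: %s skipped (constant symbiont values)", label)
            return
        r = linear_fit(xs, ys)
        rows.append(
            {
                "label": label,
                "slope": r.slope,
                "intercept": r.intercept,
                "adj_r_squared": r.adj_r_squared,
                "p_slope": r.p_slope,
                "n": r.n,
                "significant": r.p_slope < alpha,
            }
        )

    for label in ps.fa_labels:
        xs = np.asarray([symbionts[c].get(label) for c in colonies])
        ys = np.asarray([hosts[c].get(label) for c in colonies])
        if (xs == 0).all() and (ys == 0).all():
            continue
        _fit_row(label, xs, ys)
    _fit_row(
        "lc_mufa_sum",
        np.asarray([sum_lc_mufa(symbionts[c]) for c in colonies]),
        np.asarray([sum_lc_mufa(hosts[c]) for c in colonies]),
    )
    return pd.DataFrame(rows)
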