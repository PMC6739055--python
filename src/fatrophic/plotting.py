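"""Optional ordination plotting (requires matplotlib).

A thin layer: score scatter with normal-theory 95% confidence ellipses per
group. Everything quantitative lives in :mod:`fatrophic.multivariate`.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .multivariate import PCAResult


def confidence_ellipse(points: np.ndarray, level: float = 0.95) -> tuple[np.ndarray, np.ndarray, float]:
    """Center, axis half-lengths and rotation of a 2-D normal ellipse.

    The ellipse bounds the given coverage level for a bivariate normal
    fitted to the points (chi-square quantile on 2 df).
    """
    from scipy.stats import chi2

    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need an (n>=3, 2) array of scores")
    center = pts.mean(axis=0)
    cov = np.cov(pts.T)
    vals, vecs = np.linalg.eigh(cov)
    r = np.sqrt(chi2.ppf(level, df=2))
    half = r * np.sqrt(np.clip(vals, 0, None))
    angle = float(np.degrees(np.arctan2(vecs[1, -1], vecs[0, -1])))
    return center, half[::-1], angle


def plot_scores(
    result: PCAResult,
    groups: Sequence,
    ax=None,
    dims: tuple[int, int] = (0, 1),
    level: float = 0.95,
):
    """Scatter the first two component scores with per-group 95% ellipses."""
    import matplotlib.pyplot as plt
    from matplotlib.patches import Ellipse

    if ax is None:
        _, ax = plt.subplots()
    g = np.asarray(groups, dtype=object)
    i, j = dims
    for level_name in dict.fromkeys(g):
        member = g == level_name
        pts = result.scores[member][:, [i, j]]
        sc = ax.scatter(pts[:, 0], pts[:, 1], label=str(level_name), s=20)
        if member.sum() >= 3:
            center, half, angle = confidence_ellipse(pts, level)
            ax.add_patch(
                Ellipse(
                    center, 2 * half[0], 2 * half[1], angle=angle,
                    fill=False, color=sc.get_facecolor()[0],
                )
            )
    ax.set_xlabel(f"Dim{i + 1} ({result.explained_pct[i]:.1f}%)")
    ax.set_ylabel(f"Dim{j + 1} ({result.explained_pct[j]:.1f}%)")
    ax.legend(fontsize=8)
    return ax
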