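"""End-to-end orchestration: validate → multivariate → indices → univariate
→ regressions → attribution.

The pipeline mirrors the analysis order used on coral host/symbiont
fatty-acid data. Depth is tested first in the full three-factor
permutation model; when it is not significant at α the two depths are
pooled (the default ``pool_depth="auto"``; ``"always"``/``"never"``
override). Every stochastic output records the seed, and the run report
embeds a digest of the configuration so a run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import attribution as attr
from . import indices as idx
from . import multivariate as mv
from . import univariate as uv
from .io import read_profiles
from .nomenclature import LDA_PUFA_LABELS, PUFA_LABELS
from .profiles import ProfileSet

__all__ = ["RunConfig", "RunReport", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    profiles: str
    sources: str | None = None
    outdir: str = "fatrophic_out"
    metric: str = "bray_curtis"
    n_perm: int = 9999
    n_iter: int = 10000
    loocv_threshold: float = 0.85
    ridge: float | None = None
    seed: int = 0
    renormalize: bool = False
    pool_depth: str = "auto"  # auto | always | never
    alpha: float = 0.05
    category_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.metric not in ("bray_curtis", "euclidean"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.n_perm < 10:
            raise ValueError("n_perm must be >= 10")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if not 0 <= self.loocv_threshold <= 1:
            raise ValueError("loocv_threshold must be in [0, 1]")
        if self.pool_depth not in ("auto", "always", "never"):
            raise ValueError("pool_depth must be auto|always|never")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_perm < 99:
            log.warning("n_perm=%d is low; permutation p-values will be coarse", self.n_perm)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Provenance plus per-stage outputs of one pipeline run."""

    config_digest: str
    seed: int
    stages: dict[str, Any] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_digest": self.config_digest,
                "seed": self.seed,
                "stages": self.stages,
                "warnings": self.warnings,
            },
            indent=2,
            sort_keys=True,
            default=_jsonable,
        )


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _permanova_dict(res: mv.PermanovaResult) -> dict[str, Any]:
    return {
        "terms": [
            {
                "name": t.name,
                "df": t.df,
                "ss": t.ss,
                "pseudo_f": t.pseudo_f,
                "p_perm": t.p_perm,
            }
            for t in res.terms
        ],
        "residual_df": res.residual_df,
        "residual_ss": res.residual_ss,
        "n_perm": res.n_perm,
        "seed": res.seed,
    }


def _default_category(source: str) -> str:
    return "symbiont" if "symbiont" in source.lower() else "particulate"


def run_pipeline(config: RunConfig) -> RunReport:
    """Run every analysis stage on a profile table, writing outputs to disk.

    Stages: profile validation; depth test and pooling decision; crossed
    species × tissue permutation test with pairwise follow-ups and the
    dispersion check; trophic indices with per-tissue ANOVA/Tukey;
    ordination of the full panel and of the 12-PUFA subset; per-acid
    host-vs-symbiont regressions; and — when a source table is supplied —
    the bootstrap-LDA attribution per host species.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config_digest=config.digest(), seed=config.seed)

    ps = read_profiles(config.profiles, renormalize=config.renormalize)
    coral = ps.select(lambda p: p.tissue in ("host", "symbiont"))
    report.stages["validate"] = {
        "n_samples": len(ps),
        "n_coral": len(coral),
        "fa_labels": list(ps.fa_labels),
    }

    # --- depth test and pooling -------------------------------------------
    depths = {p.depth_m for p in coral if p.depth_m is not None}
    pooled = True
    if config.pool_depth == "always" or len(depths) < 2:
        report.stages["depth"] = {"tested": False, "pooled": True}
    else:
        d = mv.distance_matrix(coral, config.metric)
        factors = {
            "species": coral.factor("species"),
            "tissue": coral.factor("tissue"),
            "depth": np.asarray([f"{p.depth_m:g}" for p in coral], dtype=object),
        }
        terms = [
            "species", "tissue", "depth",
            "species:tissue", "species:depth", "tissue:depth",
            "species:tissue:depth",
        ]
        res = mv.permanova(d, factors, terms, n_perm=config.n_perm, seed=config.seed)
        p_depth = res.term("depth").p_perm
        pooled = config.pool_depth == "auto" and p_depth >= config.alpha
        if config.pool_depth == "never":
            pooled = False
        report.stages["depth"] = {
            "tested": True,
            "p_perm": p_depth,
            "pseudo_f": res.term("depth").pseudo_f,
            "pooled": pooled,
            "full_model": _permanova_dict(res),
        }

    # --- crossed species × tissue permutation tests ------------------------
    d = mv.distance_matrix(coral, config.metric)
    factors = {
        "species": coral.factor("species"),
        "tissue": coral.factor("tissue"),
    }
    if not pooled:
        factors["depth"] = np.asarray(
            [f"{p.depth_m:g}" for p in coral], dtype=object
        )
    terms = ["species", "tissue", "species:tissue"]
    if not pooled:
        terms.append("depth")
    res = mv.permanova(d, factors, terms, n_perm=config.n_perm, seed=config.seed + 1)
    report.stages["permanova"] = _permanova_dict(res)

    cell = [f"{p.species}/{p.tissue}" for p in coral]
    disp = mv.permdisp(d, cell, n_perm=config.n_perm, seed=config.seed + 2)
    report.stages["permdisp"] = {
        "f_stat": disp.f_stat,
        "p_perm": disp.p_perm,
        "dispersions": dict(disp.group_dispersions),
    }
    pw_tissue = mv.pairwise_permanova(
        d, coral.factor("tissue"), n_perm=config.n_perm, seed=config.seed + 3
    )
    pairwise = {"tissue": [(c.pair, c.pseudo_f, c.p_perm) for c in pw_tissue]}
    for tissue in ("host", "symbiont"):
        sub = coral.select(lambda p, t=tissue: p.tissue == t)
        if len({p.species for p in sub}) >= 2:
            d_sub = mv.distance_matrix(sub, config.metric)
            pw = mv.pairwise_permanova(
                d_sub, sub.factor("species"), n_perm=config.n_perm,
                seed=config.seed + 4,
            )
            pairwise[f"species_within_{tissue}"] = [
                (c.pair, c.pseudo_f, c.p_perm) for c in pw
            ]
    report.stages["pairwise_permanova"] = pairwise

    # --- indices and univariate tests --------------------------------------
    table = idx.index_table(coral)
    table.to_csv(outdir / "indices.csv", index=False)
    index_stats: dict[str, Any] = {}
    for tissue in ("host", "symbiont"):
        sub = table[table["tissue"] == tissue]
        if sub["species"].nunique() < 2:
            continue
        for col in ("ratio_18_1", "photo_animal", "lc_mufa_sum"):
            a = uv.anova(sub[col], {"species": sub["species"]})
            entry: dict[str, Any] = {
                "f": a.terms[0].f,
                "df": [a.terms[0].df, a.residual_df],
                "p": a.terms[0].p,
            }
            if a.terms[0].p < config.alpha:
                tk = uv.tukey_hsd(sub[col], sub["species"])
                entry["tukey"] = [
                    {"pair": list(pr.pair), "diff": pr.mean_diff, "p_adj": pr.p_adj}
                    for pr in tk.pairs
                ]
            index_stats[f"{tissue}:{col}"] = entry
    report.stages["indices"] = index_stats

    # --- ordination ---------------------------------------------------------
    pca_out: dict[str, Any] = {}
    for tissue in ("host", "symbiont"):
        sub = coral.select(lambda p, t=tissue: p.tissue == t)
        if len(sub) < 3:
            continue
        for tag, labels in (("all_fa", None), ("pufa", PUFA_LABELS)):
            data = sub if labels is None else sub.subset_labels(
                [l for l in labels if l in sub.fa_labels]
            )
            # constant acids (e.g. structurally absent in one tissue) carry
            # no variance and are excluded from the correlation-matrix PCA
            x = data.matrix()
            varying = x.std(axis=0, ddof=1) > 0
            if not varying.all():
                dropped = [l for l, v in zip(data.fa_labels, varying) if not v]
                report.warnings.append(f"pca {tissue}/{tag}: dropped constant {dropped}")
                data = data.subset_labels(
                    [l for l, v in zip(data.fa_labels, varying) if v]
                )
            try:
                r = mv.pca(data, standardize=True)
            except ValueError as e:
                report.warnings.append(f"pca {tissue}/{tag}: {e}")
                continue
            pca_out[f"{tissue}:{tag}"] = {
                "explained_pct": r.explained_pct[:2].tolist(),
                "top_contributors_dim1": [
                    r.variables[j]
                    for j in np.argsort(-r.contributions[:, 0])[:5]
                ],
            }
    report.stages["pca"] = pca_out

    # --- host vs symbiont regressions --------------------------------------
    try:
        reg = uv.host_symbiont_regressions(coral, alpha=config.alpha)
        reg.to_csv(outdir / "regressions.csv", index=False)
        report.stages["regressions"] = {
            "n_models": int(len(reg)),
            "n_significant": int(reg["significant"].sum()),
        }
    except ValueError as e:
        report.warnings.append(f"regressions skipped: {e}")

    # --- attribution --------------------------------------------------------
    if config.sources is not None:
        sources = read_profiles(config.sources, renormalize=config.renormalize)
        pufa = [l for l in LDA_PUFA_LABELS if l in ps.fa_labels]
        src_pufa = sources.subset_labels(pufa, renormalize=True)
        attribution_out: dict[str, Any] = {}
        host_species = sorted({p.species for p in coral if p.tissue == "host"})
        for i, species in enumerate(host_species):
            lib_groups = dict(
                attr.SourceLibrary.from_profiles(src_pufa, pufa).groups
            )
            symb = coral.select(
                lambda p, s=species: p.tissue == "symbiont" and p.species == s
            )
            if len(symb) >= 3:
                symb_pufa = symb.subset_labels(pufa, renormalize=True)
                lib_groups[f"{species}_symbiont"] = symb_pufa.matrix()
            lib = attr.SourceLibrary(lib_groups, tuple(pufa))
            rep = attr.loocv(lib, ridge=config.ridge)
            lib = attr.prune_sources(lib, rep, threshold=config.loocv_threshold)
            hosts = coral.select(
                lambda p, s=species: p.tissue == "host" and p.species == s
            ).subset_labels(pufa, renormalize=True)
            lib, hosts = attr.drop_unshared_pufa(lib, hosts)
            dist = attr.bootstrap_attribution(
                lib, hosts, n_iter=config.n_iter, ridge=config.ridge,
                seed=config.seed + 10 + i,
            )
            mapping = {
                n: config.category_map.get(n, _default_category(n))
                for n in lib.names
            }
            attribution_out[species] = {
                "loocv_rates": dict(rep.rates),
                "retained_sources": list(lib.names),
                "model_labels": list(lib.pufa_labels),
                "contributions": dist.summary().to_dict(orient="records"),
                "categories": attr.aggregate_contributions(dist, mapping).to_dict(
                    orient="records"
                ),
                "seed": dist.seed,
                "n_iter": dist.n_iter,
            }
        report.stages["attribution"] = attribution_out

    (outdir / "report.json").write_text(report.to_json())
    return report
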