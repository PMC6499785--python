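"""Study orchestration: per-site model fitting and cross-site comparison.

A study run fits the multilevel ERGM per site (base model, residual
landing-site activity screen, refit with flagged controls, and a
with/without cross-level closure comparison), classifies sites by the
pre-registered grouping rule — a site is a "closure site" when its
cross-level closure estimate is positive and exceeds twice its standard
error — and then compares ecological condition metrics between the two
site groups (one-sided) along with any declared covariates (two-sided).
Site-level failures are flagged and the study continues; the comparative
design tolerates a missing site.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .comparisons import GroupComparison, compare_site_groups, format_comparison, \
    group_ttest
from .ecology import DEFAULT_TRAIT_FIELDS, TransectRecord
from .ergm import DegeneracyError, GofReport, ModelComparison, MultilevelERGM, \
    MultilevelERGMResults, compare_models_mahalanobis
from .network import MultilevelNetwork
from .statistics import ERGMSpec, Statistic

__all__ = [
    "StudyConfig",
    "SiteAnalysis",
    "StudyReport",
    "run_site_analysis",
    "run_comparison",
]


@dataclass
class StudyConfig:
    """Pre-registered analysis settings for a whole study."""

    base_statistics: list[str] = field(
        default_factory=lambda: ["edge_density", "alt_triangle"])
    closure_statistic: str = "se_closure"
    lam: float = 2.0
    fit_options: dict = field(default_factory=dict)
    gof_sims: int = 200
    screen_sims: int = 100
    metrics: list[str] = field(default_factory=lambda: ["biomass",
                                                        "functional_richness"])
    trait_fields: tuple[str, ...] = DEFAULT_TRAIT_FIELDS
    significance_factor: float = 2.0   # |estimate| > factor * SE
    max_retries: int = 2
    seed: int = 0

    def spec(self, extra_sites: list[str] = (), with_closure: bool = True
             ) -> ERGMSpec:
        stats = [Statistic.parse(t) for t in self.base_statistics]
        stats += [Statistic("site_activity", site=a) for a in extra_sites]
        if with_closure:
            stats.append(Statistic.parse(self.closure_statistic))
        return ERGMSpec(stats)

    def hash(self) -> str:
        blob = json.dumps({k: (list(v) if isinstance(v, tuple) else v)
                           for k, v in self.__dict__.items()},
                          sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class SiteAnalysis:
    """Per-site fit artifacts (or a flagged failure)."""

    site_id: str
    fit: MultilevelERGMResults | None = None
    gof_with: GofReport | None = None
    gof_without: GofReport | None = None
    comparison: ModelComparison | None = None
    flagged_sites: list[str] = field(default_factory=list)
    failed: bool = False
    error: str = ""

    def closure_significant(self, closure_stat: str = "se_closure",
                            factor: float = 2.0) -> bool:
        if self.fit is None or closure_stat not in self.fit.params:
            return False
        est = self.fit.params[closure_stat]
        return bool(est > 0 and abs(est) > factor * self.fit.bse[closure_stat])

    def to_dict(self) -> dict:
        return {
            "site_id": self.site_id,
            "failed": self.failed,
            "error": self.error,
            "fit": None if self.fit is None else self.fit.to_dict(),
            "flagged_sites": self.flagged_sites,
            "gof_with": None if self.gof_with is None else self.gof_with.to_dict(),
            "gof_without": (None if self.gof_without is None
                            else self.gof_without.to_dict()),
            "mahalanobis": (None if self.comparison is None else {
                "with": self.comparison.distance_with,
                "without": self.comparison.distance_without,
                "preferred": self.comparison.preferred,
            }),
        }


def _site_seed(root: int, site_id: str, salt: int = 0) -> int:
    h = hashlib.sha256(f"{root}:{site_id}:{salt}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def run_site_analysis(site_id: str, net: MultilevelNetwork,
                      actors: pd.DataFrame, config: StudyConfig,
                      full_gof: bool = True) -> SiteAnalysis:
    """Fit one site end to end.

    Base fit -> residual landing-site activity screen -> refit with flagged
    site-activity controls, with and without the cross-level closure
    statistic -> goodness of fit and Mahalanobis model comparison.
    Degeneracy after the configured retries flags the site instead of
    aborting the study.
    """
    out = SiteAnalysis(site_id)

    def fit_spec(spec: ERGMSpec, salt: int) -> MultilevelERGMResults:
        last: Exception | None = None
        for attempt in range(config.max_retries + 1):
            try:
                model = MultilevelERGM(net, actors, spec)
                return model.fit(seed=_site_seed(config.seed, site_id,
                                                 salt + 97 * attempt),
                                 **config.fit_options)
            except DegeneracyError as err:
                last = err
        raise last  # type: ignore[misc]

    try:
        base = fit_spec(config.spec(with_closure=False), salt=1)
        flagged = base.residual_site_activity_screen(
            n_sim=config.screen_sims, seed=_site_seed(config.seed, site_id, 2))
        out.flagged_sites = flagged
        without = (fit_spec(config.spec(extra_sites=flagged,
                                        with_closure=False), salt=3)
                   if flagged else base)
        full = fit_spec(config.spec(extra_sites=flagged, with_closure=True),
                        salt=4)
        out.fit = full
        if full_gof:
            out.gof_with = full.gof(n_sim=config.gof_sims,
                                    seed=_site_seed(config.seed, site_id, 5))
            out.gof_without = without.gof(n_sim=config.gof_sims,
                                          seed=_site_seed(config.seed, site_id, 6))
            out.comparison = compare_models_mahalanobis(out.gof_with,
                                                        out.gof_without)
    except DegeneracyError as err:
        out.failed = True
        out.error = str(err)
    return out


@dataclass
class StudyReport:
    """Cross-site comparison results plus provenance."""

    closure_sites: list[str]
    non_closure_sites: list[str]
    metric_comparisons: dict[str, GroupComparison]
    covariate_comparisons: dict[str, GroupComparison]
    site_analyses: dict[str, SiteAnalysis] = field(default_factory=dict)
    not_applicable: bool = False
    provenance: dict = field(default_factory=dict)

    def render_text(self) -> str:
        lines = [
            f"closure sites:     {', '.join(self.closure_sites) or '(none)'}",
            f"non-closure sites: {', '.join(self.non_closure_sites) or '(none)'}",
        ]
        if self.not_applicable:
            lines.append("comparisons not applicable: one group is empty")
            return "\n".join(lines)
        lines.append("\necological condition (one-sided, closure > non-closure):")
        for name, gc in self.metric_comparisons.items():
            lines.append("  " + format_comparison(name, gc))
        if self.covariate_comparisons:
            lines.append("\ncovariates (two-sided):")
            for name, gc in self.covariate_comparisons.items():
                lines.append("  " + format_comparison(name, gc))
        return "\n".join(lines)

    def to_dict(self) -> dict:
        def gc_dict(gc: GroupComparison) -> dict:
            return {
                "n1": gc.group1.n, "mean1": gc.group1.mean, "sd1": gc.group1.sd,
                "n2": gc.group2.n, "mean2": gc.group2.mean, "sd2": gc.group2.sd,
                "t": gc.t, "df": gc.df, "p": gc.p, "variant": gc.variant,
                "sidedness": gc.sidedness, "cohens_d": gc.cohens_d,
                "d_ci": list(gc.d_ci), "ci_level": gc.ci_level,
            }
        return {
            "closure_sites": self.closure_sites,
            "non_closure_sites": self.non_closure_sites,
            "not_applicable": self.not_applicable,
            "metric_comparisons": {k: gc_dict(v)
                                   for k, v in self.metric_comparisons.items()},
            "covariate_comparisons": {k: gc_dict(v) for k, v in
                                      self.covariate_comparisons.items()},
            "sites": {k: v.to_dict() for k, v in self.site_analyses.items()},
            "provenance": self.provenance,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2,
                                         sort_keys=True))


def run_comparison(config: StudyConfig,
                   site_analyses: dict[str, SiteAnalysis],
                   transects_by_site: dict[str, list[TransectRecord]],
                   traits: pd.DataFrame,
                   covariate_summaries: pd.DataFrame | None = None
                   ) -> StudyReport:
    """Group sites by the pre-registered closure rule and compare groups.

    ``covariate_summaries`` rows (columns ``metric, n1, mean1, sd1, n2,
    mean2, sd2, variant``) are recomputed with two-sided tests; the
    ecological metrics use raw transect values and one-sided tests.
    """
    closure, non_closure = [], []
    for site_id, an in site_analyses.items():
        if an.failed:
            continue
        (closure if an.closure_significant(config.closure_statistic,
                                           config.significance_factor)
         else non_closure).append(site_id)
    report = StudyReport(sorted(closure), sorted(non_closure), {}, {},
                         site_analyses=site_analyses)
    report.provenance = {"config_hash": config.hash(), "seed": config.seed,
                         "grouping_rule":
                             f"closure estimate > 0 and |estimate| > "
                             f"{config.significance_factor} * SE"}
    if not closure or not non_closure:
        report.not_applicable = True
        return report
    usable = {s: t for s, t in transects_by_site.items()
              if s in closure or s in non_closure}
    for metric in config.metrics:
        report.metric_comparisons[metric] = compare_site_groups(
            usable, set(closure), metric, traits,
            trait_fields=config.trait_fields, sidedness="greater")
    if covariate_summaries is not None:
        for row in covariate_summaries.itertuples():
            gc = group_ttest((row.n1, row.mean1, row.sd1),
                             (row.n2, row.mean2, row.sd2),
                             variant=row.variant, sidedness="two-sided")
            report.covariate_comparisons[row.metric] = gc
    return report
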