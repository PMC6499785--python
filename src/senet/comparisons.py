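"""Two-sample group comparisons: t tests, effect sizes, variance/rank tests.

These back the between-group analyses of the study pipeline: ecological
condition metrics (one-sided, closure group > non-closure group),
environmental/human-impact covariates (two-sided), variance comparisons of
survey responses (Levene), and rank comparisons of ordinal scales
(Mann-Whitney U).  Every operation accepts either raw samples or
``(n, mean, sd)`` summary triples, so published summary tables can be
recomputed directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy import stats as sps

from .ecology import (DEFAULT_TRAIT_FIELDS, TransectRecord, estimate_biomass,
                      functional_richness)

__all__ = [
    "GroupSummary",
    "GroupComparison",
    "VarianceTest",
    "RankTest",
    "group_ttest",
    "cohens_d",
    "levene_test",
    "mann_whitney_u",
    "compare_site_groups",
    "format_comparison",
]

SIDEDNESS = ("two-sided", "greater", "less")


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float
    sd: float


@dataclass
class GroupComparison:
    """Two-sample t test with effect size.

    ``df`` is the integer pooled value ``n1+n2-2`` or the fractional
    Satterthwaite approximation under the unequal-variance (Welch) variant.
    ``cohens_d`` always uses the pooled (n-1)-weighted standard deviation;
    its confidence interval comes from noncentral-t inversion.
    """

    group1: GroupSummary
    group2: GroupSummary
    t: float
    df: float
    p: float
    variant: str            # "pooled" | "welch"
    sidedness: str
    cohens_d: float
    d_ci: tuple[float, float]
    ci_level: float
    note: str = ""


@dataclass
class VarianceTest:
    W: float
    df: tuple[int, int]
    p: float


@dataclass
class RankTest:
    U: float
    p: float
    method: str
    n1: int
    n2: int


def _summarize(x) -> tuple[GroupSummary, np.ndarray | None]:
    """Accept a raw sample (array-like) or an ``(n, mean, sd)`` triple."""
    if isinstance(x, GroupSummary):
        return x, None
    if isinstance(x, tuple) and len(x) == 3 and np.isscalar(x[0]):
        n, mean, sd = x
        return GroupSummary(int(n), float(mean), float(sd)), None
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("sample must be a nonempty 1-d array or (n, mean, sd)")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return GroupSummary(arr.size, float(arr.mean()), sd), arr


def _pooled_sd(g1: GroupSummary, g2: GroupSummary) -> float:
    dof = g1.n + g2.n - 2
    if dof <= 0:
        return float("nan")
    return math.sqrt(((g1.n - 1) * g1.sd ** 2 + (g2.n - 1) * g2.sd ** 2) / dof)


def _satterthwaite_df(g1: GroupSummary, g2: GroupSummary) -> float:
    v1, v2 = g1.sd ** 2 / g1.n, g2.sd ** 2 / g2.n
    num = (v1 + v2) ** 2
    den = 0.0
    if v1 > 0:
        den += v1 ** 2 / (g1.n - 1)
    if v2 > 0:
        den += v2 ** 2 / (g2.n - 1)
    if den == 0:
        return float(g1.n + g2.n - 2)
    return num / den


def _pvalue(t: float, df: float, sidedness: str) -> float:
    if sidedness == "two-sided":
        return 2 * sps.t.sf(abs(t), df)
    if sidedness == "greater":
        return sps.t.sf(t, df)
    return sps.t.cdf(t, df)


def cohens_d(x1, x2, ci_level: float = 0.90) -> tuple[float, tuple[float, float]]:
    """Standardized mean difference with a noncentral-t confidence interval.

    ``D = (mean1 - mean2) / s_pooled`` with the (n-1)-weighted pooled SD.
    The CI inverts the noncentral-t distribution of ``D * sqrt(n~)`` with
    ``n~ = n1 n2/(n1+n2)`` and ``df = n1+n2-2``.
    """
    g1, _ = _summarize(x1)
    g2, _ = _summarize(x2)
    sp = _pooled_sd(g1, g2)
    if not sp > 0:
        return float("nan"), (float("nan"), float("nan"))
    d = (g1.mean - g2.mean) / sp
    df = g1.n + g2.n - 2
    ntilde = g1.n * g2.n / (g1.n + g2.n)
    tval = d * math.sqrt(ntilde)
    alpha = 1 - ci_level

    def solve(q: float) -> float:
        # nct.cdf(tval; df, delta) is decreasing in delta
        f = lambda delta: sps.nct.cdf(tval, df, delta) - q
        lo, hi = tval - 2, tval + 2
        while f(lo) < 0:
            lo -= 5
        while f(hi) > 0:
            hi += 5
        return optimize.brentq(f, lo, hi, xtol=1e-8)

    delta_lo = solve(1 - alpha / 2)
    delta_hi = solve(alpha / 2)
    return d, (delta_lo / math.sqrt(ntilde), delta_hi / math.sqrt(ntilde))


def group_ttest(x1, x2, variant: str = "auto", sidedness: str = "two-sided",
                ci_level: float = 0.90, levene_alpha: float = 0.05) -> GroupComparison:
    """Two-sample t test (pooled or Welch/Satterthwaite) with Cohen's D.

    ``variant="auto"`` (raw samples only) runs Levene's test first and uses
    the pooled statistic when variances are not significantly unequal at
    ``levene_alpha``, Welch otherwise.  Summary-statistic inputs require an
    explicit variant.
    """
    if sidedness not in SIDEDNESS:
        raise ValueError(f"sidedness must be one of {SIDEDNESS}")
    g1, raw1 = _summarize(x1)
    g2, raw2 = _summarize(x2)
    note = ""
    if variant == "auto":
        if raw1 is None or raw2 is None:
            raise ValueError("variant='auto' needs raw samples (Levene screen); "
                             "pass variant='pooled' or 'welch' for summaries")
        lev = levene_test([raw1, raw2], center="mean")
        variant = "pooled" if lev.p >= levene_alpha else "welch"
        note = f"variant chosen by Levene p={lev.p:.3f}"
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    min_n = 2 if variant == "pooled" else 1
    for g in (g1, g2):
        if g.n < min_n:
            raise ValueError(f"group size {g.n} too small for {variant} test")
        if g.n == 1 and g.sd != 0:
            raise ValueError("n=1 group must have sd 0")

    diff = g1.mean - g2.mean
    if variant == "pooled":
        sp = _pooled_sd(g1, g2)
        denom = sp * math.sqrt(1 / g1.n + 1 / g2.n)
        df: float = g1.n + g2.n - 2
    else:
        denom = math.sqrt(g1.sd ** 2 / g1.n + g2.sd ** 2 / g2.n)
        df = _satterthwaite_df(g1, g2)
    if denom == 0:
        t = float("nan")
        p = float("nan")
        note = (note + "; " if note else "") + \
            "t undefined: zero variance in both groups" + \
            ("" if diff == 0 else " with unequal means")
    else:
        t = diff / denom
        p = _pvalue(t, df, sidedness)
    d, ci = cohens_d((g1.n, g1.mean, g1.sd), (g2.n, g2.mean, g2.sd), ci_level)
    return GroupComparison(g1, g2, t, df, p, variant, sidedness, d, ci,
                           ci_level, note)


def levene_test(groups: list, center: str = "mean") -> VarianceTest:
    """Levene's test for equality of variances across >= 2 groups.

    One-way ANOVA F on absolute deviations from the group center
    (``mean`` default; ``median`` gives the Brown-Forsythe variant).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    for g in arrs:
        if g.size < 2:
            raise ValueError("every group needs n >= 2")
    W, p = sps.levene(*arrs, center=center)
    N = sum(g.size for g in arrs)
    return VarianceTest(float(W), (len(arrs) - 1, N - len(arrs)), float(p))


def mann_whitney_u(x1, x2, alternative: str = "two-sided",
                   exact_max_product: int = 400) -> RankTest:
    """Mann-Whitney U from rank sums (midranks for ties).

    Uses exact enumeration when ``n1*n2 <= exact_max_product`` and there are
    no ties, otherwise the normal approximation with tie correction.
    """
    a1 = np.asarray(x1, dtype=float)
    a2 = np.asarray(x2, dtype=float)
    if a1.size == 0 or a2.size == 0:
        raise ValueError("samples must be nonempty")
    has_ties = len(np.unique(np.concatenate([a1, a2]))) < a1.size + a2.size
    method = ("exact" if a1.size * a2.size <= exact_max_product and not has_ties
              else "asymptotic")
    res = sps.mannwhitneyu(a1, a2, alternative=alternative, method=method)
    return RankTest(float(res.statistic), float(res.pvalue), method,
                    a1.size, a2.size)


def compare_site_groups(transects_by_site: dict[str, list[TransectRecord]],
                        closure_sites: set[str], metric: str, traits,
                        trait_fields: tuple[str, ...] = DEFAULT_TRAIT_FIELDS,
                        sidedness: str = "greater",
                        variant: str = "auto",
                        ci_level: float = 0.90) -> GroupComparison:
    """Compare a per-transect metric between closure and non-closure sites.

    Transects are pooled within each group; the default alternative is
    one-sided (closure group mean greater), matching the directional
    hypothesis that closure supports better ecological conditions.
    """
    metrics = {
        "biomass": lambda t: estimate_biomass(t, traits),
        "functional_richness": lambda t: float(
            functional_richness(t, traits, trait_fields)),
    }
    if metric not in metrics:
        raise KeyError(f"unknown metric {metric!r}; choose from {sorted(metrics)}")
    with_vals, without_vals = [], []
    for site, transects in transects_by_site.items():
        target = with_vals if site in closure_sites else without_vals
        target.extend(metrics[metric](t) for t in transects)
    if not with_vals or not without_vals:
        raise ValueError("both site groups must be nonempty")
    return group_ttest(np.array(with_vals), np.array(without_vals),
                       variant=variant, sidedness=sidedness, ci_level=ci_level)


def format_comparison(name: str, gc: GroupComparison) -> str:
    """One table row in the style ``n; mean (sd) | t(df) = t, p | D [CI]``."""
    g1, g2 = gc.group1, gc.group2
    df = f"{gc.df:.0f}" if float(gc.df).is_integer() else f"{gc.df:.1f}"
    lo, hi = gc.d_ci
    return (f"{name:<22} n={g1.n}; {g1.mean:.2f} ({g1.sd:.2f}) | "
            f"n={g2.n}; {g2.mean:.2f} ({g2.sd:.2f}) | "
            f"t({df}) = {gc.t:.2f}, {gc.p:.2f} | "
            f"{gc.cohens_d:.2f} [{lo:.2f}, {hi:.2f}]")
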