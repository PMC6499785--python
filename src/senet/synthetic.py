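"""Synthetic study-site generator with known ground truth.

Emulates the empirical design this package analyzes: five reef-fishery
communities of 71-232 fishers each, 3-5 gear types with overlapping target
sets drawn from a pool of 36 species, social networks with mean degree in
the 1.5-3.5 range, and replicate 500 m^2 visual-census transects whose
biomass stays below the 1200 kg/ha pristine reference.  Social networks are
drawn from the multilevel ERGM itself at a declared parameter vector
``theta*`` (the cross-level closure effect is injected through ``theta*``,
never by post-hoc rewiring), so estimation recovery is a fair test.  The
baseline edge parameter is calibrated by single-parameter stochastic
approximation to hit each site's declared mean degree.

Seeding: one root seed spawns per-site seeds, and each site seed spawns
per-stage seeds (actors, traits, catalog, network, transects) through
``numpy.random.SeedSequence``, so every stage regenerates bit-identically
and independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import _engine
from .build import GearCatalog, TrophicRuleSet, build_crosslevel_ties, \
    infer_trophic_web, assemble_multilevel
from .ecology import Observation, TransectRecord
from .ergm import DegeneracyError, MultilevelERGM
from .network import MultilevelNetwork
from .statistics import ERGMSpec, Statistic, statistics_from_adjacency

__all__ = [
    "EcoEffect",
    "SiteScenario",
    "SiteData",
    "SyntheticStudy",
    "StudyDesign",
    "gen_actors",
    "gen_gear_catalog",
    "gen_species_traits",
    "gen_site",
    "gen_transects",
    "gen_study",
    "default_study_design",
    "GEARS",
]

GEARS = ("hook_line", "gillnet", "seine", "spear", "trap")
DIETS = ("piscivore", "invertivore", "herbivore", "planktivore",
         "corallivore", "omnivore")
MOBILITY = ("sedentary", "mobile", "highly_mobile")
HABITATS = ("reef_flat", "reef_slope", "lagoon")

N_FISHER_RANGE = (71, 232)
PRISTINE_BIOMASS_KG_HA = 1200.0
MEAN_DEGREE_RANGE = (1.52, 3.49)


@dataclass(frozen=True)
class EcoEffect:
    """Declared per-transect distribution targets for one site group."""

    biomass_mean: float
    biomass_sd: float
    richness_mean: float
    richness_sd: float


@dataclass
class SiteScenario:
    """Ground-truth configuration of one synthetic site."""

    site_id: str
    n_fishers: int
    seed: int
    gear_probs: dict[str, float] = field(
        default_factory=lambda: {g: p for g, p in
                                 zip(GEARS, (0.3, 0.2, 0.2, 0.15, 0.15))})
    n_landing_sites: int = 2
    leader_fraction: float = 0.08
    n_species: int = 36
    gear_overlap: float = 0.5
    target_mean_degree: float = 2.5
    closure_effect: float = 0.15       # theta* on se_closure
    alt_triangle_effect: float = 0.2   # theta* on alt_triangle
    lam: float = 2.0
    eco: EcoEffect = field(default_factory=lambda: EcoEffect(610.0, 185.0,
                                                             24.0, 3.2))
    n_transects: int = 4
    trust_mean: float = 3.9
    trust_sd: float = 0.95
    perception_probs: tuple[float, float, float] = (0.86, 0.10, 0.04)
    participation_probs: tuple[float, float, float, float] = (0.40, 0.45,
                                                              0.12, 0.03)
    fishing_primary_p: float = 0.90

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        total = sum(self.gear_probs.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"gear probabilities sum to {total}, not 1")
        if any(p < 0 for p in self.gear_probs.values()):
            raise ValueError("negative gear probability")
        if not (N_FISHER_RANGE[0] <= self.n_fishers <= N_FISHER_RANGE[1]):
            raise ValueError(
                f"n_fishers {self.n_fishers} outside {N_FISHER_RANGE}")
        if self.eco.biomass_sd <= 0 or self.eco.richness_sd <= 0:
            raise ValueError("eco effect sds must be positive")

    @property
    def has_closure_effect(self) -> bool:
        return self.closure_effect > 0


@dataclass
class SiteData:
    """Everything generated for one site, plus realized statistics."""

    scenario: SiteScenario
    network: MultilevelNetwork
    actors: pd.DataFrame
    transects: list[TransectRecord]
    theta_star: dict[str, float]
    realized: dict[str, float]


@dataclass
class SyntheticStudy:
    sites: list[SiteData]
    traits: pd.DataFrame
    catalog: GearCatalog
    ledger: dict
    seed: int

    def transects_by_site(self) -> dict[str, list[TransectRecord]]:
        return {s.scenario.site_id: s.transects for s in self.sites}

    def closure_sites_true(self) -> set[str]:
        return {s.scenario.site_id for s in self.sites
                if s.scenario.has_closure_effect}

    def ledger_json(self) -> str:
        return json.dumps(self.ledger, indent=2, sort_keys=True)


def _stage_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.Generator(np.random.PCG64(s))
            for s in np.random.SeedSequence(seed).spawn(n)]


def gen_actors(scenario: SiteScenario, rng: np.random.Generator | None = None
               ) -> pd.DataFrame:
    """Per-fisher attribute table with gear, landing site, leader flag,
    community, and survey-response fields."""
    if rng is None:
        rng = _stage_rngs(scenario.seed, 5)[0]
    n = scenario.n_fishers
    gears = sorted(scenario.gear_probs)
    probs = np.array([scenario.gear_probs[g] for g in gears])
    gear = rng.choice(gears, size=n, p=probs)
    landing = rng.integers(0, scenario.n_landing_sites, size=n)
    leader = rng.random(n) < scenario.leader_fraction
    trust = np.clip(np.rint(rng.normal(scenario.trust_mean, scenario.trust_sd,
                                       size=n)), 1, 5).astype(int)
    perception = rng.choice([-1, 0, 1], size=n, p=scenario.perception_probs)
    participation = rng.choice([0, 1, 2, 3], size=n,
                               p=scenario.participation_probs)
    fishing_primary = rng.random(n) < scenario.fishing_primary_p
    return pd.DataFrame({
        "id": [f"{scenario.site_id}_f{i:03d}" for i in range(n)],
        "gear": gear,
        "landing_site": [f"{scenario.site_id}_ls{c}" for c in landing],
        "leader": leader,
        "community": scenario.site_id,
        "trust": trust,
        "perception": perception,
        "participation": participation,
        "fishing_primary": fishing_primary,
    })


def gen_gear_catalog(n_species: int, n_gears: int, overlap: float,
                     rng: np.random.Generator | None = None,
                     species_ids: list[str] | None = None) -> GearCatalog:
    """Gear target sets with a shared core plus gear-specific species.

    ``overlap`` in [0, 1] sets the shared-core fraction of each gear's
    target set: 0 gives disjoint sets, 1 identical sets, and pairwise
    Jaccard similarity increases monotonically in between.
    """
    if n_gears < 1:
        raise ValueError("need at least one gear")
    if not 0 <= overlap <= 1:
        raise ValueError("overlap must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(0)
    if species_ids is None:
        species_ids = [f"s{u:02d}" for u in range(1, n_species + 1)]
    # largest per-gear set size k with core c = round(overlap*k) that fits
    for k in range(n_species, 0, -1):
        c = int(round(overlap * k))
        if c + n_gears * (k - c) <= n_species:
            break
    pool = list(species_ids)
    rng.shuffle(pool)
    core = set(pool[:c])
    rest = pool[c:]
    targets: dict[str, set[str]] = {}
    for g in range(n_gears):
        extra = set(rest[g * (k - c):(g + 1) * (k - c)])
        targets[GEARS[g] if g < len(GEARS) else f"gear{g}"] = core | extra
    return GearCatalog(targets)


def gen_species_traits(n_species: int = 36,
                       rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Species trait table with length-weight coefficients.

    Trait tuples (diet, size_class, mobility) are sampled without
    replacement from the combination space, so every species is its own
    functional entity and the functional richness of a sample equals its
    species count.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    size_edges = np.array([0, 10, 20, 30, 40, 60, 80, 120])
    combos = [(d, sc, mb) for d in DIETS
              for sc in range(len(size_edges) - 1) for mb in MOBILITY]
    if n_species > len(combos):
        raise ValueError(f"at most {len(combos)} unique trait combinations")
    idx = rng.choice(len(combos), size=n_species, replace=False)
    rows = []
    for u, ci in enumerate(idx, start=1):
        diet, sc, mb = combos[ci]
        lo, hi = size_edges[sc], size_edges[sc + 1]
        size = float(rng.uniform(lo + 1, hi))
        rows.append({
            "species": f"s{u:02d}",
            "diet": diet,
            "size_cm": round(size, 1),
            "size_class": f"{lo}-{hi}cm",
            "mobility": mb,
            "habitat": str(rng.choice(HABITATS)),
            "lw_a": round(float(rng.uniform(0.008, 0.03)), 4),
            "lw_b": round(float(rng.uniform(2.9, 3.1)), 3),
        })
    return pd.DataFrame(rows)


def _calibrate_edge_parameter(model: MultilevelERGM, theta: np.ndarray,
                              edge_idx: int, target_edges: float,
                              seed: int, n_iter: int = 150) -> np.ndarray:
    """Tune the edge parameter by Robbins-Monro so the simulated edge count
    matches the target, holding the other parameters fixed."""
    e = model.encoded
    _engine.seed(seed % (2 ** 31))
    A = np.zeros_like(model.network.A)
    deg = A.sum(axis=1).astype(np.int64)
    z = statistics_from_adjacency(A, e)
    steps = model.n_dyads
    scale = max(target_edges, 1.0)
    history = []
    th = theta.copy()
    _engine.run_chain(A, deg, th, e.kinds, e.lams, e.asite, e.leader,
                      e.site, e.m, 10 * model.n_dyads, z)
    for r in range(n_iter):
        _engine.run_chain(A, deg, th, e.kinds, e.lams, e.asite, e.leader,
                          e.site, e.m, steps, z)
        a = 4.0 / (r + 8.0)
        th[edge_idx] -= np.clip(a * (z[edge_idx] - target_edges) / scale,
                                -0.5, 0.5)
        history.append(th[edge_idx])
    th[edge_idx] = float(np.mean(history[n_iter // 2:]))
    return th


def gen_site(scenario: SiteScenario,
             traits: pd.DataFrame | None = None,
             catalog: GearCatalog | None = None,
             rules: TrophicRuleSet | None = None
             ) -> SiteData:
    """Generate one site: actors, X from gear, B from traits, and a social
    network drawn from the multilevel ERGM at the scenario's ``theta*``."""
    rng_actors, rng_traits, rng_cat, rng_net, _ = _stage_rngs(scenario.seed, 5)
    actors = gen_actors(scenario, rng_actors)
    if traits is None:
        traits = gen_species_traits(scenario.n_species, rng_traits)
    if catalog is None:
        catalog = gen_gear_catalog(scenario.n_species, len(GEARS),
                                   scenario.gear_overlap, rng_cat,
                                   species_ids=traits["species"].tolist())
    species = traits["species"].tolist()
    X = build_crosslevel_ties(actors, catalog, species)
    B = infer_trophic_web(traits, rules or TrophicRuleSet())
    n = scenario.n_fishers
    empty_A = np.zeros((n, n), dtype=np.int8)
    net0 = assemble_multilevel(empty_A, B, X, actors, species)

    spec = ERGMSpec([
        Statistic("edge_density"),
        Statistic("alt_triangle", lam=scenario.lam),
        Statistic("se_closure"),
    ])
    model = MultilevelERGM(net0, actors, spec)
    target_edges = scenario.target_mean_degree * n / 2.0
    p0 = min(max(target_edges / model.n_dyads, 1e-6), 1 - 1e-6)
    theta = np.array([np.log(p0 / (1 - p0)),
                      scenario.alt_triangle_effect,
                      scenario.closure_effect])
    cal_seed = int(np.random.SeedSequence(scenario.seed).generate_state(2)[1])
    theta = _calibrate_edge_parameter(model, theta, 0, target_edges, cal_seed)

    Z, nets = model.simulate(theta, n_samples=1, burn_in=20 * model.n_dyads,
                             thinning=1,
                             seed=int(rng_net.integers(2 ** 31)),
                             start=empty_A, return_networks=True)
    A = nets[0]
    edges = int(A.sum()) // 2
    if edges == 0 or edges == model.n_dyads:
        raise DegeneracyError(
            f"site {scenario.site_id}: generated network degenerate "
            f"({edges} edges)", [theta.tolist()])
    net = assemble_multilevel(A, B, X, actors, species)
    theta_star = dict(zip(spec.names, theta.tolist()))
    realized = {
        "edges": float(edges),
        "mean_degree": 2.0 * edges / n,
        "density": edges / model.n_dyads,
        "alt_triangle": float(Z[0, 1]),
        "se_closure": float(Z[0, 2]),
    }
    transects = gen_transects(scenario, traits)
    return SiteData(scenario, net, actors, transects, theta_star, realized)


def gen_transects(scenario: SiteScenario, traits: pd.DataFrame,
                  rng: np.random.Generator | None = None
                  ) -> list[TransectRecord]:
    """Replicate transects hitting the scenario's declared biomass and
    functional-richness distributions.

    Per transect: a species-count target and a biomass target are drawn
    from the declared normals (biomass truncated below the pristine
    reference), relative abundances are lognormal and lengths gamma, and
    lengths are then rescaled so the realized biomass matches the target.
    """
    if rng is None:
        rng = _stage_rngs(scenario.seed, 5)[4]
    eco = scenario.eco
    tb = traits.set_index("species")
    species = traits["species"].tolist()
    out: list[TransectRecord] = []
    area = 500.0
    for t in range(scenario.n_transects):
        k = int(np.clip(np.rint(rng.normal(eco.richness_mean, eco.richness_sd)),
                        1, len(species)))
        target = float(np.clip(rng.normal(eco.biomass_mean, eco.biomass_sd),
                               30.0, PRISTINE_BIOMASS_KG_HA - 20.0))
        chosen = list(rng.choice(species, size=k, replace=False))
        weights = rng.lognormal(mean=0.0, sigma=0.8, size=k)
        lengths = np.empty(k)
        masses = np.empty(k)
        for s, sp in enumerate(chosen):
            max_len = float(tb.at[sp, "size_cm"])
            mean_len = 0.45 * max_len
            shape = 9.0
            lengths[s] = min(float(rng.gamma(shape, mean_len / shape)),
                             max_len)
            lengths[s] = max(lengths[s], 0.15 * max_len)
        target_grams = target * area / 10.0
        a = tb.loc[chosen, "lw_a"].to_numpy(dtype=float)
        b = tb.loc[chosen, "lw_b"].to_numpy(dtype=float)
        masses = a * lengths ** b
        counts = np.maximum(1, np.rint(
            weights * target_grams / (weights * masses).sum())).astype(int)
        # rescale lengths so integer counts still meet the biomass target
        for _ in range(6):
            grams = (counts * a * lengths ** b).sum()
            factor = (target_grams / grams) ** (1.0 / b.mean())
            lengths = lengths * factor
        obs = [Observation(sp, int(c), round(float(l), 2))
               for sp, c, l in zip(chosen, counts, lengths)]
        out.append(TransectRecord(scenario.site_id,
                                  f"{scenario.site_id}_t{t + 1}", area, obs))
    return out


@dataclass
class StudyDesign:
    """Configuration of a whole synthetic study."""

    scenarios: list[SiteScenario]
    seed: int

    def __post_init__(self) -> None:
        if len(self.scenarios) < 2:
            raise ValueError("a study needs at least two sites")
        has = [s.has_closure_effect for s in self.scenarios]
        if not (any(has) and not all(has)):
            raise ValueError("need at least one site with and one without "
                             "a true closure effect")


#: Default group-level transect targets: closure group emulates higher
#: biomass/richness with standardized differences near 0.9 and 1.55.
CLOSURE_ECO = EcoEffect(610.0, 185.0, 24.0, 3.2)
NULL_ECO = EcoEffect(445.0, 185.0, 19.0, 3.2)


def default_study_design(seed: int) -> StudyDesign:
    """Five-site design: three sites with a true cross-level closure effect
    (theta*_closure = 0.15) and two without; fisher counts inside 71-232 and
    mean-degree targets inside 1.52-3.49."""
    site_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                  for s in np.random.SeedSequence(seed).spawn(5)]
    spec = [
        ("A", 87, 2.6, 3, 0.15, CLOSURE_ECO, 0.95),
        ("B", 71, 1.9, 2, 0.15, CLOSURE_ECO, 0.95),
        ("C", 103, 3.1, 3, 0.15, CLOSURE_ECO, 0.95),
        ("D", 76, 2.1, 2, 0.0, NULL_ECO, 1.15),
        ("E", 95, 2.8, 2, 0.0, NULL_ECO, 1.15),
    ]
    scenarios = [
        SiteScenario(site_id=sid, n_fishers=n, seed=s,
                     target_mean_degree=md, n_landing_sites=nls,
                     closure_effect=ce, eco=eco, trust_sd=tsd)
        for (sid, n, md, nls, ce, eco, tsd), s in zip(spec, site_seeds)
    ]
    return StudyDesign(scenarios, seed)


def gen_study(design: StudyDesign | int) -> SyntheticStudy:
    """Generate a full study (shared species pool and gear catalog across
    sites) with a ground-truth ledger of every theta* and effect target."""
    if isinstance(design, int):
        design = default_study_design(design)
    root = np.random.SeedSequence(design.seed)
    shared_traits_rng, shared_cat_rng = (
        np.random.Generator(np.random.PCG64(s)) for s in root.spawn(2))
    n_species = design.scenarios[0].n_species
    traits = gen_species_traits(n_species, shared_traits_rng)
    catalog = gen_gear_catalog(n_species, len(GEARS),
                               design.scenarios[0].gear_overlap,
                               shared_cat_rng,
                               species_ids=traits["species"].tolist())
    sites = [gen_site(sc, traits=traits, catalog=catalog)
             for sc in design.scenarios]
    ledger = {
        "seed": design.seed,
        "sites": {
            s.scenario.site_id: {
                "seed": s.scenario.seed,
                "n_fishers": s.scenario.n_fishers,
                "theta_star": s.theta_star,
                "closure_effect": s.scenario.closure_effect,
                "target_mean_degree": s.scenario.target_mean_degree,
                "eco_targets": asdict(s.scenario.eco),
                "realized": s.realized,
            } for s in sites
        },
    }
    return SyntheticStudy(sites, traits, catalog, ledger, design.seed)
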