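"""Configuration statistics for the multilevel ERGM.

The model's sufficient statistics are counts of local configurations in the
social network ``A``, some bound to actor attributes, plus one cross-level
statistic: the closed social-ecological triangle (two actors tied to the
same species who also share a social tie).  For a statistic vector ``z`` and
parameters ``theta`` the model is the exponential family
``P(A) ∝ exp(theta · z(A))`` with ``X`` and ``B`` held fixed.

Registry (``name`` is the key used in specs, configs and the CLI):

==================  ========================================================
``edge_density``    number of social ties (baseline density parameter)
``two_star``        S2 = sum_i C(d_i, 2)
``alt_star``        alternating k-star (ASA), decay ``lam`` > 1
``alt_triangle``    alternating triangle (ATA), decay ``lam`` > 1
``leader_activity`` sum over ties of the endpoints' leader flags
``site_homophily``  ties whose endpoints share a landing site
``site_activity``   tie-ends incident to actors of one landing site ``a``
``se_closure``      closed cross-level triangles: sum over ties of the
                    number of species both endpoints harvest
==================  ========================================================

The alternating star uses the degree form
``lam^2 * sum_i [(1-1/lam)^d_i - 1 + d_i/lam]`` (equal to the alternating
sum ``S2 - S3/lam + S4/lam^2 - ...``); the alternating triangle is
``lam * sum_{ties ij} [1 - (1-1/lam)^{P_ij}]`` with ``P_ij`` the number of
two-paths between i and j.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _engine
from .network import MultilevelNetwork

__all__ = [
    "Statistic",
    "ERGMSpec",
    "EncodedModel",
    "global_statistics",
    "change_statistic",
    "se_closure_count",
    "DEFAULT_LAMBDA",
]

DEFAULT_LAMBDA = 2.0

KIND_CODES = {
    "edge_density": 0,
    "two_star": 1,
    "alt_star": 2,
    "alt_triangle": 3,
    "leader_activity": 4,
    "site_homophily": 5,
    "site_activity": 6,
    "se_closure": 7,
}

_ATTRIBUTE_KINDS = {"leader_activity": "leader",
                    "site_homophily": "landing_site",
                    "site_activity": "landing_site"}


@dataclass(frozen=True)
class Statistic:
    """One configuration statistic descriptor."""

    kind: str
    lam: float = DEFAULT_LAMBDA
    site: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in KIND_CODES:
            raise ValueError(f"unknown statistic {self.kind!r}")
        if self.kind in ("alt_star", "alt_triangle") and not self.lam > 1:
            raise ValueError(f"{self.kind}: decay lambda must be > 1, got {self.lam}")
        if self.kind == "site_activity" and self.site is None:
            raise ValueError("site_activity requires a landing-site label")

    @property
    def name(self) -> str:
        if self.kind == "site_activity":
            return f"site_activity({self.site})"
        if self.kind in ("alt_star", "alt_triangle") and self.lam != DEFAULT_LAMBDA:
            return f"{self.kind}({self.lam:g})"
        return self.kind

    @classmethod
    def parse(cls, token: str) -> "Statistic":
        """Parse ``"name"``, ``"name:lam"`` or ``"site_activity:label"``."""
        kind, _, arg = token.strip().partition(":")
        if kind == "site_activity":
            return cls(kind, site=arg or None)
        if arg:
            return cls(kind, lam=float(arg))
        return cls(kind)


@dataclass
class ERGMSpec:
    """Ordered list of statistics defining one model."""

    statistics: list[Statistic]

    def __post_init__(self) -> None:
        names = [s.name for s in self.statistics]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate statistic names in spec: {names}")

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.statistics]

    def __len__(self) -> int:
        return len(self.statistics)

    def __iter__(self):
        return iter(self.statistics)

    def index(self, kind: str) -> int:
        for i, s in enumerate(self.statistics):
            if s.kind == kind or s.name == kind:
                return i
        raise KeyError(kind)

    def with_statistic(self, stat: Statistic) -> "ERGMSpec":
        return ERGMSpec(self.statistics + [stat])

    def without(self, kind: str) -> "ERGMSpec":
        return ERGMSpec([s for s in self.statistics
                         if s.kind != kind and s.name != kind])

    @classmethod
    def from_names(cls, tokens: list[str] | str) -> "ERGMSpec":
        if isinstance(tokens, str):
            tokens = [t for t in tokens.split(",") if t.strip()]
        return cls([Statistic.parse(t) for t in tokens])


@dataclass
class EncodedModel:
    """Spec + network + attributes flattened to arrays for the sampler."""

    kinds: np.ndarray      # int64 statistic kind codes
    lams: np.ndarray       # float64 decay per statistic (0 if unused)
    asite: np.ndarray      # int64 landing-site code per statistic (-1 if unused)
    leader: np.ndarray     # int64 per-actor leader flag
    site: np.ndarray       # int64 per-actor landing-site code
    m: np.ndarray          # float64 shared-species counts |N_X(i) ∩ N_X(j)|
    site_categories: list[str] = field(default_factory=list)


def encode_model(net: MultilevelNetwork, actors: pd.DataFrame | None,
                 spec: ERGMSpec) -> EncodedModel:
    """Resolve attribute bindings and precompute the shared-species matrix."""
    n = net.n_actors
    needs = {_ATTRIBUTE_KINDS[s.kind] for s in spec if s.kind in _ATTRIBUTE_KINDS}
    if needs and actors is None:
        raise ValueError(f"spec needs actor attributes {sorted(needs)} "
                         "but no actor table was given")
    leader = np.zeros(n, dtype=np.int64)
    site = np.zeros(n, dtype=np.int64)
    site_categories: list[str] = []
    if actors is not None:
        if len(actors) != n:
            raise ValueError("actor table length does not match network")
        if "leader" in actors.columns:
            leader = actors["leader"].astype(bool).to_numpy().astype(np.int64)
        elif "leader" in needs:
            raise ValueError("actor table lacks a 'leader' column")
        if "landing_site" in actors.columns:
            cats = pd.Categorical(actors["landing_site"].astype(str))
            site = np.asarray(cats.codes, dtype=np.int64)
            site_categories = list(cats.categories)
        elif "landing_site" in needs:
            raise ValueError("actor table lacks a 'landing_site' column")
    kinds = np.array([KIND_CODES[s.kind] for s in spec], dtype=np.int64)
    lams = np.array([s.lam if s.kind in ("alt_star", "alt_triangle") else 0.0
                     for s in spec], dtype=np.float64)
    asite = np.full(len(spec), -1, dtype=np.int64)
    for k, s in enumerate(spec):
        if s.kind == "site_activity":
            if s.site not in site_categories:
                raise ValueError(f"unknown landing site {s.site!r}; "
                                 f"known: {site_categories}")
            asite[k] = site_categories.index(s.site)
    X = net.X.astype(np.float64)
    m = X @ X.T
    np.fill_diagonal(m, 0.0)
    return EncodedModel(kinds, lams, asite, leader, site, m, site_categories)


def statistics_from_adjacency(A: np.ndarray, enc: EncodedModel) -> np.ndarray:
    """Evaluate the full statistic vector on an adjacency matrix."""
    A = np.asarray(A)
    Af = A.astype(np.float64)
    d = Af.sum(axis=1)
    iu = np.triu_indices(A.shape[0], k=1)
    edge_mask = Af[iu] == 1
    z = np.empty(len(enc.kinds), dtype=np.float64)
    P = None
    for k, code in enumerate(enc.kinds):
        if code == 0:
            z[k] = edge_mask.sum()
        elif code == 1:
            z[k] = (d * (d - 1) / 2).sum()
        elif code == 2:
            lam = enc.lams[k]
            r = 1.0 - 1.0 / lam
            z[k] = lam ** 2 * (r ** d - 1.0 + d / lam).sum()
        elif code == 3:
            lam = enc.lams[k]
            r = 1.0 - 1.0 / lam
            if P is None:
                P = Af @ Af
            z[k] = lam * (1.0 - r ** P[iu][edge_mask]).sum()
        elif code == 4:
            z[k] = float(enc.leader @ d)
        elif code == 5:
            same = enc.site[iu[0]] == enc.site[iu[1]]
            z[k] = (Af[iu] * same).sum()
        elif code == 6:
            z[k] = float(d[enc.site == enc.asite[k]].sum())
        elif code == 7:
            z[k] = 0.5 * (Af * enc.m).sum()
    return z


def global_statistics(net: MultilevelNetwork, actors: pd.DataFrame | None,
                      spec: ERGMSpec) -> np.ndarray:
    """Statistic vector ``z`` of the observed network, in spec order."""
    enc = encode_model(net, actors, spec)
    return statistics_from_adjacency(net.A, enc)


def change_statistic(net: MultilevelNetwork, actors: pd.DataFrame | None,
                     spec: ERGMSpec, dyad: tuple) -> np.ndarray:
    """Change statistics ``z(A_ij=1) - z(A_ij=0)`` for one actor dyad.

    Computed locally (no full recount) from the state with the tie absent;
    the dyad may be given as actor ids or integer indices.
    """
    enc = encode_model(net, actors, spec)
    i, j = dyad
    if not isinstance(i, (int, np.integer)):
        idx = net.actor_index()
        try:
            i, j = idx[str(i)], idx[str(j)]
        except KeyError as err:
            raise KeyError(f"unknown actor in dyad {dyad!r}") from err
    if i == j:
        raise ValueError("dyad endpoints must differ")
    A = net.A.copy()
    had = A[i, j] == 1
    if had:
        A[i, j] = A[j, i] = 0
    deg = A.sum(axis=1).astype(np.int64)
    out = np.empty(len(spec), dtype=np.float64)
    _engine.change_stats(A, deg, int(i), int(j), enc.kinds, enc.lams,
                         enc.asite, enc.leader, enc.site, enc.m, out)
    return out


def se_closure_count(net: MultilevelNetwork) -> int:
    """Count of closed cross-level triangles (i<j, u): A_ij=1, X_iu=X_ju=1."""
    m = net.X.astype(np.int64) @ net.X.astype(np.int64).T
    np.fill_diagonal(m, 0)
    return int((net.A.astype(np.int64) * m).sum() // 2)
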