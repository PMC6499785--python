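"""Construct the three network levels from raw field inputs.

The social level comes from a name-generator survey (each respondent
nominates up to ten contacts); nominations to non-respondents are dropped
and the remainder symmetrized into binary undirected ties.  The cross-level
incidence follows from each fisher's primary gear and a gear-to-target-
species catalog.  The ecological level is a trait-inferred trophic web:
an undirected predator-prey tie requires a permitted diet pairing, a
predator:prey body-size ratio inside an admissible interval, and (by
default) overlapping habitat use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import MultilevelNetwork, ValidationError, validate_network

__all__ = [
    "GearCatalog",
    "TrophicRuleSet",
    "DEFAULT_PREY_MAP",
    "build_social_network",
    "build_crosslevel_ties",
    "infer_trophic_web",
    "assemble_multilevel",
]

logger = logging.getLogger(__name__)

MAX_NOMINATIONS = 10

#: Which prey diet categories each predator diet category may feed on.
#: Piscivores take fish of any diet group; generalist carnivores and
#: omnivores take small lower-trophic groups.  Deliberately coarse — the
#: exact pairing is a tunable input, not a fixed taxonomy.
DEFAULT_PREY_MAP: dict[str, frozenset[str]] = {
    "piscivore": frozenset(
        {"piscivore", "invertivore", "herbivore", "planktivore", "corallivore", "omnivore"}),
    "omnivore": frozenset({"planktivore", "herbivore", "corallivore"}),
}


@dataclass
class GearCatalog:
    """Mapping from gear type to its set of target species."""

    targets: dict[str, set[str]]

    def __post_init__(self) -> None:
        self.targets = {g: set(map(str, sp)) for g, sp in self.targets.items()}

    @property
    def gears(self) -> list[str]:
        return sorted(self.targets)

    @property
    def all_species(self) -> set[str]:
        out: set[str] = set()
        for sp in self.targets.values():
            out |= sp
        return out

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GearCatalog":
        """Build from a long table with ``gear`` and ``species`` columns."""
        targets: dict[str, set[str]] = {}
        for gear, grp in df.groupby("gear"):
            targets[str(gear)] = set(grp["species"].astype(str))
        return cls(targets)

    def to_frame(self) -> pd.DataFrame:
        rows = [(g, s) for g in sorted(self.targets) for s in sorted(self.targets[g])]
        return pd.DataFrame(rows, columns=["gear", "species"])


@dataclass
class TrophicRuleSet:
    """Parameterized trait-based rules for inferring trophic ties.

    ``prey_map`` lists, per predator diet category, the prey diet categories
    it may feed on.  ``size_ratio`` is the admissible predator:prey maximum-
    body-length ratio interval (lower bound >= 1).  When
    ``require_habitat_overlap`` is set, predator and prey must share a
    habitat class.
    """

    prey_map: dict[str, frozenset[str]] = field(
        default_factory=lambda: dict(DEFAULT_PREY_MAP))
    size_ratio: tuple[float, float] = (1.5, 20.0)
    require_habitat_overlap: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.size_ratio
        if lo < 1:
            raise ValueError(f"size-ratio lower bound must be >= 1, got {lo}")
        if hi < lo:
            raise ValueError("size-ratio interval inverted")
        if not any(self.prey_map.values()):
            raise ValueError("prey map permits no predation at all")

    @classmethod
    def from_config(cls, cfg: dict) -> "TrophicRuleSet":
        prey = {k: frozenset(v) for k, v in cfg.get("prey_map", DEFAULT_PREY_MAP).items()}
        ratio = tuple(cfg.get("size_ratio", (1.5, 20.0)))
        return cls(prey, ratio, bool(cfg.get("require_habitat_overlap", True)))


def build_social_network(
    nominations: pd.DataFrame,
    respondents: set[str] | list[str],
    actor_order: list[str] | None = None,
    rule: str = "union",
) -> tuple[np.ndarray, list[str]]:
    """Symmetrized binary social adjacency from survey nominations.

    Parameters
    ----------
    nominations
        Frame with ``respondent`` and ``nominee`` columns (an optional
        ``qualifier`` column is carried by the survey but ignored here).
    respondents
        Ids of actors who completed the survey.  Nominees outside this set
        are dropped before symmetrization; nominations *by* unknown ids are
        logged and dropped, not fatal.
    rule
        ``"union"`` (either direction creates a tie; default, the standard
        choice for recall-limited name generators) or ``"intersection"``
        (both directions required).

    Returns the adjacency and the actor ordering used for its rows.
    """
    if not len(respondents):
        raise ValueError("respondent set is empty")
    if rule not in ("union", "intersection"):
        raise ValueError(f"unknown symmetrization rule {rule!r}")
    resp = {str(r) for r in respondents}
    order = [str(a) for a in (actor_order if actor_order is not None else sorted(resp))]
    if set(order) != resp:
        raise ValueError("actor_order must contain exactly the respondent set")
    idx = {a: i for i, a in enumerate(order)}
    n = len(order)
    D = np.zeros((n, n), dtype=np.int8)  # directed nominations
    counts: dict[str, int] = {}
    for _, row in nominations.iterrows():
        src, dst = str(row["respondent"]), str(row["nominee"])
        if src not in resp:
            logger.warning("dropping nomination by non-respondent %r", src)
            continue
        if src == dst:
            raise ValidationError(f"self-nomination by {src!r}")
        counts[src] = counts.get(src, 0) + 1
        if counts[src] > MAX_NOMINATIONS:
            raise ValidationError(
                f"respondent {src!r} exceeds {MAX_NOMINATIONS} nominations")
        if dst not in resp:  # non-respondent nominee: dropped
            continue
        D[idx[src], idx[dst]] = 1
    if rule == "union":
        A = np.maximum(D, D.T)
    else:
        A = np.minimum(D, D.T)
    return A.astype(np.int8), order


def build_crosslevel_ties(
    actors: pd.DataFrame,
    catalog: GearCatalog,
    species_order: list[str],
) -> np.ndarray:
    """Binary incidence X: actor i is tied to species u iff their primary
    gear targets u.  Actors sharing a gear therefore share an X row."""
    s_idx = {s: j for j, s in enumerate(species_order)}
    unknown_sp = catalog.all_species - set(species_order)
    if unknown_sp:
        raise ValidationError(f"catalog species not in registry: {sorted(unknown_sp)}")
    n = len(actors)
    X = np.zeros((n, len(species_order)), dtype=np.int8)
    for i, (_, row) in enumerate(actors.iterrows()):
        gear = row["gear"]
        if pd.isna(gear) or str(gear) not in catalog.targets:
            raise ValidationError(
                f"actor {row['id']!r} has unknown gear {gear!r}")
        for sp in catalog.targets[str(gear)]:
            X[i, s_idx[sp]] = 1
    return X


def infer_trophic_web(traits: pd.DataFrame, rules: TrophicRuleSet) -> np.ndarray:
    """Undirected trophic adjacency B from species traits.

    A tie u-v exists iff one species' diet permits preying on the other's
    diet group, the predator:prey size ratio falls in the admissible
    interval, and habitats overlap (if required).  The result is symmetric:
    trophic interaction, not feeding direction, is represented.  Output is
    invariant to the input row order up to the registry ordering.
    """
    for col in ("species", "diet", "size_cm", "habitat"):
        if col not in traits.columns:
            raise ValidationError(f"traits table missing column {col!r}")
    if (traits["size_cm"] <= 0).any():
        bad = traits.loc[traits["size_cm"] <= 0, "species"].tolist()
        raise ValidationError(f"non-positive body size for species: {bad}")
    sp = traits["species"].astype(str).tolist()
    diet = traits["diet"].astype(str).to_numpy()
    size = traits["size_cm"].to_numpy(dtype=float)
    habitat = traits["habitat"].astype(str).to_numpy()
    lo, hi = rules.size_ratio
    m = len(sp)
    B = np.zeros((m, m), dtype=np.int8)
    for u in range(m):
        for v in range(u + 1, m):
            if rules.require_habitat_overlap and habitat[u] != habitat[v]:
                continue
            # which of the pair could be the predator (strictly larger side
            # by the ratio interval, which has lower bound >= 1)
            big, small = (u, v) if size[u] >= size[v] else (v, u)
            ratio = size[big] / size[small]
            if not (lo <= ratio <= hi):
                continue
            allowed = rules.prey_map.get(diet[big], frozenset())
            if diet[small] in allowed:
                B[u, v] = B[v, u] = 1
    return B


def assemble_multilevel(
    A: np.ndarray,
    B: np.ndarray,
    X: np.ndarray,
    actors: pd.DataFrame,
    species_order: list[str],
) -> MultilevelNetwork:
    """Assemble and validate a MultilevelNetwork from its parts.

    An empty B is allowed: the ecological level is exogenous and the
    cross-level closure statistic does not use it.
    """
    net = MultilevelNetwork(actors["id"].astype(str).tolist(),
                            list(map(str, species_order)), A, B, X)
    validate_network(net).raise_if_invalid()
    return net
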