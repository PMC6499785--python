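"""Reef-fish ecological condition metrics from underwater visual census.

Transects are fixed-area (default 500 m^2) fish counts with per-record
lengths.  Biomass uses the standard length-weight conversion
``mass_g = a * L_cm ** b`` with per-species coefficients and is reported in
kg/ha: ``(total grams / area_m2) * 10``.  Functional richness is the number
of unique trait combinations (functional entities) among the species
observed, a trait-based alternative to species richness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "Observation",
    "TransectRecord",
    "estimate_biomass",
    "functional_richness",
    "read_transects",
    "write_transects",
    "DEFAULT_TRAIT_FIELDS",
    "DEFAULT_TRANSECT_AREA_M2",
]

DEFAULT_TRANSECT_AREA_M2 = 500.0
DEFAULT_TRAIT_FIELDS = ("diet", "size_class", "mobility")


@dataclass
class Observation:
    species: str
    count: int
    length_cm: float

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"count must be >= 1, got {self.count}")
        if self.length_cm <= 0:
            raise ValueError(f"length must be positive, got {self.length_cm}")


@dataclass
class TransectRecord:
    """One fixed-area visual-census transect."""

    site: str
    transect: str
    area_m2: float = DEFAULT_TRANSECT_AREA_M2
    observations: list[Observation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.area_m2 <= 0:
            raise ValueError(f"area must be positive, got {self.area_m2}")

    @property
    def species_present(self) -> set[str]:
        return {o.species for o in self.observations}


def _traits_by_species(traits: pd.DataFrame) -> pd.DataFrame:
    return traits.assign(species=traits["species"].astype(str)).set_index("species")


def estimate_biomass(transect: TransectRecord, traits: pd.DataFrame) -> float:
    """Transect fish biomass in kg/ha via length-weight conversion.

    ``traits`` must carry ``lw_a`` and ``lw_b`` columns for every observed
    species; missing species raise with the offending list.
    """
    tb = _traits_by_species(traits)
    missing = sorted(s for s in transect.species_present if s not in tb.index)
    if missing:
        raise KeyError(f"species without length-weight coefficients: {missing}")
    grams = 0.0
    for obs in transect.observations:
        a = float(tb.at[obs.species, "lw_a"])
        b = float(tb.at[obs.species, "lw_b"])
        if a <= 0:
            raise ValueError(f"non-positive length-weight 'a' for {obs.species}")
        grams += obs.count * a * obs.length_cm ** b
    return grams / transect.area_m2 * 10.0  # g/m^2 -> kg/ha


def functional_richness(transect: TransectRecord, traits: pd.DataFrame,
                        trait_fields: tuple[str, ...] = DEFAULT_TRAIT_FIELDS) -> int:
    """Number of distinct trait-value tuples among species in the transect."""
    if not trait_fields:
        raise ValueError("trait_fields must be nonempty")
    tb = _traits_by_species(traits)
    for f in trait_fields:
        if f not in tb.columns:
            raise KeyError(f"trait field {f!r} not in traits table")
    tuples = set()
    for sp in transect.species_present:
        if sp not in tb.index:
            raise KeyError(f"species {sp!r} not in traits table")
        vals = tuple(tb.at[sp, f] for f in trait_fields)
        if any(pd.isna(v) for v in vals):
            raise ValueError(f"species {sp!r} has a missing trait value")
        tuples.add(vals)
    return len(tuples)


def read_transects(path: str | Path, delimiter: str = ",") -> list[TransectRecord]:
    """Read transects from a long table
    ``(site,transect,species,count,length_cm,area_m2)``."""
    df = pd.read_csv(Path(path), sep=delimiter)
    out: list[TransectRecord] = []
    for (site, tid), grp in df.groupby(["site", "transect"], sort=True):
        area = float(grp["area_m2"].iloc[0]) if "area_m2" in grp else DEFAULT_TRANSECT_AREA_M2
        obs = [Observation(str(r.species), int(r.count), float(r.length_cm))
               for r in grp.itertuples()]
        out.append(TransectRecord(str(site), str(tid), area, obs))
    return out


def write_transects(transects: list[TransectRecord], path: str | Path,
                    delimiter: str = ",") -> None:
    rows = [
        (t.site, t.transect, o.species, o.count, o.length_cm, t.area_m2)
        for t in transects for o in t.observations
    ]
    pd.DataFrame(rows, columns=["site", "transect", "species", "count",
                                "length_cm", "area_m2"]).to_csv(
        Path(path), sep=delimiter, index=False)
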