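"""Multilevel social-ecological network container, validation, and IO.

A multilevel network couples a social network ``A`` (undirected communication
ties among resource users), an ecological network ``B`` (undirected trophic
ties among target species), and a cross-level incidence ``X`` linking each
actor to the species they harvest.  ``A`` and ``B`` are symmetric binary
adjacency matrices with zero diagonal; ``X`` is a binary actors-by-species
incidence matrix.  Only ``A`` is ever treated as random by the models in
:mod:`senet.ergm`; ``B`` and ``X`` are exogenous structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "MultilevelNetwork",
    "GraphSummaries",
    "ValidationError",
    "ValidationReport",
    "validate_network",
    "validate_actor_table",
    "degree_summary",
    "load_multilevel_network",
    "write_multilevel_network",
    "to_graphml",
]

ACTOR_COLUMNS = ("id", "gear", "landing_site", "leader", "community")

LEVELS = ("A", "B", "X-actor", "X-species")


class ValidationError(ValueError):
    """Raised when inputs violate the multilevel-network invariants."""


@dataclass
class MultilevelNetwork:
    """Two node levels plus within- and cross-level binary ties.

    Parameters
    ----------
    actors, species
        Ordered node registries (opaque string ids, disjoint between levels).
        All adjacency ordering follows these registries.
    A
        ``(n, n)`` symmetric binary social adjacency, zero diagonal.
    B
        ``(m, m)`` symmetric binary ecological adjacency, zero diagonal.
    X
        ``(n, m)`` binary actor-species incidence.
    """

    actors: list[str]
    species: list[str]
    A: np.ndarray
    B: np.ndarray
    X: np.ndarray

    def __post_init__(self) -> None:
        self.actors = [str(a) for a in self.actors]
        self.species = [str(s) for s in self.species]
        self.A = np.asarray(self.A, dtype=np.int8)
        self.B = np.asarray(self.B, dtype=np.int8)
        self.X = np.asarray(self.X, dtype=np.int8)
        n, m = len(self.actors), len(self.species)
        if self.A.shape != (n, n):
            raise ValidationError(f"A has shape {self.A.shape}, expected {(n, n)}")
        if self.B.shape != (m, m):
            raise ValidationError(f"B has shape {self.B.shape}, expected {(m, m)}")
        if self.X.shape != (n, m):
            raise ValidationError(f"X has shape {self.X.shape}, expected {(n, m)}")

    @property
    def n_actors(self) -> int:
        return len(self.actors)

    @property
    def n_species(self) -> int:
        return len(self.species)

    def actor_index(self) -> dict[str, int]:
        return {a: i for i, a in enumerate(self.actors)}

    def species_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.species)}

    def copy(self) -> "MultilevelNetwork":
        return MultilevelNetwork(
            list(self.actors), list(self.species),
            self.A.copy(), self.B.copy(), self.X.copy(),
        )


@dataclass
class ValidationReport:
    """Collected invariant violations; empty iff the network is valid."""

    findings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.findings

    def raise_if_invalid(self) -> None:
        if self.findings:
            raise ValidationError("; ".join(self.findings))


@dataclass
class GraphSummaries:
    """Degree-based summaries of one network level."""

    level: str
    degrees: np.ndarray
    n_edges: int
    density: float
    mean_degree: float
    s2: int
    s3: int
    triangles: int


def _check_binary_symmetric(M: np.ndarray, name: str, findings: list[str]) -> None:
    if not np.isin(M, (0, 1)).all():
        findings.append(f"{name} has entries outside {{0,1}}")
    if np.any(np.diag(M) != 0):
        idx = np.flatnonzero(np.diag(M))
        findings.append(f"{name} has self-ties at indices {idx.tolist()}")
    asym = np.argwhere(M != M.T)
    if asym.size:
        i, j = asym[0]
        findings.append(f"{name} asymmetric at ({i}, {j})")


def validate_network(net: MultilevelNetwork) -> ValidationReport:
    """Check all structural invariants, returning a report (never raising)."""
    findings: list[str] = []
    _check_binary_symmetric(net.A, "A", findings)
    _check_binary_symmetric(net.B, "B", findings)
    if not np.isin(net.X, (0, 1)).all():
        findings.append("X has entries outside {0,1}")
    dup_actors = pd.Index(net.actors).duplicated()
    if dup_actors.any():
        findings.append(f"duplicate actor ids: {list(pd.Index(net.actors)[dup_actors])}")
    dup_sp = pd.Index(net.species).duplicated()
    if dup_sp.any():
        findings.append(f"duplicate species ids: {list(pd.Index(net.species)[dup_sp])}")
    overlap = set(net.actors) & set(net.species)
    if overlap:
        findings.append(f"actor and species id sets overlap: {sorted(overlap)}")
    return ValidationReport(findings)


def validate_actor_table(actors: pd.DataFrame, require: tuple[str, ...] = ACTOR_COLUMNS) -> pd.DataFrame:
    """Validate a per-actor attribute table (one row per actor, gear present)."""
    missing = [c for c in require if c not in actors.columns]
    if missing:
        raise ValidationError(f"actor table missing columns: {missing}")
    if actors["id"].duplicated().any():
        dups = actors.loc[actors["id"].duplicated(), "id"].tolist()
        raise ValidationError(f"duplicate actor ids: {dups}")
    if actors["gear"].isna().any():
        bad = actors.loc[actors["gear"].isna(), "id"].tolist()
        raise ValidationError(f"actors with missing gear: {bad}")
    out = actors.copy()
    out["id"] = out["id"].astype(str)
    out["leader"] = out["leader"].astype(bool)
    return out


def degree_summary(net: MultilevelNetwork, level: str = "A") -> GraphSummaries:
    """Degrees, density, mean degree, k-star and triangle counts for a level.

    For the bipartite levels ``X-actor`` / ``X-species`` degrees are row /
    column sums of ``X``, density is relative to ``n*m`` possible ties, and
    the triangle count is zero by construction.
    """
    if level not in LEVELS:
        raise ValueError(f"unknown level {level!r}; expected one of {LEVELS}")
    if level == "A":
        M, d = net.A, net.A.sum(axis=1)
        n = net.n_actors
        possible = n * (n - 1) / 2
        n_edges = int(M.sum()) // 2
        triangles = int(np.trace(np.linalg.matrix_power(M.astype(np.int64), 3)) // 6)
    elif level == "B":
        M, d = net.B, net.B.sum(axis=1)
        m = net.n_species
        possible = m * (m - 1) / 2
        n_edges = int(M.sum()) // 2
        triangles = int(np.trace(np.linalg.matrix_power(M.astype(np.int64), 3)) // 6)
    else:
        d = net.X.sum(axis=1) if level == "X-actor" else net.X.sum(axis=0)
        possible = net.n_actors * net.n_species
        n_edges = int(net.X.sum())
        triangles = 0
    d = d.astype(np.int64)
    s2 = int((d * (d - 1) // 2).sum())
    s3 = int((d * (d - 1) * (d - 2) // 6).sum())
    density = n_edges / possible if possible else 0.0
    mean_degree = float(d.mean()) if d.size else 0.0
    return GraphSummaries(level, d, n_edges, density, mean_degree, s2, s3, triangles)


# ---------------------------------------------------------------------------
# Tabular IO
# ---------------------------------------------------------------------------

def _read_edges(path: str | Path, columns: tuple[str, str], delimiter: str,
                encoding: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=delimiter, encoding=encoding, dtype=str,
                     skip_blank_lines=True)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    # line numbers for error reporting: header is line 1
    df = df.reset_index().rename(columns={"index": "_line"})
    df["_line"] = df["_line"] + 2
    return df


def load_multilevel_network(
    actor_table_path: str | Path,
    social_edges_path: str | Path,
    x_edges_path: str | Path,
    b_edges_path: str | Path,
    species_table_path: str | Path | None = None,
    delimiter: str = ",",
    encoding: str = "utf-8",
) -> tuple[MultilevelNetwork, pd.DataFrame]:
    """Load a validated multilevel network from delimited-text tables.

    Files: actor table ``(id,gear,landing_site,leader,community,...)``,
    social edges ``(source,target)``, incidence ``(actor,species)``, and
    ecological edges ``(source,target)``.  The species registry comes from
    ``species_table_path`` (a traits table with a ``species`` column) when
    given, otherwise from the ids appearing in the X/B edge files.

    Returns the network together with the parsed actor table.  Unknown ids
    and self-loops are reported with their file line numbers.
    """
    actor_path = Path(actor_table_path)
    if not actor_path.exists():
        raise FileNotFoundError(actor_path)
    actors_df = validate_actor_table(
        pd.read_csv(actor_path, sep=delimiter, encoding=encoding))
    actors = actors_df["id"].tolist()

    a_edges = _read_edges(social_edges_path, ("source", "target"), delimiter, encoding)
    x_edges = _read_edges(x_edges_path, ("actor", "species"), delimiter, encoding)
    b_edges = _read_edges(b_edges_path, ("source", "target"), delimiter, encoding)

    if species_table_path is not None:
        sp_df = pd.read_csv(Path(species_table_path), sep=delimiter, encoding=encoding)
        col = "species" if "species" in sp_df.columns else "id"
        species = sp_df[col].astype(str).tolist()
    else:
        species = sorted(
            set(x_edges["species"]) | set(b_edges["source"]) | set(b_edges["target"]))

    a_idx = {a: i for i, a in enumerate(actors)}
    s_idx = {s: i for i, s in enumerate(species)}
    n, m = len(actors), len(species)
    A = np.zeros((n, n), dtype=np.int8)
    B = np.zeros((m, m), dtype=np.int8)
    X = np.zeros((n, m), dtype=np.int8)

    problems: list[str] = []
    for _, row in a_edges.iterrows():
        u, v, line = row["source"], row["target"], row["_line"]
        if u == v:
            problems.append(f"{social_edges_path} line {line}: self-loop {u}-{v}")
            continue
        if u not in a_idx or v not in a_idx:
            bad = u if u not in a_idx else v
            problems.append(f"{social_edges_path} line {line}: unknown actor {bad!r}")
            continue
        A[a_idx[u], a_idx[v]] = A[a_idx[v], a_idx[u]] = 1
    for _, row in b_edges.iterrows():
        u, v, line = row["source"], row["target"], row["_line"]
        if u == v:
            problems.append(f"{b_edges_path} line {line}: self-loop {u}-{v}")
            continue
        if u not in s_idx or v not in s_idx:
            bad = u if u not in s_idx else v
            problems.append(f"{b_edges_path} line {line}: unknown species {bad!r}")
            continue
        B[s_idx[u], s_idx[v]] = B[s_idx[v], s_idx[u]] = 1
    for _, row in x_edges.iterrows():
        a, s, line = row["actor"], row["species"], row["_line"]
        if a not in a_idx:
            problems.append(f"{x_edges_path} line {line}: unknown actor {a!r}")
            continue
        if s not in s_idx:
            problems.append(f"{x_edges_path} line {line}: unknown species {s!r}")
            continue
        X[a_idx[a], s_idx[s]] = 1

    if problems:
        raise ValidationError("; ".join(problems))

    net = MultilevelNetwork(actors, species, A, B, X)
    validate_network(net).raise_if_invalid()
    return net, actors_df


def _edge_frame(M: np.ndarray, ids: list[str], cols: tuple[str, str]) -> pd.DataFrame:
    iu, ju = np.triu_indices(len(ids), k=1)
    mask = M[iu, ju] == 1
    pairs = sorted(
        tuple(sorted((ids[i], ids[j]))) for i, j in zip(iu[mask], ju[mask]))
    return pd.DataFrame(pairs, columns=list(cols))


def write_multilevel_network(
    net: MultilevelNetwork,
    directory: str | Path,
    actors_df: pd.DataFrame | None = None,
    delimiter: str = ",",
) -> dict[str, Path]:
    """Write the network as delimited edge/incidence tables.

    Edges are emitted once per unordered pair, lexicographically sorted, so
    repeated writes of the same network are byte-identical.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "social_edges": directory / "social_edges.csv",
        "b_edges": directory / "b_edges.csv",
        "x_edges": directory / "x_edges.csv",
        "species": directory / "species.csv",
    }
    _edge_frame(net.A, net.actors, ("source", "target")).to_csv(
        paths["social_edges"], sep=delimiter, index=False)
    _edge_frame(net.B, net.species, ("source", "target")).to_csv(
        paths["b_edges"], sep=delimiter, index=False)
    ai, si = np.nonzero(net.X)
    x_pairs = sorted((net.actors[i], net.species[j]) for i, j in zip(ai, si))
    pd.DataFrame(x_pairs, columns=["actor", "species"]).to_csv(
        paths["x_edges"], sep=delimiter, index=False)
    pd.DataFrame({"species": net.species}).to_csv(
        paths["species"], sep=delimiter, index=False)
    if actors_df is not None:
        paths["actors"] = directory / "actors.csv"
        actors_df.to_csv(paths["actors"], sep=delimiter, index=False)
    return paths


def to_graphml(net: MultilevelNetwork, path: str | Path) -> None:
    """Export to GraphML with ``level`` node and ``type`` edge attributes."""
    G = nx.Graph()
    for a in net.actors:
        G.add_node(a, level="social")
    for s in net.species:
        G.add_node(s, level="ecological")
    for i, j in zip(*np.nonzero(np.triu(net.A))):
        G.add_edge(net.actors[i], net.actors[j], type="A")
    for i, j in zip(*np.nonzero(np.triu(net.B))):
        G.add_edge(net.species[i], net.species[j], type="B")
    for i, u in zip(*np.nonzero(net.X)):
        G.add_edge(net.actors[i], net.species[u], type="X")
    nx.write_graphml(G, str(path))
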