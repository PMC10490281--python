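"""The eight descriptor families of the final 2D-QSAR model.

Open-convention implementations of: Broto–Moreau autocorrelation (log form),
Balaban-like index from the Barysz weighted distance matrix, CATS2D
pharmacophore-pair counts, element-pair frequencies at fixed topological
distance, spectral moments of the dipole-augmented edge adjacency matrix,
and the radial distribution function over 3D coordinates. Numerical
identity with any commercial descriptor engine is not a goal; conventions
are fixed and documented here so values are reproducible and testable.
"""

from __future__ import annotations

import math
from functools import lru_cache
from importlib import resources

import numpy as np
import yaml
from scipy.sparse.csgraph import shortest_path
from scipy.spatial.distance import squareform, pdist

from ..exceptions import ConfigError, DomainError
from .graph import Conformer, MolecularGraph, topo_distances
from .ppp import PPP_TYPES, assign_ppp

__all__ = [
    "ats",
    "barysz_balaban",
    "cats2d",
    "atom_pair_freq",
    "edge_spectral_moment",
    "rdf",
    "bond_dipoles",
    "compute_table1_descriptors",
    "TABLE1_NAMES",
]

TABLE1_NAMES = (
    "ATS6m",
    "J_Dz(p)",
    "CATS2D_07_AA",
    "CATS2D_03_NL",
    "CATS2D_05_AA",
    "SM14_AEA(dm)",
    "F09[N-O]",
    "RDF140v",
)


def ats(graph: MolecularGraph, lag: int, weight: str) -> float:
    """Broto–Moreau autocorrelation at topological lag ``lag`` (log form).

    ``ATS_k,w = ln(1 + Σ_{i<j, d(i,j)=k} w̃_i w̃_j)`` with carbon-scaled
    atomic weights w̃. Lags beyond the graph diameter give ln(1+0) = 0.
    """
    if lag < 1:
        raise ConfigError(f"lag must be >= 1, got {lag}")
    w = graph.weights(weight)
    D = topo_distances(graph)
    iu = np.triu_indices(graph.n_atoms, k=1)
    mask = D[iu] == lag
    total = float(np.sum(w[iu[0]][mask] * w[iu[1]][mask]))
    return math.log1p(total)


def barysz_balaban(graph: MolecularGraph, weight: str) -> float:
    """Balaban-like index J from the Barysz weighted distance matrix.

    The Barysz matrix accumulates, along shortest paths, edge contributions
    ``1 / (π_rs · w̃_r · w̃_s)`` (π = bond order, aromatic = 1.5) and has
    diagonal ``1 − 1/w̃_i``; the index is the Balaban-type sum
    ``J = m/(μ+1) · Σ_edges (VS_i VS_j)^(-1/2)`` over its off-diagonal row
    sums VS, with m bonds and cyclomatic number μ.
    """
    n = graph.n_atoms
    if n < 2:
        raise DomainError("Barysz–Balaban index undefined for a trivial graph")
    w = graph.weights(weight)
    # weighted shortest paths over edge lengths 1/(order * w_r * w_s)
    W = np.full((n, n), np.inf)
    np.fill_diagonal(W, 0.0)
    for i, j, order in graph.bonds:
        W[i, j] = W[j, i] = 1.0 / (order * w[i] * w[j])
    D = shortest_path(W, method="D", directed=False)
    if not np.isfinite(D).all():
        topo_distances(graph)  # raises DisconnectedGraphError with fragments
    np.fill_diagonal(D, 1.0 - 1.0 / w)
    vs = D.sum(axis=1) - np.diag(D)
    m = graph.n_bonds
    mu = graph.cyclomatic_number
    total = sum(1.0 / math.sqrt(vs[i] * vs[j]) for i, j, _ in graph.bonds)
    return m / (mu + 1.0) * total


def cats2d(graph: MolecularGraph, lag: int, pair: tuple[str, str]) -> int:
    """CATS2D pharmacophore-pair count at a topological lag.

    Counts unordered heavy-atom pairs (i, j), i ≠ j, where one atom carries
    the first PPP type, the other the second, and their topological distance
    equals ``lag``. Raw (unscaled) counts.
    """
    t1, t2 = pair
    for t in (t1, t2):
        if t not in PPP_TYPES:
            raise ConfigError(f"invalid PPP type {t!r}; valid: {PPP_TYPES}")
    if not 0 <= lag <= 9:
        raise ConfigError(f"lag must be in 0..9, got {lag}")
    labels = assign_ppp(graph)
    D = topo_distances(graph)
    count = 0
    for i in range(graph.n_atoms):
        for j in range(i + 1, graph.n_atoms):
            if D[i, j] != lag:
                continue
            if (t1 in labels[i] and t2 in labels[j]) or (t2 in labels[i] and t1 in labels[j]):
                count += 1
    return count


def atom_pair_freq(graph: MolecularGraph, elem1: str, elem2: str, distance: int) -> int:
    """Count of unordered {elem1, elem2} atom pairs at an exact topological distance."""
    if distance < 1:
        raise ConfigError(f"distance must be >= 1, got {distance}")
    D = topo_distances(graph)
    syms = [a.element for a in graph.atoms]
    count = 0
    for i in range(graph.n_atoms):
        for j in range(i + 1, graph.n_atoms):
            if D[i, j] != distance:
                continue
            if {syms[i], syms[j]} == {elem1, elem2} or (
                elem1 == elem2 and syms[i] == elem1 and syms[j] == elem1
            ):
                count += 1
    return count


@lru_cache(maxsize=1)
def bond_dipoles() -> dict:
    """Bond dipole lookup (Debye), keyed ``'El1-El2:order'`` (sorted pair)."""
    ref = resources.files("qsarwb.descriptors").joinpath("data/bond_dipoles.yaml")
    raw = yaml.safe_load(ref.read_text())
    return {str(k): float(v) for k, v in raw.items()}


def _dipole_key(e1: str, e2: str, order: float) -> str:
    a, b = sorted((e1, e2))
    o = int(order) if float(order).is_integer() else order
    return f"{a}-{b}:{o}"


def edge_spectral_moment(
    graph: MolecularGraph, order: int, bond_weight: dict | None = None
) -> float:
    """Spectral moment of the dipole-augmented edge adjacency matrix.

    ``SM_k = ln(1 + trace(B̃^k))`` where B̃ has a 1 for every pair of bonds
    sharing an atom and bond dipole moments (Debye) on the diagonal, from
    ``bond_weight`` or the packaged lookup table.
    """
    if order < 1:
        raise ConfigError(f"order must be >= 1, got {order}")
    if graph.n_bonds < 1:
        raise DomainError("edge spectral moment needs at least one bond")
    lookup = bond_dipoles() if bond_weight is None else bond_weight
    m = graph.n_bonds
    B = np.zeros((m, m))
    for e, (i, j, bo) in enumerate(graph.bonds):
        key = _dipole_key(graph.atoms[i].element, graph.atoms[j].element, bo)
        if key not in lookup:
            raise ConfigError(
                f"bond type {key!r} (bond {i}-{j}) missing from dipole lookup"
            )
        B[e, e] = lookup[key]
    for e in range(m):
        ie, je, _ = graph.bonds[e]
        for f in range(e + 1, m):
            if_, jf, _ = graph.bonds[f]
            if {ie, je} & {if_, jf}:
                B[e, f] = B[f, e] = 1.0
    trace = float(np.trace(np.linalg.matrix_power(B, order)))
    return math.log1p(trace)


def rdf(
    conformer: Conformer,
    graph: MolecularGraph,
    radius: float,
    weight: str,
    beta: float = 100.0,
) -> float:
    """Radial distribution function at probe radius R (Å).

    ``RDF_R,w = Σ_{i<j} w̃_i w̃_j exp(−β (R − r_ij)²)`` with carbon-scaled
    weights and the Gaussian smoothing parameter β in Å⁻².
    """
    if conformer is None:
        raise DomainError("RDF needs 3D coordinates; supply a 3D SDF or Conformer")
    if beta <= 0:
        raise ConfigError(f"beta must be positive, got {beta}")
    coords = conformer.coords
    if coords.shape[0] != graph.n_atoms:
        raise DomainError(
            f"conformer has {coords.shape[0]} atoms, graph has {graph.n_atoms}"
        )
    w = graph.weights(weight)
    if graph.n_atoms < 2:
        return 0.0
    r = squareform(pdist(coords))
    iu = np.triu_indices(graph.n_atoms, k=1)
    return float(np.sum(w[iu[0]] * w[iu[1]] * np.exp(-beta * (radius - r[iu]) ** 2)))


def compute_table1_descriptors(
    graph: MolecularGraph, conformer: Conformer | None = None
) -> dict[str, float]:
    """The eight final-model descriptors for one molecule.

    ``RDF140v`` requires 3D coordinates and is reported as NaN when no
    conformer is supplied; everything else is purely topological.
    """
    values = {
        "ATS6m": ats(graph, 6, "mass"),
        "J_Dz(p)": barysz_balaban(graph, "polarizability"),
        "CATS2D_07_AA": float(cats2d(graph, 7, ("A", "A"))),
        "CATS2D_03_NL": float(cats2d(graph, 3, ("N", "L"))),
        "CATS2D_05_AA": float(cats2d(graph, 5, ("A", "A"))),
        "SM14_AEA(dm)": edge_spectral_moment(graph, 14),
        "F09[N-O]": float(atom_pair_freq(graph, "N", "O", 9)),
        "RDF140v": (
            rdf(conformer, graph, 14.0, "vdw_volume") if conformer is not None else float("nan")
        ),
    }
    return values
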