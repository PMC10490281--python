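"""Hydrogen-depleted molecular graphs and atomic property weights.

A :class:`MolecularGraph` is the common substrate for all topological
descriptors: heavy atoms with element / charge / aromaticity / attached-H
attributes and bonds with orders in {1, 1.5, 2, 3} (1.5 = aromatic).
Property weights (mass, polarizability, van der Waals volume) come from an
editable YAML table and are used carbon-scaled throughout, i.e.
``w̃_i = w_i / w_C``, the common convention of whole-molecule descriptor
engines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np
import yaml
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

from ..exceptions import ConfigError, DisconnectedGraphError, DomainError

__all__ = [
    "Atom",
    "MolecularGraph",
    "Conformer",
    "atomic_properties",
    "topo_distances",
]

_WEIGHT_NAMES = ("mass", "polarizability", "vdw_volume", "unit")


@lru_cache(maxsize=1)
def atomic_properties() -> dict:
    """Load the per-element property table (mass, polarizability, vdW radius)."""
    ref = resources.files("qsarwb.descriptors").joinpath("data/atomic_properties.yaml")
    return yaml.safe_load(ref.read_text())


def _property_value(element: str, name: str) -> float:
    table = atomic_properties()
    if element not in table:
        raise ConfigError(f"element {element!r} missing from atomic property table")
    props = table[element]
    if name == "mass":
        return float(props["mass"])
    if name == "polarizability":
        return float(props["polarizability"])
    if name == "vdw_volume":
        r = float(props["vdw_radius"])
        return 4.0 / 3.0 * math.pi * r**3
    if name == "unit":
        return 1.0
    raise ConfigError(f"unknown property weight {name!r}; valid: {_WEIGHT_NAMES}")


@dataclass(frozen=True)
class Atom:
    """A heavy atom: element symbol, formal charge, aromatic flag, attached H count."""

    element: str
    formal_charge: int = 0
    aromatic: bool = False
    n_h: int = 0


@dataclass
class Conformer:
    """3D coordinates (Å) aligned to a graph's atom order."""

    coords: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise DomainError(f"coords must be (n, 3), got {self.coords.shape}")
        if not np.isfinite(self.coords).all():
            raise DomainError("non-finite coordinates")


@dataclass
class MolecularGraph:
    """Hydrogen-depleted atom/bond graph with per-atom property weights.

    ``bonds`` entries are ``(i, j, order)`` with 0-based indices and order in
    {1, 1.5, 2, 3}.
    """

    atoms: list[Atom]
    bonds: list[tuple[int, int, float]]
    _mol: object = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        n = len(self.atoms)
        seen = set()
        norm = []
        for i, j, order in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise DomainError(f"invalid bond ({i},{j}) for {n} atoms")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise DomainError(f"duplicate bond {key}")
            seen.add(key)
            norm.append((key[0], key[1], float(order)))
        self.bonds = norm

    # -- construction --------------------------------------------------------
    @classmethod
    def from_rdkit(cls, mol) -> "MolecularGraph":
        from rdkit import Chem

        mol = Chem.RemoveHs(mol)
        atoms = [
            Atom(
                element=a.GetSymbol(),
                formal_charge=a.GetFormalCharge(),
                aromatic=a.GetIsAromatic(),
                n_h=a.GetTotalNumHs(),
            )
            for a in mol.GetAtoms()
        ]
        bonds = [
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
            for b in mol.GetBonds()
        ]
        return cls(atoms=atoms, bonds=bonds, _mol=mol)

    @classmethod
    def from_smiles(cls, smiles: str) -> "MolecularGraph":
        from rdkit import Chem

        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise DomainError(f"unparsable SMILES: {smiles!r}")
        return cls.from_rdkit(mol)

    def to_rdkit(self):
        """RDKit mol for this graph (cached when built from RDKit)."""
        if self._mol is not None:
            return self._mol
        from rdkit import Chem

        order_map = {
            1.0: Chem.BondType.SINGLE,
            1.5: Chem.BondType.AROMATIC,
            2.0: Chem.BondType.DOUBLE,
            3.0: Chem.BondType.TRIPLE,
        }
        rw = Chem.RWMol()
        for atom in self.atoms:
            a = Chem.Atom(atom.element)
            a.SetFormalCharge(atom.formal_charge)
            a.SetNumExplicitHs(atom.n_h)
            a.SetNoImplicit(True)
            a.SetIsAromatic(atom.aromatic)
            rw.AddAtom(a)
        for i, j, order in self.bonds:
            if order not in order_map:
                raise DomainError(f"unsupported bond order {order}")
            rw.AddBond(i, j, order_map[order])
        mol = rw.GetMol()
        Chem.SanitizeMol(mol)
        self._mol = mol
        return mol

    # -- basic structure -----------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    @property
    def cyclomatic_number(self) -> int:
        # assumes connected; callers check connectivity first
        return self.n_bonds - self.n_atoms + 1

    def adjacency(self) -> np.ndarray:
        """0/1 adjacency matrix over heavy atoms."""
        A = np.zeros((self.n_atoms, self.n_atoms))
        for i, j, _ in self.bonds:
            A[i, j] = A[j, i] = 1.0
        return A

    def weights(self, name: str, scaled: bool = True) -> np.ndarray:
        """Per-atom property weights; carbon-scaled unless ``scaled=False``."""
        w = np.array([_property_value(a.element, name) for a in self.atoms])
        if scaled and name != "unit":
            w = w / _property_value("C", name)
        return w

    def permuted(self, perm) -> "MolecularGraph":
        """Graph with atoms reordered so new index ``perm[i]`` = old index i."""
        perm = list(perm)
        inv = [0] * len(perm)
        for new, old in enumerate(perm):
            inv[old] = new
        atoms = [self.atoms[old] for old in perm]
        bonds = [(inv[i], inv[j], order) for i, j, order in self.bonds]
        return MolecularGraph(atoms=atoms, bonds=bonds)


def topo_distances(graph: MolecularGraph) -> np.ndarray:
    """Topological distance matrix: minimal bond counts between heavy atoms.

    Symmetric with zero diagonal. Raises :class:`DisconnectedGraphError`
    naming the fragments if the graph is not connected.
    """
    n = graph.n_atoms
    if n == 0:
        raise DomainError("empty graph")
    if n == 1:
        return np.zeros((1, 1), dtype=int)
    rows, cols = [], []
    for i, j, _ in graph.bonds:
        rows += [i, j]
        cols += [j, i]
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp > 1:
        frags = [sorted(np.flatnonzero(labels == c).tolist()) for c in range(n_comp)]
        raise DisconnectedGraphError(
            f"graph has {n_comp} fragments: {frags}", fragments=frags
        )
    dist = shortest_path(adj, method="BF", directed=False, unweighted=True)
    return dist.astype(int)
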