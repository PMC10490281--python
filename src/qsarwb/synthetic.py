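"""Synthetic descriptor datasets with a planted sparse linear signal.

Stands in for a curated inhibitor descriptor matrix so every pipeline stage
(pretreatment, selection, fitting, validation, AD, consensus) is testable
offline. Descriptors are standard Gaussian columns, optionally with a block
sharing a common latent factor at pairwise correlation ρ; the response is a
sparse linear combination plus Gaussian noise on the pIC50 scale (intercept
6, spanning roughly 4–9 like a typical µM–nM potency range).

Also provides the hand-checkable fixture molecules used by the descriptor
oracle tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset_io import DescriptorTable
from .descriptors import Atom, Conformer, MolecularGraph
from .exceptions import ConfigError

__all__ = ["SimSpec", "TrueModel", "gen_descriptor_dataset", "fixture_molecules", "FixtureMolecule"]


@dataclass(frozen=True)
class SimSpec:
    """Specification of a synthetic descriptor/activity dataset.

    ``coefficients`` maps informative column indices (0-based, referring to
    the first ``k_informative`` columns by default) to true β values.
    ``collinear_block`` columns (taken from the tail, never overlapping the
    informative ones) share pairwise correlation ``rho``.
    """

    n_compounds: int = 150
    p_total: int = 22
    coefficients: tuple = ((0, 2.0), (1, -3.0))
    intercept: float = 6.0
    noise_sd: float = 0.1
    collinear_block: int = 0
    rho: float = 0.0
    seed: int = 0

    @property
    def k_informative(self) -> int:
        return len(self.coefficients)

    def __post_init__(self):
        if self.k_informative > self.p_total:
            raise ConfigError("more informative coefficients than columns")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if not 0.0 <= self.rho < 1.0:
            raise ConfigError("rho must be in [0, 1)")
        if self.collinear_block > self.p_total - self.k_informative:
            raise ConfigError("collinear block overlaps informative columns")
        for j, _ in self.coefficients:
            if not 0 <= j < self.p_total:
                raise ConfigError(f"coefficient index {j} out of range")


@dataclass(frozen=True)
class TrueModel:
    """Ground truth stored alongside a generated dataset."""

    intercept: float
    coefficients: dict
    noise_sd: float
    informative: tuple
    collinear_columns: tuple
    rho: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "coefficients": {str(k): v for k, v in self.coefficients.items()},
            "noise_sd": self.noise_sd,
            "informative": list(self.informative),
            "collinear_columns": list(self.collinear_columns),
            "rho": self.rho,
            "seed": self.seed,
        }


def gen_descriptor_dataset(spec: SimSpec) -> tuple[DescriptorTable, TrueModel]:
    """Generate a descriptor table with a known sparse linear signal.

    Columns are unit-variance Gaussian; the collinear block is built as
    ``√ρ·f + √(1−ρ)·e_j`` around a common factor f, giving pairwise
    correlation ρ. ``y = β₀ + Σ β_j x_j + ε`` with ε ~ N(0, noise_sd²).
    Bit-identical for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_compounds, spec.p_total
    X = rng.standard_normal((n, p))
    block_cols = tuple(range(p - spec.collinear_block, p)) if spec.collinear_block else ()
    if spec.collinear_block >= 2 and spec.rho > 0:
        f = rng.standard_normal(n)
        for j in block_cols:
            X[:, j] = np.sqrt(spec.rho) * f + np.sqrt(1.0 - spec.rho) * rng.standard_normal(n)
    beta = dict(spec.coefficients)
    y = spec.intercept + sum(b * X[:, j] for j, b in beta.items())
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, size=n)
    names = [f"x{j + 1}" for j in range(p)]
    ids = [f"cmpd{i + 1:03d}" for i in range(n)]
    table = DescriptorTable(
        pd.DataFrame(X, index=ids, columns=names),
        pd.Series(np.asarray(y, dtype=float), index=ids, name="activity"),
    )
    truth = TrueModel(
        intercept=spec.intercept,
        coefficients={names[j]: float(b) for j, b in beta.items()},
        noise_sd=spec.noise_sd,
        informative=tuple(names[j] for j in beta),
        collinear_columns=tuple(names[j] for j in block_cols),
        rho=spec.rho,
        seed=spec.seed,
    )
    return table, truth


# ---------------------------------------------------------------------------
# Hand-checkable molecule fixtures
# ---------------------------------------------------------------------------

@dataclass
class FixtureMolecule:
    """A tiny molecule with hand-derived expected descriptor values."""

    name: str
    graph: MolecularGraph
    expected: dict
    smiles: str | None = None
    conformer: Conformer | None = None


def fixture_molecules() -> list[FixtureMolecule]:
    """The documented fixture set used by the descriptor oracle tests.

    Expected values are hand-derived: ATS lag-1 sums by pair enumeration
    (carbon-scaled masses, e.g. w̃_O = 15.999/12.011), the Barysz–Balaban
    ethane value from the closed form, CATS/atom-pair counts by inspection,
    and the RDF probe from the zero-exponent limit.
    """
    w_o = 15.999 / 12.011
    fixtures = [
        FixtureMolecule(
            name="ethane",
            smiles="CC",
            graph=MolecularGraph.from_smiles("CC"),
            expected={
                "ATS1m": float(np.log1p(1.0)),
                "J_Dz(any)": 1.0,
            },
        ),
        FixtureMolecule(
            name="ethanol",
            smiles="CCO",
            graph=MolecularGraph.from_smiles("CCO"),
            expected={
                "ATS1m": float(np.log1p(1.0 + w_o)),  # = ln(3.3320) = 1.2036
                "ppp_O": {"A", "D"},
            },
        ),
        FixtureMolecule(
            name="n-hexane",
            smiles="CCCCCC",
            graph=MolecularGraph.from_smiles("CCCCCC"),
            expected={
                "CATS2D_05_AA": 0,
                "CATS2D_07_AA": 0,
                "CATS2D_03_NL": 0,
                "F09[N-O]": 0,
                "all_carbons_L": True,
            },
        ),
        FixtureMolecule(
            name="pentane-1,5-diol",
            smiles="OCCCCCO",
            graph=MolecularGraph.from_smiles("OCCCCCO"),
            expected={"CATS2D_06_AA": 1, "CATS2D_05_AA": 0},
        ),
        FixtureMolecule(
            name="9-bond N-O chain",
            smiles="NCCCCCCCCO",
            graph=MolecularGraph.from_smiles("NCCCCCCCCO"),
            expected={"F09[N-O]": 1},
        ),
        FixtureMolecule(
            name="acetate",
            smiles="CC([O-])=O",
            graph=MolecularGraph.from_smiles("CC([O-])=O"),
            expected={"oxygens_N": True},
        ),
        FixtureMolecule(
            name="rdf-probe-14A",
            smiles=None,
            graph=MolecularGraph(
                atoms=[Atom("C", n_h=3), Atom("C", n_h=3)],
                bonds=[(0, 1, 1.0)],
            ),
            conformer=Conformer(np.array([[0.0, 0.0, 0.0], [14.0, 0.0, 0.0]])),
            expected={"RDF140v": 1.0},
        ),
    ]
    return fixtures
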