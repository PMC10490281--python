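"""Dataset handling: activity conversion, table I/O, splitting and pretreatment.

The central container is :class:`DescriptorTable`, a compounds × descriptors
matrix with an aligned activity vector, backed by pandas. Activities are
handled on the pIC50 (molar) scale: ``pIC50 = -log10(IC50 / 1e6)`` with IC50
in µM, so 1 µM ↦ 6.0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigError, DomainError, EmptyMatrixError, SchemaError

logger = logging.getLogger(__name__)

__all__ = [
    "CompoundRecord",
    "DescriptorTable",
    "SplitResult",
    "to_pic50",
    "from_pic50",
    "split_dataset",
    "pretreat",
    "read_smiles_file",
]


def to_pic50(ic50_um: float) -> float:
    """Convert an IC50 in µM to pIC50 in molar -log10 units.

    Raises :class:`DomainError` for non-positive or non-finite input.
    """
    ic50_um = float(ic50_um)
    if not math.isfinite(ic50_um) or ic50_um <= 0:
        raise DomainError(f"IC50 must be a positive finite value in µM, got {ic50_um!r}")
    return -math.log10(ic50_um * 1e-6)


def from_pic50(pic50: float) -> float:
    """Inverse of :func:`to_pic50`: pIC50 (molar) back to IC50 in µM."""
    pic50 = float(pic50)
    if not math.isfinite(pic50):
        raise DomainError(f"pIC50 must be finite, got {pic50!r}")
    return 10.0 ** (-pic50) * 1e6


@dataclass
class CompoundRecord:
    """A single compound: identifier, SMILES and activity.

    At least one of ``ic50`` (µM) / ``pic50`` (molar log units) must be
    given; when both are given they must be consistent to 1e-9.
    """

    id: str
    smiles: str
    ic50: float | None = None
    pic50: float | None = None

    def __post_init__(self):
        if self.ic50 is None and self.pic50 is None:
            raise SchemaError(f"compound {self.id!r}: need ic50 or pic50")
        if self.ic50 is not None:
            expected = to_pic50(self.ic50)
            if self.pic50 is None:
                self.pic50 = expected
            elif abs(self.pic50 - expected) > 1e-9:
                raise SchemaError(
                    f"compound {self.id!r}: inconsistent ic50={self.ic50} µM "
                    f"vs pic50={self.pic50} (expected {expected})"
                )


class DescriptorTable:
    """Compounds × named descriptors with an aligned activity vector.

    Parameters
    ----------
    X:
        DataFrame of descriptor values; index = compound ids, columns =
        descriptor names (unique).
    activity:
        Series aligned to ``X.index`` (typically pIC50 values).
    """

    def __init__(self, X: pd.DataFrame, activity: pd.Series):
        X = pd.DataFrame(X)
        activity = pd.Series(activity)
        if len(X) != len(activity):
            raise SchemaError(
                f"row count {len(X)} != activity length {len(activity)}"
            )
        if X.columns.duplicated().any():
            dupes = X.columns[X.columns.duplicated()].tolist()
            raise SchemaError(f"duplicate descriptor names: {dupes}")
        if X.index.duplicated().any():
            dupes = X.index[X.index.duplicated()].tolist()
            raise SchemaError(f"duplicate compound ids: {dupes}")
        if X.isna().any().any():
            bad = X.columns[X.isna().any()].tolist()
            raise SchemaError(f"missing values in descriptor columns {bad}; impute or drop upstream")
        if activity.isna().any():
            raise SchemaError("missing values in activity")
        activity.index = X.index
        self.X = X.astype(float)
        self.activity = activity.astype(float)
        self.pretreat_log: dict | None = None

    # -- convenience views -------------------------------------------------
    @property
    def compound_ids(self) -> list[str]:
        return [str(i) for i in self.X.index]

    @property
    def descriptor_names(self) -> list[str]:
        return [str(c) for c in self.X.columns]

    @property
    def values(self) -> np.ndarray:
        return self.X.to_numpy()

    @property
    def n_compounds(self) -> int:
        return len(self.X)

    def __len__(self) -> int:
        return len(self.X)

    def __repr__(self) -> str:
        return f"DescriptorTable({self.n_compounds} compounds × {self.X.shape[1]} descriptors)"

    def subset(self, ids) -> "DescriptorTable":
        """Row subset by compound ids (order follows ``ids``)."""
        ids = list(ids)
        missing = [i for i in ids if i not in self.X.index]
        if missing:
            raise SchemaError(f"unknown compound ids: {missing}")
        return DescriptorTable(self.X.loc[ids], self.activity.loc[ids])

    def select(self, names) -> "DescriptorTable":
        """Column subset by descriptor names."""
        names = list(names)
        missing = [n for n in names if n not in self.X.columns]
        if missing:
            raise SchemaError(f"unknown descriptors: {missing}")
        return DescriptorTable(self.X[names], self.activity)

    # -- I/O ----------------------------------------------------------------
    @classmethod
    def from_csv(cls, path, id_col: str = "id", activity_col: str = "activity") -> "DescriptorTable":
        """Read a CSV with an id column, descriptor columns and an activity column."""
        df = pd.read_csv(path)
        for col in (id_col, activity_col):
            if col not in df.columns:
                raise SchemaError(f"{path}: missing required column {col!r}")
        df = df.set_index(id_col)
        y = df.pop(activity_col)
        return cls(df, y)

    def to_csv(self, path, id_col: str = "id", activity_col: str = "activity") -> None:
        out = self.X.copy()
        out[activity_col] = self.activity
        out.index.name = id_col
        out.to_csv(path)


@dataclass(frozen=True)
class SplitResult:
    """Deterministic train/test partition of a table's compound ids."""

    train_ids: tuple
    test_ids: tuple
    seed: int
    test_fraction: float

    def apply(self, table: DescriptorTable) -> tuple[DescriptorTable, DescriptorTable]:
        return table.subset(self.train_ids), table.subset(self.test_ids)


def split_dataset(table: DescriptorTable, test_fraction: float = 0.2, seed: int = 3) -> SplitResult:
    """Seeded shuffle-then-partition split.

    The test set takes ``ceil(n * test_fraction)`` compounds (184 compounds at
    fraction 0.2 give the conventional 147/37 partition). Reproducible for a
    fixed (seed, row order); the shuffle is a Fisher–Yates permutation driven
    by a 64-bit seeded generator, so only internal reproducibility is
    guaranteed, not agreement with any other tool's splitter.
    """
    if not 0 < test_fraction < 1:
        raise ConfigError(f"test_fraction must be in (0,1), got {test_fraction}")
    n = table.n_compounds
    if n < 5:
        raise ConfigError(f"need at least 5 compounds to split, got {n}")
    n_test = math.ceil(n * test_fraction)
    if n_test == 0 or n_test == n:
        raise ConfigError(f"degenerate split: n={n}, test_fraction={test_fraction}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    ids = np.asarray(table.compound_ids, dtype=object)
    test_ids = tuple(ids[perm[:n_test]])
    train_ids = tuple(ids[perm[n_test:]])
    return SplitResult(train_ids=train_ids, test_ids=test_ids, seed=int(seed), test_fraction=float(test_fraction))


def pretreat(
    table: DescriptorTable,
    variance_cutoff: float = 1e-4,
    correlation_cutoff: float = 0.99,
) -> DescriptorTable:
    """Remove near-constant and highly intercorrelated descriptor columns.

    Columns with variance below ``variance_cutoff`` are dropped first; then
    while any pair has |Pearson r| above ``correlation_cutoff``, the most
    correlated pair is resolved by dropping the member with the larger mean
    absolute correlation to all remaining columns (ties: the higher column
    index goes). The returned table satisfies both cutoffs; removals are
    recorded in ``table.pretreat_log`` and logged.
    """
    if variance_cutoff <= 0 or correlation_cutoff <= 0:
        raise ConfigError("cutoffs must be positive")
    if table.n_compounds == 0 or not table.descriptor_names:
        raise EmptyMatrixError("pretreat: empty input table")

    X = table.X
    variances = X.var(axis=0, ddof=1)
    low_var = variances.index[variances < variance_cutoff].tolist()
    kept = X.drop(columns=low_var)
    if kept.shape[1] == 0:
        raise EmptyMatrixError("pretreat removed all columns (variance filter)")

    removed_corr: list[tuple[str, str, float]] = []
    cols = list(kept.columns)
    corr = kept.corr().abs().to_numpy()
    np.fill_diagonal(corr, 0.0)
    while True:
        if len(cols) < 2:
            break
        flat = np.argmax(corr)
        i, j = divmod(flat, corr.shape[1])
        if corr[i, j] <= correlation_cutoff:
            break
        # drop the member with the larger mean |r| against everything else
        mean_i = corr[i].sum() / (len(cols) - 1)
        mean_j = corr[j].sum() / (len(cols) - 1)
        if mean_i > mean_j:
            drop = i
        elif mean_j > mean_i:
            drop = j
        else:
            drop = max(i, j)
        keep = j if drop == i else i
        removed_corr.append((cols[drop], cols[keep], float(corr[i, j])))
        corr = np.delete(np.delete(corr, drop, axis=0), drop, axis=1)
        del cols[drop]
    if not cols:
        raise EmptyMatrixError("pretreat removed all columns (correlation filter)")

    out = DescriptorTable(kept[cols], table.activity)
    out.pretreat_log = {
        "low_variance": low_var,
        "correlated": [
            {"removed": r, "kept": k, "abs_r": v} for r, k, v in removed_corr
        ],
        "variance_cutoff": variance_cutoff,
        "correlation_cutoff": correlation_cutoff,
    }
    if low_var or removed_corr:
        logger.info(
            "pretreat: removed %d low-variance and %d correlated columns",
            len(low_var), len(removed_corr),
        )
    return out


def read_smiles_file(path) -> list[tuple[str, str]]:
    """Read a .smi file: one ``SMILES<whitespace>id`` record per line.

    Returns (id, smiles) pairs; a missing id falls back to the 1-based line
    number.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            cid = parts[1].strip() if len(parts) > 1 else str(lineno)
            records.append((cid, smiles))
    return records
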