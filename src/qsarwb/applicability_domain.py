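"""Leverage-based applicability domain and Williams plot data.

The applicability domain (AD) of a regression model is delimited by the
hat-matrix leverage ``h_i = x_i (XᵀX)⁻¹ x_iᵀ`` (intercept-augmented) with
warning threshold ``h* = 3(p+1)/n``, plotted against standardized residuals
(cutoff ±3). Compounds beyond h* are structural outliers; residuals beyond
±3 standard deviations are response outliers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset_io import DescriptorTable
from .exceptions import DomainError, SingularityError
from .models import MLRModel

__all__ = ["ADRecord", "leverages", "williams_table", "plot_williams"]


@dataclass(frozen=True)
class ADRecord:
    """Per-compound applicability-domain entry."""

    compound_id: str
    leverage: float
    std_residual: float
    structural_outlier: bool
    response_outlier: bool
    inside: bool
    set: str  # "train" | "test"


def leverages(X_train, X_query=None) -> tuple[np.ndarray, float]:
    """Hat-matrix leverages and the warning threshold h* = 3(p+1)/n.

    Leverages are computed against the training design (intercept column
    added); query rows, if given, are projected onto the same hat matrix
    without refitting.
    """
    if isinstance(X_train, DescriptorTable):
        X_train = X_train.values
    X_train = np.asarray(X_train, dtype=float)
    n, p = X_train.shape
    Z = np.column_stack([np.ones(n), X_train])
    gram = Z.T @ Z
    try:
        gram_inv = np.linalg.inv(gram)
    except np.linalg.LinAlgError as err:
        raise SingularityError("XᵀX is singular; remove collinear descriptors") from err
    h_star = 3.0 * (p + 1) / n
    if X_query is None:
        h = np.einsum("ij,jk,ik->i", Z, gram_inv, Z)
    else:
        if isinstance(X_query, DescriptorTable):
            X_query = X_query.values
        X_query = np.asarray(X_query, dtype=float)
        Q = np.column_stack([np.ones(len(X_query)), X_query])
        h = np.einsum("ij,jk,ik->i", Q, gram_inv, Q)
    return h, h_star


def williams_table(
    model: MLRModel,
    train: DescriptorTable,
    test: DescriptorTable | None = None,
    residual_cutoff: float = 3.0,
) -> pd.DataFrame:
    """Williams plot data: leverage, standardized residual and outlier flags.

    Residuals are standardized by the training RMSE with n − p − 1 degrees
    of freedom; test-set leverages use the training hat matrix (no refit).
    Returns a DataFrame with one row per compound (train first).
    """
    names = model.descriptor_names
    Xtr = train.X[names]
    ytr = train.activity.to_numpy()
    n, p = Xtr.shape
    resid_tr = ytr - model.predict(Xtr)
    dof = n - p - 1
    if dof <= 0:
        raise DomainError(f"no residual degrees of freedom (n={n}, p={p})")
    s = float(np.sqrt(np.sum(resid_tr**2) / dof))
    if s == 0:
        raise DomainError("zero residual variance; standardized residuals undefined")

    h_tr, h_star = leverages(Xtr.to_numpy())
    records = _records(train.compound_ids, h_tr, resid_tr / s, h_star, residual_cutoff, "train")
    if test is not None:
        Xte = test.X[names]
        resid_te = test.activity.to_numpy() - model.predict(Xte)
        h_te, _ = leverages(Xtr.to_numpy(), Xte.to_numpy())
        records += _records(
            test.compound_ids, h_te, resid_te / s, h_star, residual_cutoff, "test"
        )
    df = pd.DataFrame([r.__dict__ for r in records])
    df.attrs["h_star"] = h_star
    df.attrs["residual_cutoff"] = residual_cutoff
    return df


def _records(ids, h, std_resid, h_star, cutoff, which) -> list[ADRecord]:
    out = []
    for cid, hi, ri in zip(ids, h, std_resid):
        structural = bool(hi > h_star)
        response = bool(abs(ri) > cutoff)
        out.append(
            ADRecord(
                compound_id=str(cid),
                leverage=float(hi),
                std_residual=float(ri),
                structural_outlier=structural,
                response_outlier=response,
                inside=not structural and not response,
                set=which,
            )
        )
    return out


def plot_williams(table: pd.DataFrame, path) -> None:
    """Render the Williams plot (leverage vs standardized residual) to a file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    h_star = table.attrs.get("h_star")
    cutoff = table.attrs.get("residual_cutoff", 3.0)
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for which, marker in (("train", "o"), ("test", "^")):
        sub = table[table["set"] == which]
        if len(sub):
            ax.scatter(sub["leverage"], sub["std_residual"], marker=marker, label=which, alpha=0.7)
    if h_star is not None:
        ax.axvline(h_star, color="red", linestyle="--", label="h*")
    ax.axhline(cutoff, color="gray", linestyle=":")
    ax.axhline(-cutoff, color="gray", linestyle=":")
    ax.set_xlabel("leverage h")
    ax.set_ylabel("standardized residual")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
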