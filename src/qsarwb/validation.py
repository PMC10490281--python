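"""Internal/external validation battery for QSAR regression models.

Implements the standard roster: leave-one-out Q², the external predictivity
coefficients Q²_F1 / Q²_F2 / Q²_F3 and RMSEP, Roy's rm² metrics, variance
inflation factors, the Todeschini multivariate K correlation index
(K_xx, ΔK) and the Y-randomization test with the cR_p² statistic
``cR_p² = R · √(R² − R̄_r²)``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .dataset_io import DescriptorTable
from .exceptions import ConfigError, DomainError
from .models import MLRModel

__all__ = [
    "q2_loo",
    "external_q2",
    "rm2_metrics",
    "vif",
    "kxx_deltak",
    "y_randomization",
    "crp2",
    "YRandomizationResult",
    "ValidationReport",
    "validate_model",
]


def _design(X: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(len(X)), X])


def _ols_r2(X: np.ndarray, y: np.ndarray) -> float:
    """Training R² of an intercept OLS fit (fast lstsq path)."""
    Z = _design(X)
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    resid = y - Z @ beta
    tss = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - float(resid @ resid) / tss


def q2_loo(X, y=None) -> float:
    """Leave-one-out cross-validated R²: ``1 − PRESS/TSS``.

    Uses the exact hat-matrix identity ``e_(i) = e_i / (1 − h_ii)`` for the
    deleted residuals; identical (to rounding) to n explicit refits.
    """
    if isinstance(X, DescriptorTable):
        X, y = X.values, X.activity.to_numpy()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p + 2:
        raise DomainError(f"q2_loo needs n > p + 2 (n={n}, p={p})")
    Z = _design(X)
    try:
        H = Z @ np.linalg.solve(Z.T @ Z, Z.T)
    except np.linalg.LinAlgError as err:
        raise DomainError("singular design in q2_loo") from err
    h = np.diag(H)
    if np.any(h >= 1.0 - 1e-12):
        raise DomainError("leverage of 1 encountered; a refit would be singular")
    resid = y - H @ y
    press = float(np.sum((resid / (1.0 - h)) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press / tss


def external_q2(y_test, y_pred, y_train) -> tuple[float, float, float, float]:
    """External predictivity coefficients (Q²_F1, Q²_F2, Q²_F3) and RMSEP.

    F1 references the training mean, F2 the test mean, F3 the per-observation
    training variance.
    """
    y_test = np.asarray(y_test, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    if y_test.shape != y_pred.shape or y_test.ndim != 1:
        raise DomainError("y_test and y_pred must be 1-D and aligned")
    sse = float(np.sum((y_test - y_pred) ** 2))
    ss_train_ref = float(np.sum((y_test - y_train.mean()) ** 2))
    ss_test_ref = float(np.sum((y_test - y_test.mean()) ** 2))
    ss_train = float(np.sum((y_train - y_train.mean()) ** 2))
    if ss_train_ref == 0 or ss_test_ref == 0 or ss_train == 0:
        raise DomainError("zero reference sum of squares; metrics undefined")
    f1 = 1.0 - sse / ss_train_ref
    f2 = 1.0 - sse / ss_test_ref
    f3 = 1.0 - (sse / len(y_test)) / (ss_train / len(y_train))
    rmsep = float(np.sqrt(sse / len(y_test)))
    return f1, f2, f3, rmsep


def _r0_squared(y: np.ndarray, x: np.ndarray) -> float:
    """R² of the through-origin regression of y on x."""
    k = float(x @ y) / float(x @ x)
    resid = y - k * x
    tss = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - float(resid @ resid) / tss


def rm2_metrics(y_obs, y_pred) -> tuple[float, float]:
    """Roy's modified r² metrics: average rm² and Δrm².

    For each direction, ``rm² = r² (1 − √max(r² − r0², 0))`` with r² the
    squared Pearson correlation and r0² the through-origin determination
    coefficient; the two directions (obs-on-pred and pred-on-obs) are
    averaged and their absolute difference reported.
    """
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if len(y_obs) < 3:
        raise DomainError("rm2 needs at least 3 points")
    if np.std(y_obs) == 0 or np.std(y_pred) == 0:
        raise DomainError("constant vector; rm2 undefined")
    r2 = float(np.corrcoef(y_obs, y_pred)[0, 1]) ** 2

    def one_direction(y, x):
        r0sq = _r0_squared(y, x)
        return r2 * (1.0 - np.sqrt(max(r2 - r0sq, 0.0)))

    rm2_fwd = one_direction(y_obs, y_pred)
    rm2_rev = one_direction(y_pred, y_obs)
    return (rm2_fwd + rm2_rev) / 2.0, abs(rm2_fwd - rm2_rev)


def rm2_directional(y_obs, y_pred) -> tuple[float, float]:
    """Both raw rm² directions (obs-on-pred, pred-on-obs)."""
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    r2 = float(np.corrcoef(y_obs, y_pred)[0, 1]) ** 2
    fwd = r2 * (1.0 - np.sqrt(max(r2 - _r0_squared(y_obs, y_pred), 0.0)))
    rev = r2 * (1.0 - np.sqrt(max(r2 - _r0_squared(y_pred, y_obs), 0.0)))
    return fwd, rev


def vif(X) -> pd.Series:
    """Variance inflation factors ``VIF_i = 1 / (1 − R_i²)`` per descriptor.

    Perfectly collinear columns are reported as +inf with a warning rather
    than raising.
    """
    if isinstance(X, DescriptorTable):
        X = X.X
    X = pd.DataFrame(X).astype(float)
    n, p = X.shape
    if n <= p + 1:
        raise DomainError(f"vif needs n > p + 1 (n={n}, p={p})")
    out = {}
    mat = X.to_numpy()
    for i, col in enumerate(X.columns):
        others = np.delete(mat, i, axis=1)
        r2 = _ols_r2(others, mat[:, i]) if others.shape[1] else 0.0
        if r2 >= 1.0 - 1e-12:
            warnings.warn(f"descriptor {col!r} perfectly collinear; VIF = inf")
            out[str(col)] = np.inf
        else:
            out[str(col)] = 1.0 / (1.0 - r2)
    return pd.Series(out)


def _k_index(corr: np.ndarray) -> float:
    """Todeschini K multivariate correlation of a correlation matrix."""
    q = corr.shape[0]
    lam = np.linalg.eigvalsh(corr)
    lam = np.clip(lam, 0.0, None)
    total = lam.sum()
    return float(np.sum(np.abs(lam / total - 1.0 / q)) / (2.0 * (q - 1.0) / q))


def kxx_deltak(X, y=None) -> tuple[float, float]:
    """K_xx of the descriptor correlation matrix and ΔK = K_xy − K_xx.

    K is 0 for mutually orthogonal columns and 1 for complete correlation;
    K_xy is computed on the correlation matrix of [X | y].
    """
    if isinstance(X, DescriptorTable):
        X, y = X.X, X.activity
    X = pd.DataFrame(X).astype(float)
    if X.shape[1] < 2:
        raise DomainError("kxx needs at least 2 descriptors")
    cx = np.corrcoef(X.to_numpy(), rowvar=False)
    if not np.isfinite(cx).all():
        raise DomainError("non-finite correlations (constant column?)")
    k_xx = _k_index(cx)
    if y is None:
        raise DomainError("activity vector required for ΔK")
    xy = np.column_stack([X.to_numpy(), np.asarray(y, dtype=float)])
    cxy = np.corrcoef(xy, rowvar=False)
    if not np.isfinite(cxy).all():
        raise DomainError("non-finite correlations with response")
    return k_xx, _k_index(cxy) - k_xx


def crp2(r2: float, mean_r2_rand: float) -> float:
    """``cR_p² = R · √(R² − R̄_r²)``, floored at 0 when the radicand is negative."""
    radicand = r2 - mean_r2_rand
    if radicand < 0:
        warnings.warn(
            "mean randomized R² exceeds the model R²; model no better than chance"
        )
        return 0.0
    return float(np.sqrt(r2) * np.sqrt(radicand))


@dataclass(frozen=True)
class YRandomizationResult:
    n_runs: int
    r2_true: float
    mean_r2_randomized: float
    crp2: float
    r2_randomized: tuple = field(repr=False, default=())


def y_randomization(X, y=None, n_runs: int = 1000, seed: int = 0) -> YRandomizationResult:
    """Response-scrambling robustness test.

    Each run permutes y (run i uses a generator seeded ``seed + i``), refits
    the OLS model and records its R²; cR_p² is computed from the mean
    randomized R² against the true model's R².
    """
    if n_runs < 100:
        raise ConfigError(f"n_runs must be >= 100, got {n_runs}")
    if isinstance(X, DescriptorTable):
        X, y = X.values, X.activity.to_numpy()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    r2_true = _ols_r2(X, y)
    r2_rand = np.empty(n_runs)
    for i in range(n_runs):
        rng = np.random.default_rng(seed + i)
        r2_rand[i] = _ols_r2(X, rng.permutation(y))
    mean_rand = float(r2_rand.mean())
    return YRandomizationResult(
        n_runs=n_runs,
        r2_true=r2_true,
        mean_r2_randomized=mean_rand,
        crp2=crp2(r2_true, mean_rand),
        r2_randomized=tuple(float(v) for v in r2_rand),
    )


@dataclass
class ValidationReport:
    """The full internal/external metric battery for one MLR model."""

    # internal (training)
    r2: float
    r2_adj: float
    f_stat: float
    mae: float
    q2_loo: float
    rm2_loo: float
    delta_rm2_loo: float
    k_xx: float
    delta_k: float
    vif: dict[str, float]
    # external (test)
    q2_f1: float
    q2_f2: float
    q2_f3: float
    rmsep: float
    rm2_test: float
    delta_rm2_test: float
    # optional randomization block
    y_randomization: dict | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    def summary_line(self, n_train: int, n_test: int) -> str:
        return (
            f"N_training = {n_train}, R2 = {self.r2:.3f}, R2_adj = {self.r2_adj:.3f}, "
            f"Q2_LOO = {self.q2_loo:.3f}, MAE = {self.mae:.3f}, "
            f"rm2_LOO = {self.rm2_loo:.3f}, delta_rm2_LOO = {self.delta_rm2_loo:.3f}, "
            f"K_xx = {self.k_xx:.3f}, delta_K = {self.delta_k:.3f}. "
            f"N_test = {n_test}, Q2_F1 = {self.q2_f1:.3f}, Q2_F2 = {self.q2_f2:.3f}, "
            f"Q2_F3 = {self.q2_f3:.3f}, RMSEP = {self.rmsep:.3f}, "
            f"rm2_test = {self.rm2_test:.3f}, delta_rm2_test = {self.delta_rm2_test:.3f}"
        )


def _loo_predictions(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Deleted (leave-one-out) predictions via the hat-matrix identity."""
    Z = _design(X)
    H = Z @ np.linalg.solve(Z.T @ Z, Z.T)
    h = np.diag(H)
    resid = y - H @ y
    return y - resid / (1.0 - h)


def validate_model(
    model: MLRModel,
    train: DescriptorTable,
    test: DescriptorTable,
    y_randomization_runs: int = 0,
    seed: int = 0,
) -> ValidationReport:
    """Assemble the complete validation battery for a fitted MLR model."""
    names = model.descriptor_names
    Xtr = train.X[names]
    ytr = train.activity.to_numpy()
    Xte = test.X[names]
    yte = test.activity.to_numpy()

    q2 = q2_loo(Xtr.to_numpy(), ytr)
    loo_pred = _loo_predictions(Xtr.to_numpy(), ytr)
    rm2_l, d_rm2_l = rm2_metrics(ytr, loo_pred)
    kxx, dk = kxx_deltak(Xtr, ytr)
    vifs = vif(Xtr)

    yhat_test = model.predict(Xte)
    f1, f2, f3, rmsep = external_q2(yte, yhat_test, ytr)
    rm2_t, d_rm2_t = rm2_metrics(yte, yhat_test)

    yrand = None
    if y_randomization_runs:
        res = y_randomization(
            Xtr.to_numpy(), ytr, n_runs=y_randomization_runs, seed=seed
        )
        yrand = {
            "n_runs": res.n_runs,
            "r2_true": res.r2_true,
            "mean_r2_randomized": res.mean_r2_randomized,
            "crp2": res.crp2,
        }

    return ValidationReport(
        r2=model.r2,
        r2_adj=model.r2_adj,
        f_stat=model.f_stat,
        mae=model.mae,
        q2_loo=q2,
        rm2_loo=rm2_l,
        delta_rm2_loo=d_rm2_l,
        k_xx=kxx,
        delta_k=dk,
        vif={k: float(v) for k, v in vifs.items()},
        q2_f1=f1,
        q2_f2=f2,
        q2_f3=f3,
        rmsep=rmsep,
        rm2_test=rm2_t,
        delta_rm2_test=d_rm2_t,
        y_randomization=yrand,
    )
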