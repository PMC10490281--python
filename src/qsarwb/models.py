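"""Regression models: MLR (OLS), PLS with a Q²_LOO stop rule, and tuned non-linear models.

The MLR model is the workhorse of the whole pipeline: an ordinary
least-squares fit with named coefficients, standard errors, standardized
coefficients (b*_j = b_j · s_xj / s_y) and the usual training diagnostics.
PLS adds latent components only while each one improves the leave-one-out
Q² by at least a configurable increment. Non-linear models (MLP / random
forest / SVM) are thin tuning wrappers over scikit-learn grid search.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import mean_absolute_error, r2_score
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR

from .dataset_io import DescriptorTable
from .exceptions import ConfigError, DomainError, SchemaError, SingularityError

__all__ = [
    "MLRModel",
    "fit_mlr",
    "predict_mlr",
    "PLSModel",
    "fit_pls",
    "TunedRegressor",
    "tune_regressor",
    "DEFAULT_GRIDS",
]

MODEL_SCHEMA_VERSION = 1


def _as_xy(X, y=None):
    """Accept a DescriptorTable or (DataFrame, Series)."""
    if isinstance(X, DescriptorTable):
        return X.X, X.activity
    if y is None:
        raise SchemaError("y required when X is not a DescriptorTable")
    return pd.DataFrame(X), pd.Series(y)


@dataclass
class MLRModel:
    """Fitted multiple linear regression with named coefficients.

    Predictions are ``intercept + Σ_j b_j x_j`` over the model's descriptor
    names. ``standardized_coefficients`` hold b_j · s_xj / s_y, the scale
    used to rank relative descriptor significance.
    """

    descriptor_names: list[str]
    intercept: float
    coefficients: dict[str, float]
    std_errors: dict[str, float]          # includes "(intercept)"
    standardized_coefficients: dict[str, float]
    r2: float
    r2_adj: float
    f_stat: float
    mae: float
    n_train: int
    schema_version: int = MODEL_SCHEMA_VERSION

    def predict(self, descriptors) -> np.ndarray:
        """Predict activity for a DataFrame/dict of named descriptor values."""
        if isinstance(descriptors, DescriptorTable):
            descriptors = descriptors.X
        if isinstance(descriptors, dict):
            descriptors = pd.DataFrame([descriptors])
        df = pd.DataFrame(descriptors)
        missing = [n for n in self.descriptor_names if n not in df.columns]
        if missing:
            raise SchemaError(f"missing descriptors for prediction: {missing}")
        X = df[self.descriptor_names].to_numpy(dtype=float)
        b = np.array([self.coefficients[n] for n in self.descriptor_names])
        return self.intercept + X @ b

    def significance_ranking(self) -> list[str]:
        """Descriptors ordered by decreasing |standardized coefficient|."""
        return sorted(
            self.descriptor_names,
            key=lambda n: -abs(self.standardized_coefficients[n]),
        )

    # -- (de)serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "type": "MLR",
            "descriptor_names": self.descriptor_names,
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "std_errors": self.std_errors,
            "standardized_coefficients": self.standardized_coefficients,
            "diagnostics": {
                "r2": self.r2,
                "r2_adj": self.r2_adj,
                "f_stat": self.f_stat,
                "mae": self.mae,
                "n_train": self.n_train,
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "MLRModel":
        diag = d["diagnostics"]
        return cls(
            descriptor_names=list(d["descriptor_names"]),
            intercept=float(d["intercept"]),
            coefficients={k: float(v) for k, v in d["coefficients"].items()},
            std_errors={k: float(v) for k, v in d["std_errors"].items()},
            standardized_coefficients={
                k: float(v) for k, v in d["standardized_coefficients"].items()
            },
            r2=float(diag["r2"]),
            r2_adj=float(diag["r2_adj"]),
            f_stat=float(diag["f_stat"]),
            mae=float(diag["mae"]),
            n_train=int(diag["n_train"]),
            schema_version=int(d.get("schema_version", MODEL_SCHEMA_VERSION)),
        )

    @classmethod
    def from_json(cls, path) -> "MLRModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _check_rank(X: pd.DataFrame) -> None:
    mat = X.to_numpy(dtype=float)
    design = np.column_stack([np.ones(len(mat)), mat])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # name columns involved: those whose removal restores full rank
        collinear = []
        for k, col in enumerate(X.columns):
            reduced = np.delete(design, k + 1, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                collinear.append(str(col))
        raise SingularityError(
            f"design matrix is rank-deficient; collinear columns: {collinear}",
            columns=collinear,
        )


def fit_mlr(X, y=None) -> MLRModel:
    """Ordinary least-squares fit with intercept.

    Requires n > p + 1 and a full-rank design; raises
    :class:`SingularityError` naming collinear columns otherwise.
    """
    Xdf, ys = _as_xy(X, y)
    n, p = Xdf.shape
    if n <= p + 1:
        raise DomainError(f"need n > p + 1 (n={n}, p={p})")
    _check_rank(Xdf)
    design = sm.add_constant(Xdf.astype(float), has_constant="add")
    res = sm.OLS(ys.astype(float), design).fit()
    names = [str(c) for c in Xdf.columns]
    coefs = {nm: float(res.params[nm]) for nm in names}
    ses = {"(intercept)": float(res.bse["const"])}
    ses.update({nm: float(res.bse[nm]) for nm in names})
    s_y = float(ys.std(ddof=1))
    std_coefs = {
        nm: float(coefs[nm] * Xdf[nm].std(ddof=1) / s_y) for nm in names
    }
    fitted = res.fittedvalues.to_numpy()
    return MLRModel(
        descriptor_names=names,
        intercept=float(res.params["const"]),
        coefficients=coefs,
        std_errors=ses,
        standardized_coefficients=std_coefs,
        r2=float(res.rsquared),
        r2_adj=float(res.rsquared_adj),
        f_stat=float(res.fvalue),
        mae=float(mean_absolute_error(ys, fitted)),
        n_train=n,
    )


def predict_mlr(model: MLRModel, descriptors) -> np.ndarray:
    """Functional alias for :meth:`MLRModel.predict`."""
    return model.predict(descriptors)


# ---------------------------------------------------------------------------
# PLS with the component-increment stop rule
# ---------------------------------------------------------------------------

@dataclass
class PLSModel:
    """PLS regression chosen by a leave-one-out Q² increment rule."""

    n_components: int
    q2_trace: list[float]                 # Q²_LOO for 1..n_components
    estimator: PLSRegression = field(repr=False)
    descriptor_names: list[str] = field(default_factory=list)

    def predict(self, X) -> np.ndarray:
        if isinstance(X, DescriptorTable):
            X = X.X
        X = pd.DataFrame(X)
        if self.descriptor_names:
            X = X[self.descriptor_names]
        return self.estimator.predict(X.to_numpy(dtype=float)).ravel()

    def to_dict(self) -> dict:
        return {
            "schema_version": MODEL_SCHEMA_VERSION,
            "type": "PLS",
            "n_components": self.n_components,
            "q2_trace": self.q2_trace,
            "descriptor_names": self.descriptor_names,
        }


def _pls_q2_loo(X: np.ndarray, y: np.ndarray, k: int) -> float:
    """Leave-one-out Q² of a k-component PLS fit (explicit refits)."""
    n = len(y)
    press = 0.0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        est = PLSRegression(n_components=k, scale=True)
        est.fit(X[mask], y[mask])
        press += float(y[i] - est.predict(X[i : i + 1]).ravel()[0]) ** 2
    tss = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press / tss


def fit_pls(X, y=None, max_components: int = 5, min_gain: float = 0.05) -> PLSModel:
    """NIPALS PLS adding components while each improves Q²_LOO enough.

    The increment rule is relative when the running Q² is positive
    (``Q²_new >= Q²_old * (1 + min_gain)``) and absolute otherwise
    (``Q²_new >= Q²_old + min_gain``). Component count is further capped by
    ``max_components`` and the rank of the (centered) descriptor block.
    """
    Xdf, ys = _as_xy(X, y)
    n = len(ys)
    if n < 6:
        raise DomainError(f"PLS needs n >= 6, got {n}")
    yv = ys.to_numpy(dtype=float)
    if np.var(yv) == 0:
        raise DomainError("zero-variance response")
    Xv = Xdf.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(Xv - Xv.mean(axis=0))
    cap = int(min(max_components, rank))
    trace: list[float] = []
    chosen = 0
    for k in range(1, cap + 1):
        q2 = _pls_q2_loo(Xv, yv, k)
        if chosen == 0:
            trace.append(q2)
            chosen = 1
            continue
        prev = trace[-1]
        ok = q2 >= prev * (1.0 + min_gain) if prev > 0 else q2 >= prev + min_gain
        if not ok:
            break
        trace.append(q2)
        chosen = k
    est = PLSRegression(n_components=chosen, scale=True)
    est.fit(Xv, yv)
    return PLSModel(
        n_components=chosen,
        q2_trace=trace,
        estimator=est,
        descriptor_names=[str(c) for c in Xdf.columns],
    )


# ---------------------------------------------------------------------------
# Non-linear model tuning
# ---------------------------------------------------------------------------

DEFAULT_GRIDS: dict[str, dict] = {
    "MLP": {
        "hidden_layer_sizes": [(5,), (10,), (50,)],
        "activation": ["identity", "relu"],
        "solver": ["lbfgs"],
    },
    "RF": {
        "n_estimators": [100, 200],
        "max_depth": [10, 30, None],
        "max_features": ["sqrt"],
        "min_samples_leaf": [1, 2],
    },
    "SVM": {
        "C": [1.0, 10.0, 100.0],
        "gamma": ["scale", 1.0],
        "kernel": ["linear", "rbf"],
    },
}


@dataclass
class TunedRegressor:
    """Grid-search winner refit on the full training set."""

    method: str
    best_params: dict
    q2_cv: float                         # mean 5-fold CV R² of the winner
    estimator: object = field(repr=False)
    cv_results: dict = field(repr=False, default_factory=dict)
    r2_pred: float | None = None         # external test R², if a test set was given

    def predict(self, X) -> np.ndarray:
        if isinstance(X, DescriptorTable):
            X = X.values
        return self.estimator.predict(np.asarray(X, dtype=float))

    def to_dict(self) -> dict:
        return {
            "schema_version": MODEL_SCHEMA_VERSION,
            "type": f"tuned-{self.method}",
            "best_params": {k: repr(v) for k, v in self.best_params.items()},
            "q2_cv": self.q2_cv,
            "r2_pred": self.r2_pred,
        }


def _make_estimator(method: str, seed: int):
    if method == "MLP":
        return MLPRegressor(random_state=seed, max_iter=2000)
    if method == "RF":
        return RandomForestRegressor(random_state=seed)
    if method == "SVM":
        return SVR()
    raise ConfigError(f"unknown method {method!r}; valid: MLP, RF, SVM")


def tune_regressor(
    X,
    y=None,
    method: str = "SVM",
    grid: dict | None = None,
    cv: int = 5,
    seed: int = 42,
    X_test=None,
    y_test=None,
) -> TunedRegressor:
    """Exhaustive hyperparameter grid search scored by k-fold CV R².

    The winner is refit on the full training set; if a test set is supplied
    its external R² is reported as ``r2_pred``. Invalid hyperparameter names
    raise :class:`ConfigError` listing the valid keys.
    """
    Xdf, ys = _as_xy(X, y)
    base = _make_estimator(method, seed)
    grid = DEFAULT_GRIDS[method] if grid is None else grid
    if not grid:
        raise ConfigError("empty hyperparameter grid")
    valid = set(base.get_params())
    bad = [k for k in grid if k not in valid]
    if bad:
        raise ConfigError(
            f"invalid hyperparameters for {method}: {bad}; valid keys: {sorted(valid)}"
        )
    search = GridSearchCV(
        base,
        grid,
        scoring="r2",
        cv=KFold(n_splits=cv, shuffle=True, random_state=seed),
        refit=True,
    )
    search.fit(Xdf.to_numpy(dtype=float), ys.to_numpy(dtype=float))
    r2_pred = None
    if X_test is not None:
        if isinstance(X_test, DescriptorTable):
            X_test, y_test = X_test.values, X_test.activity
        r2_pred = float(r2_score(y_test, search.best_estimator_.predict(np.asarray(X_test, dtype=float))))
    return TunedRegressor(
        method=method,
        best_params=dict(search.best_params_),
        q2_cv=float(search.best_score_),
        estimator=search.best_estimator_,
        cv_results={
            "params": [dict(p) for p in search.cv_results_["params"]],
            "mean_test_score": [float(v) for v in search.cv_results_["mean_test_score"]],
        },
        r2_pred=r2_pred,
    )
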