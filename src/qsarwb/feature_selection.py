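"""Descriptor subset selection for MLR models: SFS grid and genetic algorithm.

Sequential forward selection (SFS) is deterministic: starting from the empty
set it greedily adds the descriptor that most improves the objective, scored
either on the training fit or by 5-fold cross-validation, with four scorers
(R², negative MAE, negative mean Poisson deviance, negative mean gamma
deviance) — a 4 × 2 grid of eight configurations per descriptor set.

The genetic algorithm evolves fixed-size-capped descriptor subsets with
one-point crossover and per-gene mutation, keeping an elite of survivors per
generation; it is stochastic, so it is repeated over several seeded runs and
the best run winner is chosen by overall predictivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import (
    mean_absolute_error,
    mean_gamma_deviance,
    mean_poisson_deviance,
    r2_score,
)
from sklearn.model_selection import KFold

from .dataset_io import DescriptorTable
from .exceptions import ConfigError, DomainError
from .models import MLRModel, fit_mlr

__all__ = [
    "SelectionConfig",
    "ModelCandidate",
    "sfs_mlr",
    "ga_mlr",
    "enumerate_configurations",
    "SCORING_FUNCTIONS",
]

SCORINGS = ("R2", "NMAE", "NMPD", "NMGD")
CV_OPTIONS = ("none", "5-fold")


def _score_r2(y, yhat):
    return r2_score(y, yhat)


def _score_nmae(y, yhat):
    return -mean_absolute_error(y, yhat)


def _score_nmpd(y, yhat):
    if np.any(y <= 0):
        raise DomainError("Poisson deviance needs strictly positive responses")
    if np.any(yhat <= 0):
        return -np.inf  # candidate predicts outside the domain; worst score
    return -mean_poisson_deviance(y, yhat)


def _score_nmgd(y, yhat):
    if np.any(y <= 0):
        raise DomainError("gamma deviance needs strictly positive responses")
    if np.any(yhat <= 0):
        return -np.inf
    return -mean_gamma_deviance(y, yhat)


SCORING_FUNCTIONS = {
    "R2": _score_r2,
    "NMAE": _score_nmae,
    "NMPD": _score_nmpd,
    "NMGD": _score_nmgd,
}


@dataclass(frozen=True)
class SelectionConfig:
    """Settings for one feature-selection run.

    GA parameters follow the conventional defaults of GA-MLR QSAR tools:
    population 100, 100 generations, crossover probability 1.0, mutation
    probability 0.3, 30 survivors per generation, at least 20 repeated runs.
    """

    method: str = "SFS"                     # SFS | GA
    scoring: str = "R2"                     # R2 | NMAE | NMPD | NMGD
    cv: str = "none"                        # none | 5-fold
    max_features: int = 8
    population: int = 100
    generations: int = 100
    p_crossover: float = 1.0
    p_mutation: float = 0.3
    survivors: int = 30
    n_runs: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.method not in ("SFS", "GA"):
            raise ConfigError(f"method must be SFS or GA, got {self.method!r}")
        if self.scoring not in SCORINGS:
            raise ConfigError(f"scoring must be one of {SCORINGS}, got {self.scoring!r}")
        if self.cv not in CV_OPTIONS:
            raise ConfigError(f"cv must be one of {CV_OPTIONS}, got {self.cv!r}")
        if self.max_features < 1:
            raise ConfigError("max_features must be >= 1")
        for name in ("p_crossover", "p_mutation"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.population < self.survivors:
            raise ConfigError(
                f"population ({self.population}) smaller than survivors ({self.survivors})"
            )


@dataclass
class ModelCandidate:
    """A selected descriptor subset with its fitted MLR model and score."""

    descriptor_names: list[str]
    model: MLRModel
    score: float
    config: SelectionConfig


class _SubsetScorer:
    """Scores descriptor index subsets; memoises results per subset."""

    def __init__(self, X: np.ndarray, y: np.ndarray, config: SelectionConfig):
        self.X = X
        self.y = y
        self.fn = SCORING_FUNCTIONS[config.scoring]
        self.cv = config.cv
        self.seed = config.seed
        self._cache: dict[frozenset, float] = {}
        if self.cv == "5-fold":
            kf = KFold(n_splits=5, shuffle=True, random_state=config.seed)
            self._folds = list(kf.split(X))

    def __call__(self, subset) -> float:
        key = frozenset(subset)
        if key in self._cache:
            return self._cache[key]
        cols = sorted(key)
        Xs = self.X[:, cols]
        try:
            if self.cv == "none":
                yhat = self._fit_predict(Xs, self.y, Xs)
                score = float(self.fn(self.y, yhat))
            else:
                scores = []
                for tr, te in self._folds:
                    yhat = self._fit_predict(Xs[tr], self.y[tr], Xs[te])
                    scores.append(float(self.fn(self.y[te], yhat)))
                score = float(np.mean(scores))
        except DomainError:
            raise
        except np.linalg.LinAlgError:
            score = -np.inf
        self._cache[key] = score
        return score

    @staticmethod
    def _fit_predict(Xtr, ytr, Xte) -> np.ndarray:
        Ztr = np.column_stack([np.ones(len(Xtr)), Xtr])
        beta, *_ = np.linalg.lstsq(Ztr, ytr, rcond=None)
        Zte = np.column_stack([np.ones(len(Xte)), Xte])
        return Zte @ beta


def _check_table(table: DescriptorTable, config: SelectionConfig) -> None:
    import warnings

    n = table.n_compounds
    if config.max_features > n / 5:
        warnings.warn(
            f"max_features={config.max_features} exceeds n/5={n / 5:.1f}; "
            "risk of overfitted subsets"
        )


def sfs_mlr(table: DescriptorTable, config: SelectionConfig) -> ModelCandidate:
    """Greedy sequential forward selection of descriptors for an MLR model.

    Adds one descriptor at a time (ties broken toward the lowest column
    index) until ``max_features`` is reached or no candidate improves the
    objective. Deterministic for a fixed input column order.
    """
    _check_table(table, config)
    X = table.values
    y = table.activity.to_numpy()
    scorer = _SubsetScorer(X, y, config)
    n_cols = X.shape[1]
    selected: list[int] = []
    best_score = -np.inf
    while len(selected) < min(config.max_features, n_cols):
        best_j, best_cand = None, -np.inf
        for j in range(n_cols):
            if j in selected:
                continue
            s = scorer(selected + [j])
            if s > best_cand:  # strict: first (lowest) index wins ties
                best_cand, best_j = s, j
        if best_j is None or best_cand <= best_score:
            break
        selected.append(best_j)
        best_score = best_cand
    names = [table.descriptor_names[j] for j in selected]
    model = fit_mlr(table.select(names))
    return ModelCandidate(descriptor_names=names, model=model, score=best_score, config=config)


# ---------------------------------------------------------------------------
# Genetic algorithm
# ---------------------------------------------------------------------------

def _random_subset(rng, n_cols: int, max_features: int) -> tuple:
    size = int(rng.integers(1, min(max_features, n_cols) + 1))
    return tuple(sorted(rng.choice(n_cols, size=size, replace=False).tolist()))


def _repair(genes: list[int], rng, n_cols: int) -> tuple:
    """Replace duplicate genes by redrawing from unused descriptors."""
    seen, out = set(), []
    for g in genes:
        if g in seen:
            unused = [c for c in range(n_cols) if c not in seen and c not in genes]
            if not unused:
                continue
            g = int(rng.choice(unused))
        seen.add(g)
        out.append(g)
    return tuple(sorted(out))


def _crossover(a: tuple, b: tuple, rng, n_cols: int) -> tuple:
    la, lb = list(a), list(b)
    k = int(rng.integers(0, min(len(la), len(lb)) + 1))
    child = la[:k] + lb[k:]
    return _repair(child, rng, n_cols)


def _mutate(genes: tuple, rng, n_cols: int, p: float) -> tuple:
    out = list(genes)
    for idx in range(len(out)):
        if rng.random() < p:
            unused = [c for c in range(n_cols) if c not in out]
            if unused:
                out[idx] = int(rng.choice(unused))
    return tuple(sorted(set(out)))


def _ga_single_run(X, y, config: SelectionConfig, rng) -> tuple[tuple, float]:
    """One GA run; returns (best subset, fitness)."""
    n_cols = X.shape[1]
    scorer = _SubsetScorer(X, y, config)
    pop = [_random_subset(rng, n_cols, config.max_features) for _ in range(config.population)]
    best, best_fit = None, -np.inf
    for _ in range(config.generations):
        fits = [scorer(ind) for ind in pop]
        order = np.argsort(-np.asarray(fits), kind="stable")
        elite = [pop[i] for i in order[: config.survivors]]
        if fits[order[0]] > best_fit:
            best, best_fit = pop[order[0]], fits[order[0]]
        children = list(elite)
        while len(children) < config.population:
            ia, ib = rng.choice(len(elite), size=2, replace=True)
            pa, pb = elite[int(ia)], elite[int(ib)]
            if rng.random() < config.p_crossover:
                child = _crossover(pa, pb, rng, n_cols)
            else:
                child = pa
            child = _mutate(child, rng, n_cols, config.p_mutation)
            if child:
                children.append(child)
        pop = children
    # final evaluation of the last generation
    for ind in pop:
        f = scorer(ind)
        if f > best_fit:
            best, best_fit = ind, f
    return best, best_fit


def ga_mlr(
    table: DescriptorTable,
    config: SelectionConfig,
    test: DescriptorTable | None = None,
) -> ModelCandidate:
    """GA descriptor selection repeated over seeded runs.

    Within a run: random initial subsets (size ≤ max_features), elitist
    selection of the top ``survivors``, refill by one-point crossover and
    per-gene mutation. Across ``n_runs`` runs (run r is seeded
    ``config.seed + r``), winners are re-ranked by the mean of Q²_LOO and —
    when a test table is supplied — the external R²_Pred; without a test
    table the ranking falls back to Q²_LOO alone.
    """
    from .validation import external_q2, q2_loo

    _check_table(table, config)
    X = table.values
    y = table.activity.to_numpy()
    run_winners: list[tuple] = []
    for r in range(config.n_runs):
        rng = np.random.default_rng(config.seed + r)
        subset, fitness = _ga_single_run(X, y, config, rng)
        run_winners.append((subset, fitness))

    best_names, best_model, best_rank, best_fit = None, None, -np.inf, -np.inf
    for subset, fitness in run_winners:
        names = [table.descriptor_names[j] for j in subset]
        try:
            model = fit_mlr(table.select(names))
            q2 = q2_loo(table.X[names].to_numpy(), y)
        except Exception:
            continue
        if test is not None:
            yhat = model.predict(test.X[names])
            f1, _, _, _ = external_q2(test.activity.to_numpy(), yhat, y)
            rank = (q2 + f1) / 2.0
        else:
            rank = q2
        if rank > best_rank:
            best_names, best_model, best_rank, best_fit = names, model, rank, fitness
    if best_model is None:
        raise DomainError("GA produced no fittable candidate")
    return ModelCandidate(
        descriptor_names=best_names, model=best_model, score=best_fit, config=config
    )


def enumerate_configurations(
    n_descriptor_sets: int, seed: int = 0
) -> list[tuple[int, SelectionConfig]]:
    """Cross product of descriptor sets with the 8 SFS + 1 GA configurations.

    Nine descriptor sets give the conventional 81-model screen. Ordering is
    stable: per set, SFS configs iterate scorers × CV options first, then
    the single GA config.
    """
    if n_descriptor_sets < 1:
        raise ConfigError("need at least one descriptor set")
    out: list[tuple[int, SelectionConfig]] = []
    for s in range(n_descriptor_sets):
        for scoring in SCORINGS:
            for cv in CV_OPTIONS:
                out.append((s, SelectionConfig(method="SFS", scoring=scoring, cv=cv, seed=seed)))
        out.append((s, SelectionConfig(method="GA", seed=seed)))
    return out
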