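"""Bayes maximum-likelihood decoding of food level from expression or lifespan readouts.

The decoder asks how accurately a readout encodes the categorical food
stimulus: class-conditional densities are fitted per food level on training
data (multivariate Gaussian for expression, Weibull for lifespan), posteriors
p(food | observation) are computed for held-out animals under k-fold
cross-validation, and each animal is assigned to the food with the highest
posterior.  Results are reported both as a probability matrix (mean posterior
mass per true food) and a maximum-likelihood confusion matrix (hard
assignment frequencies); overall accuracy above the chance floor 1/K
quantifies encoding fidelity.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .synthetic_data import NEURONS

logger = logging.getLogger(__name__)

#: ridge added to each covariance diagonal, as a fraction of trace/d
COV_EPSILON = 1e-6
#: Weibull shape cap for degenerate (zero-spread) samples
MAX_WEIBULL_SHAPE = 100.0


@dataclass
class ClassConditionalModel:
    """Per-food fitted density: Gaussian (mean vector, covariance) or Weibull (shape, scale)."""

    kind: str  # "gaussian" | "weibull"
    foods: list[str]  # ordered food labels
    params: dict[str, tuple]  # label -> (mean, cov) or (shape, scale)
    neuron_subset: tuple[str, ...] = ()
    prior: np.ndarray | None = None  # defaults to uniform

    def __post_init__(self) -> None:
        if self.prior is None:
            self.prior = np.full(len(self.foods), 1.0 / len(self.foods))
        self.prior = np.asarray(self.prior, dtype=float)
        if not np.isclose(self.prior.sum(), 1.0):
            raise ValueError("priors must sum to 1")

    def log_density(self, obs: np.ndarray) -> np.ndarray:
        """Log class-conditional density of one observation under each food."""
        return self.log_density_matrix(np.atleast_2d(obs))[0]

    def log_density_matrix(self, X: np.ndarray) -> np.ndarray:
        """(n, K) log densities for n observations under every food level."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty((X.shape[0], len(self.foods)))
        for i, label in enumerate(self.foods):
            if self.kind == "gaussian":
                mean, cov = self.params[label]
                out[:, i] = stats.multivariate_normal.logpdf(X, mean=mean, cov=cov)
            else:
                shape, scale = self.params[label]
                out[:, i] = stats.weibull_min.logpdf(X[:, 0], shape, loc=0, scale=scale)
        return out


@dataclass
class DecodingResult:
    """Cross-validated decoding summary for one readout set."""

    foods: list[str]
    prob_matrix: np.ndarray  # rows: true food; columns: mean posterior mass
    ml_matrix: np.ndarray  # rows: true food; columns: assignment frequency
    overall_accuracy: float
    per_food_accuracy: np.ndarray
    n_per_food: np.ndarray
    k_folds: int
    seed: int
    readout: str  # "expression" | "lifespan"
    neuron_subset: tuple[str, ...] = ()

    @property
    def accuracy_above_chance(self) -> float:
        return self.overall_accuracy - 1.0 / len(self.foods)

    def to_frames(self) -> dict[str, pd.DataFrame]:
        idx = pd.Index(self.foods, name="true_food")
        cols = pd.Index(self.foods, name="inferred_food")
        return {
            "prob_matrix": pd.DataFrame(self.prob_matrix, index=idx, columns=cols),
            "ml_matrix": pd.DataFrame(self.ml_matrix, index=idx, columns=cols),
            "accuracy": pd.DataFrame({
                "food_label": self.foods + ["overall"],
                "accuracy": list(self.per_food_accuracy) + [self.overall_accuracy],
                "n": list(self.n_per_food) + [int(self.n_per_food.sum())],
            }),
        }


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def fit_gaussian(train: pd.DataFrame, neuron_subset: tuple[str, ...],
                 covariance: str = "full",
                 prior: np.ndarray | None = None) -> ClassConditionalModel:
    """Per-food mean vector and (regularized) covariance of the selected neurons.

    Rows missing any subset neuron are dropped listwise. Each food level
    needs at least d + 2 complete rows (d = subset size). A ridge of
    ``COV_EPSILON * trace/d`` is added to the covariance diagonal so folds
    with nearly collinear readouts stay invertible.
    """
    neuron_subset = tuple(neuron_subset)
    if not neuron_subset:
        raise ValueError("neuron_subset must be non-empty")
    unknown = set(neuron_subset) - set(NEURONS)
    if unknown:
        raise ValueError(f"unknown neurons {sorted(unknown)}; expected subset of {NEURONS}")
    d = len(neuron_subset)
    foods = _ordered_foods(train)
    complete = train.dropna(subset=list(neuron_subset))
    params: dict[str, tuple] = {}
    for label in foods:
        X = complete.loc[complete.food_label == label, list(neuron_subset)].to_numpy(float)
        if len(X) < d + 2:
            raise ValueError(
                f"food level {label!r} has {len(X)} complete rows; need >= {d + 2}")
        mean = X.mean(axis=0)
        cov = np.cov(X, rowvar=False, ddof=1).reshape(d, d)
        cov = cov + np.eye(d) * (COV_EPSILON * np.trace(cov) / d)
        params[label] = (mean, cov)
    return ClassConditionalModel(kind="gaussian", foods=foods, params=params,
                                 neuron_subset=neuron_subset, prior=prior)


def fit_weibull(train: pd.DataFrame,
                prior: np.ndarray | None = None) -> ClassConditionalModel:
    """Per-food maximum-likelihood Weibull (shape, scale) on observed deaths.

    Censored rows are excluded (with a warning). A zero-spread sample drives
    the shape MLE to infinity; the shape is capped at ``MAX_WEIBULL_SHAPE``
    with a warning.
    """
    foods = _ordered_foods(train)
    if (train.event == 0).any():
        n_cens = int((train.event == 0).sum())
        warnings.warn(f"dropping {n_cens} censored rows from Weibull decoding fits")
    deaths = train[train.event == 1]
    params: dict[str, tuple] = {}
    for label in foods:
        ages = deaths.loc[deaths.food_label == label, "age_days"].to_numpy(float)
        if len(ages) < 5:
            raise ValueError(f"food level {label!r} has {len(ages)} death events; need >= 5")
        if np.ptp(ages) == 0:
            warnings.warn(f"degenerate lifespan sample at {label!r}; capping Weibull shape")
            params[label] = (MAX_WEIBULL_SHAPE, float(ages[0]))
            continue
        try:
            shape, _, scale = stats.weibull_min.fit(ages, floc=0)
        except Exception as exc:  # pragma: no cover - scipy failure path
            raise RuntimeError(f"Weibull fit failed for food level {label!r}: {exc}") from exc
        if not np.isfinite(shape) or not np.isfinite(scale) or shape <= 0 or scale <= 0:
            raise RuntimeError(f"Weibull fit did not converge for food level {label!r}")
        if shape > MAX_WEIBULL_SHAPE:
            warnings.warn(f"capping Weibull shape at {label!r}")
            shape = MAX_WEIBULL_SHAPE
        params[label] = (float(shape), float(scale))
    return ClassConditionalModel(kind="weibull", foods=foods, params=params, prior=prior)


def conditional_probs(model: ClassConditionalModel, observation) -> np.ndarray:
    """Posterior p(food | observation), proportional to prior x density.

    Densities are combined in log space. If every class density underflows
    to zero the posterior falls back to uniform (with a warning).
    """
    obs = np.atleast_1d(np.asarray(observation, dtype=float))
    if model.kind == "gaussian" and obs.shape[-1] != len(model.neuron_subset):
        raise ValueError(
            f"observation has dimension {obs.shape[-1]}; model expects {len(model.neuron_subset)}")
    logp = model.log_density(obs if model.kind == "gaussian" else obs[0])
    logp = logp + np.log(model.prior)
    if not np.isfinite(logp).any():
        warnings.warn("all class densities underflowed; returning uniform posterior")
        return np.full(len(model.foods), 1.0 / len(model.foods))
    return np.exp(logp - logsumexp(logp))


def ml_assign(posterior: np.ndarray) -> int:
    """Index of the food with the highest posterior; ties break to the lower index."""
    posterior = np.asarray(posterior, dtype=float)
    if not np.isclose(posterior.sum(), 1.0, atol=1e-6):
        raise ValueError("posterior must sum to 1")
    return int(np.argmax(posterior))


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def _ordered_foods(table: pd.DataFrame) -> list[str]:
    order = table[["food_label", "food_cells_per_ml"]].drop_duplicates()
    return list(order.sort_values("food_cells_per_ml").food_label)


def _canonical_sort(table: pd.DataFrame, value_cols: list[str]) -> pd.DataFrame:
    # fold assignment must not depend on input row order
    return table.sort_values(["food_label", "animal_id", *value_cols],
                             kind="mergesort").reset_index(drop=True)


def stratified_folds(table: pd.DataFrame, value_cols: list[str], k: int,
                     seed: int) -> tuple[pd.DataFrame, np.ndarray]:
    """Canonically ordered table plus a per-row fold id, stratified by food.

    Within each food group, rows (in canonical order) are permuted with a
    seeded generator and dealt round-robin into k folds, so every fold holds
    roughly n/k animals of every food level.
    """
    table = _canonical_sort(table, value_cols)
    folds = np.full(len(table), -1, dtype=int)
    rng = np.random.default_rng(seed)
    for label in _ordered_foods(table):
        idx = np.flatnonzero((table.food_label == label).to_numpy())
        if len(idx) < k:
            raise ValueError(
                f"food level {label!r} has {len(idx)} rows; cannot stratify into {k} folds")
        perm = rng.permutation(len(idx))
        folds[idx[perm]] = np.arange(len(idx)) % k
    return table, folds


def crossval_decode(data: pd.DataFrame, *, readout: str = "expression",
                    neuron_subset: tuple[str, ...] = tuple(NEURONS), k: int = 5,
                    seed: int = 0, covariance: str = "full",
                    prior: str = "uniform",
                    return_details: bool = False,
                    _precomputed: tuple[pd.DataFrame, np.ndarray] | None = None
                    ):
    """k-fold cross-validated Bayes decoding of food level.

    Folds are stratified by food level. For each fold the class-conditional
    model is fitted on the complement and posteriors computed for the held-out
    animals; the probability matrix row for true food f is the mean posterior
    vector of its animals, the ML matrix row the frequencies of hard argmax
    assignments.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if readout == "expression":
        neuron_subset = tuple(neuron_subset)
        value_cols = list(neuron_subset)
        data = data.dropna(subset=value_cols)
    elif readout == "lifespan":
        value_cols = ["age_days"]
        n_cens = int((data.event == 0).sum())
        if n_cens:
            warnings.warn(f"dropping {n_cens} censored rows before lifespan decoding")
            data = data[data.event == 1]
    else:
        raise ValueError(f"unknown readout {readout!r}")

    if _precomputed is None:
        table, folds = stratified_folds(data, value_cols, k, seed)
    else:
        table, folds = _precomputed

    foods = _ordered_foods(table)
    K = len(foods)
    food_index = {label: i for i, label in enumerate(foods)}
    true_idx = table.food_label.map(food_index).to_numpy()
    posteriors = np.empty((len(table), K))

    for fold in range(k):
        test_mask = folds == fold
        train = table[~test_mask]
        if readout == "expression":
            model = fit_gaussian(train, neuron_subset, covariance=covariance,
                                 prior=_prior_vector(prior, train, foods))
            X = table.loc[test_mask, value_cols].to_numpy(float)
        else:
            model = fit_weibull(train, prior=_prior_vector(prior, train, foods))
            X = table.loc[test_mask, value_cols].to_numpy(float)
        rows = np.flatnonzero(test_mask)
        logp = model.log_density_matrix(X) + np.log(model.prior)
        bad = ~np.isfinite(logp).any(axis=1)
        if bad.any():
            warnings.warn("all class densities underflowed for some animals; "
                          "using uniform posteriors")
            logp[bad] = 0.0
        posteriors[rows] = np.exp(logp - logsumexp(logp, axis=1, keepdims=True))

    assignments = np.array([ml_assign(p) for p in posteriors])
    prob_matrix = np.zeros((K, K))
    ml_matrix = np.zeros((K, K))
    n_per_food = np.zeros(K, dtype=int)
    for f in range(K):
        mask = true_idx == f
        n_per_food[f] = int(mask.sum())
        prob_matrix[f] = posteriors[mask].mean(axis=0)
        ml_matrix[f] = np.bincount(assignments[mask], minlength=K) / mask.sum()
    per_food_accuracy = np.diag(ml_matrix).copy()
    overall = float((n_per_food * per_food_accuracy).sum() / n_per_food.sum())
    result = DecodingResult(
        foods=foods, prob_matrix=prob_matrix, ml_matrix=ml_matrix,
        overall_accuracy=overall, per_food_accuracy=per_food_accuracy,
        n_per_food=n_per_food, k_folds=k, seed=seed, readout=readout,
        neuron_subset=neuron_subset if readout == "expression" else ())
    if return_details:
        return result, {"table": table, "folds": folds, "posteriors": posteriors,
                        "assignments": assignments}
    return result


def _prior_vector(kind: str, train: pd.DataFrame, foods: list[str]) -> np.ndarray:
    if kind == "uniform":
        return np.full(len(foods), 1.0 / len(foods))
    if kind == "empirical":
        counts = train.food_label.value_counts()
        vec = np.array([counts.get(f, 0) for f in foods], dtype=float)
        return vec / vec.sum()
    raise ValueError(f"unknown prior kind {kind!r}")


# ---------------------------------------------------------------------------
# Neuron subsets
# ---------------------------------------------------------------------------

FUNCTIONAL_SUBSETS = {
    "wildtype": ("NSM", "ADF", "ASI"),
    "tph1_null": ("ASI",),
    "daf7_null": ("NSM", "ADF"),
    "double_null": (),
}


def functional_subset(genotype: str) -> tuple[str, ...]:
    """Neurons whose underlying gene is intact in the genotype.

    A mutant's reporter still fluoresces, but only intact genes constitute
    physiological readouts; the double mutant retains none, so its functional
    decoding accuracy is defined as the chance floor 1/K.
    """
    try:
        return FUNCTIONAL_SUBSETS[genotype]
    except KeyError:
        raise KeyError(
            f"unknown genotype {genotype!r}; known: {sorted(FUNCTIONAL_SUBSETS)}") from None


def chance_result(foods: list[str], n_per_food: np.ndarray, k: int, seed: int) -> DecodingResult:
    """Degenerate result for an empty readout set: uniform matrices, accuracy 1/K."""
    K = len(foods)
    uniform = np.full((K, K), 1.0 / K)
    return DecodingResult(
        foods=list(foods), prob_matrix=uniform.copy(), ml_matrix=uniform.copy(),
        overall_accuracy=1.0 / K, per_food_accuracy=np.full(K, 1.0 / K),
        n_per_food=np.asarray(n_per_food, dtype=int), k_folds=k, seed=seed,
        readout="expression", neuron_subset=())


def all_neuron_subsets() -> list[tuple[str, ...]]:
    """The 7 non-empty subsets of {NSM, ADF, ASI}, singletons first."""
    subsets = []
    for r in (1, 2, 3):
        subsets.extend(itertools.combinations(NEURONS, r))
    return subsets


def subset_sweep(data: pd.DataFrame, *, k: int = 5, seed: int = 0,
                 covariance: str = "full", prior: str = "uniform"
                 ) -> dict[tuple[str, ...], DecodingResult]:
    """Cross-validated decoding per non-empty neuron subset with shared folds.

    Rows are restricted to complete cases across all three neurons and folds
    are assigned once, so subset accuracies are directly comparable.
    """
    complete = data.dropna(subset=list(NEURONS))
    table, folds = stratified_folds(complete, list(NEURONS), k, seed)
    results = {}
    for subset in all_neuron_subsets():
        results[subset] = crossval_decode(
            table, readout="expression", neuron_subset=subset, k=k, seed=seed,
            covariance=covariance, prior=prior, _precomputed=(table, folds))
    return results
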