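"""Feature-combination weights: closed-form least squares per image and a
real-coded genetic algorithm per dataset.

Per image, the density map D is regressed on the three flattened feature
maps: W_best = (X^T X)^{-1} X^T D -- the literal normal-equations solution,
unconstrained, so weights may be negative.

Per dataset, a genetic algorithm searches for a single *static* weight
triple maximizing the mean fixation AUC of the combined map across all
images.  The population holds 60 three-gene chromosomes; the 30 best are
parents of the next generation; diversity is kept by random re-injection.
Because AUC is rank-based, the fitness is invariant to positive rescaling
of a chromosome, so only the direction of the weight vector is identified.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .density import DensityMap, SaccadicMap
from .errors import DataValidationError, DimensionError, SingularFeatureMatrixError
from .features import FEATURE_ORDER, FeatureMap, WeightVector, _maps_in_order
from .metrics import _positive_mask, auc_many

__all__ = [
    "FeatureMatrix",
    "GAConfig",
    "GAResult",
    "flatten_features",
    "lse_weights",
    "evaluate_weights",
    "ga_optimize",
]


@dataclass
class FeatureMatrix:
    """(n_rows * n_cols) x 3 stack of flattened maps, columns in
    (color, intensity, orientation) order, rows in row-major raster order."""

    values: np.ndarray
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 3:
            raise DimensionError("feature matrix must be (n_pixels, 3)")
        if self.values.shape[0] != self.n_rows * self.n_cols:
            raise DimensionError("feature matrix rows disagree with map size")
        if not np.all(np.isfinite(self.values)):
            raise DataValidationError("feature matrix must be finite")

    def reshape_column(self, k: int) -> np.ndarray:
        return self.values[:, k].reshape(self.n_rows, self.n_cols)


def flatten_features(
    maps: Mapping[str, FeatureMap] | Sequence[FeatureMap],
) -> FeatureMatrix:
    """Stack three same-shape feature maps as the columns of X."""
    ordered = _maps_in_order(maps)
    h, w = ordered[0].shape
    cols = [m.values.ravel() for m in ordered]
    return FeatureMatrix(np.column_stack(cols), n_rows=h, n_cols=w)


def _flat_target(D, n_pixels: int) -> np.ndarray:
    if isinstance(D, DensityMap):
        d = D.values.ravel()
    else:
        d = np.asarray(D, dtype=float).ravel()
    if d.size != n_pixels:
        raise DimensionError(
            f"target has {d.size} pixels, feature matrix has {n_pixels}"
        )
    if not np.all(np.isfinite(d)):
        raise DataValidationError("regression target must be finite")
    return d


def lse_weights(X: FeatureMatrix, D) -> WeightVector:
    """Unconstrained least-squares weights W_best = (X^T X)^{-1} X^T D.

    Raises :class:`SingularFeatureMatrixError` (naming the most collinear
    column pair) when the three maps are numerically linearly dependent.
    """
    d = _flat_target(D, X.values.shape[0])
    gram = X.values.T @ X.values
    if np.linalg.cond(gram) > 1e12:
        norms = np.sqrt(np.diag(gram))
        norms[norms == 0] = 1.0
        corr = gram / np.outer(norms, norms)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        pair = (FEATURE_ORDER[min(i, j)], FEATURE_ORDER[max(i, j)])
        raise SingularFeatureMatrixError(
            f"feature matrix is rank deficient; columns {pair[0]!r} and "
            f"{pair[1]!r} are (near-)collinear",
            collinear=pair,
        )
    w = np.linalg.solve(gram, X.values.T @ d)
    return WeightVector.from_array(w, constrained=False)


# ---------------------------------------------------------------------------
# genetic algorithm
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GAConfig:
    """Knobs of the real-coded genetic optimizer.

    The population/parent/gene counts and the 10-run averaging are the
    method's fixed structure; crossover and mutation operators, elitism,
    random injection, the gene bounds and the stopping rule are
    implementation choices, all logged with the run.
    """

    population_size: int = 60
    n_parents: int = 30
    generations: int = 100
    mutation_rate: float = 0.1
    mutation_sd: float = 0.1
    crossover_kind: str = "blend"
    random_inject_fraction: float = 0.1
    weight_bounds: tuple[float, float] = (0.0, 2.0)
    seed: int = 0
    n_runs: int = 10
    n_elite: int = 1
    stagnation_patience: int = 20

    n_genes: int = 3  # one weight per channel; fixed by the model

    def __post_init__(self) -> None:
        if self.population_size % 2 != 0 or self.population_size < 4:
            raise ValueError("population_size must be even and >= 4")
        if not (0 < self.n_parents <= self.population_size):
            raise ValueError("n_parents must be in (0, population_size]")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.weight_bounds[0] >= self.weight_bounds[1]:
            raise ValueError("weight bounds must be an increasing pair")
        if not (0 <= self.random_inject_fraction < 1):
            raise ValueError("random_inject_fraction must be in [0, 1)")


@dataclass
class GAResult:
    """Outcome of the seeded runs of the genetic optimizer."""

    best_weights: list[WeightVector]
    best_fitness: list[float]
    trajectories: list[list[float]]  # best-so-far mean AUC per generation
    mean_weights: WeightVector
    mean_fitness: float
    config: GAConfig


def _prepare_dataset(dataset) -> list[tuple[np.ndarray, np.ndarray]]:
    if not dataset:
        raise DataValidationError("GA dataset is empty")
    items = []
    for idx, (maps, positives) in enumerate(dataset):
        X = maps if isinstance(maps, FeatureMatrix) else flatten_features(maps)
        shape = (X.n_rows, X.n_cols)
        if isinstance(positives, SaccadicMap):
            mask = positives.values.astype(bool)
        else:
            mask = _positive_mask(positives, shape)
        flat = mask.ravel()
        if flat.sum() == 0:
            raise DataValidationError(f"dataset item {idx} has no positive pixels")
        if flat.all():
            raise DataValidationError(f"dataset item {idx} has no negative pixels")
        items.append((X.values, flat))
    return items


def _population_fitness(
    items: list[tuple[np.ndarray, np.ndarray]], population: np.ndarray
) -> np.ndarray:
    """Mean fixation AUC over images for each chromosome (rows of population)."""
    total = np.zeros(population.shape[0])
    W = population.T  # (3, k)
    for X, mask in items:
        sal = np.clip(X @ W, 0.0, None)  # combined-map semantics: rectified
        total += auc_many(sal, mask)
    return total / len(items)


def evaluate_weights(dataset, weights) -> float:
    """Mean over images of the fixation AUC of the combined map."""
    items = _prepare_dataset(dataset)
    w = weights.as_array() if isinstance(weights, WeightVector) else np.asarray(
        weights, dtype=float
    )
    return float(_population_fitness(items, w.reshape(1, 3))[0])


def _ga_single_run(
    items: list[tuple[np.ndarray, np.ndarray]],
    cfg: GAConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float, list[float]]:
    lo, hi = cfg.weight_bounds
    pop = rng.uniform(lo, hi, size=(cfg.population_size, cfg.n_genes))
    fitness = _population_fitness(items, pop)
    trajectory: list[float] = []
    best_fit = float(fitness.max())
    best_w = pop[int(fitness.argmax())].copy()
    stagnant = 0
    n_inject = int(round(cfg.random_inject_fraction * cfg.population_size))
    n_children = cfg.population_size - cfg.n_elite - n_inject
    for _ in range(cfg.generations):
        order = np.argsort(-fitness, kind="stable")
        parents = pop[order[: cfg.n_parents]]
        elite = pop[order[: cfg.n_elite]]
        pair_idx = rng.integers(0, cfg.n_parents, size=(n_children, 2))
        blend = rng.uniform(size=(n_children, cfg.n_genes))
        children = (
            blend * parents[pair_idx[:, 0]] + (1 - blend) * parents[pair_idx[:, 1]]
        )
        mutate = rng.uniform(size=children.shape) < cfg.mutation_rate
        children = children + mutate * rng.normal(
            0.0, cfg.mutation_sd, size=children.shape
        )
        children = np.clip(children, lo, hi)
        injected = rng.uniform(lo, hi, size=(n_inject, cfg.n_genes))
        pop = np.vstack([elite, children, injected])
        fitness = _population_fitness(items, pop)
        gen_best = float(fitness.max())
        if gen_best > best_fit + 1e-9:
            best_fit = gen_best
            best_w = pop[int(fitness.argmax())].copy()
            stagnant = 0
        else:
            stagnant += 1
        trajectory.append(best_fit)
        if stagnant >= cfg.stagnation_patience:
            break
    return best_w, best_fit, trajectory


def ga_optimize(dataset, cfg: GAConfig | None = None) -> GAResult:
    """Run the genetic optimizer ``cfg.n_runs`` times and average.

    Every run is independently seeded from ``cfg.seed`` and fully
    deterministic; elitism makes the best-so-far fitness trajectory
    non-decreasing within each run.
    """
    cfg = cfg or GAConfig()
    items = _prepare_dataset(dataset)
    best_ws, best_fs, trajs = [], [], []
    for run in range(cfg.n_runs):
        rng = np.random.default_rng([cfg.seed, run])
        w, f, traj = _ga_single_run(items, cfg, rng)
        best_ws.append(WeightVector.from_array(w, constrained=True))
        best_fs.append(f)
        trajs.append(traj)
    mean_w = WeightVector.from_array(
        np.mean([w.as_array() for w in best_ws], axis=0), constrained=True
    )
    return GAResult(
        best_weights=best_ws,
        best_fitness=best_fs,
        trajectories=trajs,
        mean_weights=mean_w,
        mean_fitness=float(np.mean(best_fs)),
        config=cfg,
    )
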