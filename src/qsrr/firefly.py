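"""Binary firefly-algorithm wrapper feature selection.

Each firefly is a point in [0, 1]^p decoded to a descriptor subset by
thresholding at 0.5; its brightness is the inverse of the cross-validated
RMSE of an epsilon-SVR model fitted on the decoded subset of the training
rows.  Fireflies move toward every brighter firefly with the canonical
distance-decaying attractiveness

    beta(r) = beta0 * exp(-gamma_abs * r^2),

plus an alpha-weighted uniform random perturbation that guards against local
optima.  The number of fireflies controls exploration, the number of
generations exploitation.  The incumbent best subset is tracked separately
(elitism), so the best fitness is non-increasing over generations, and
fitness values are cached by mask bit-pattern -- the CV x SVR evaluation is
the cost center.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .dataset import QSRRDataset
from .svr import SVRConfig
from .validation import CVScheme, cv_rmse

__all__ = [
    "FireflyConfig",
    "FireflySwarm",
    "SelectionResult",
    "attractiveness",
    "move_firefly",
    "decode_mask",
    "fitness",
    "select_descriptors",
    "QUINOLONE_FFA_PROFILE",
    "SULFONAMIDE_FFA_PROFILE",
]


@dataclass(frozen=True)
class FireflyConfig:
    n_fireflies: int = 10
    generations: int = 100
    alpha: float = 0.1        # randomization weight
    beta0: float = 1.0        # attractiveness at zero distance
    gamma_abs: float = 0.01   # light absorption coefficient
    seed: int = 0
    min_descriptors: int = 1
    max_descriptors: int | None = None

    def __post_init__(self) -> None:
        if self.n_fireflies < 1 or self.generations < 1:
            raise ValueError("counts must be >= 1")
        if self.alpha < 0 or self.gamma_abs < 0:
            raise ValueError("alpha and gamma_abs must be >= 0")
        if self.min_descriptors < 1:
            raise ValueError("min_descriptors must be >= 1")


#: tuned profiles for the two packaged study sizes
QUINOLONE_FFA_PROFILE = FireflyConfig(n_fireflies=10, generations=100,
                                      alpha=0.10, beta0=1.0, gamma_abs=0.01)
SULFONAMIDE_FFA_PROFILE = FireflyConfig(n_fireflies=20, generations=100,
                                        alpha=0.15, beta0=1.0, gamma_abs=0.01)


@dataclass
class FireflySwarm:
    positions: np.ndarray             # (n_fireflies, p) in [0,1]
    masks: np.ndarray                 # (n_fireflies, p) bool
    fitnesses: np.ndarray             # RMSE_CV per firefly
    best_mask: np.ndarray
    best_fitness: float
    history: list[float] = field(default_factory=list)


@dataclass
class SelectionResult:
    selected_descriptor_names: list[str]
    selected_mask: np.ndarray
    final_fitness: float              # RMSE_CV of the best subset
    history: list[float]              # best fitness per generation
    config: FireflyConfig
    seed: int
    n_fitness_evaluations: int
    n_cache_hits: int


def attractiveness(beta0: float, gamma_abs: float, r: float) -> float:
    """beta(r) = beta0 * exp(-gamma_abs * r^2)."""
    if r < 0:
        raise ValueError("distance must be >= 0")
    return float(beta0 * np.exp(-gamma_abs * r * r))


def move_firefly(
    x_i: np.ndarray,
    x_j: np.ndarray,
    config: FireflyConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Move firefly i toward brighter firefly j; result clipped to [0,1]^p."""
    x_i = np.asarray(x_i, float)
    x_j = np.asarray(x_j, float)
    if x_i.shape != x_j.shape:
        raise ValueError("positions must have equal length")
    r = float(np.linalg.norm(x_j - x_i))
    beta = attractiveness(config.beta0, config.gamma_abs, r)
    u = rng.uniform(size=x_i.shape)
    x_new = x_i + beta * (x_j - x_i) + config.alpha * (u - 0.5)
    return np.clip(x_new, 0.0, 1.0)


def decode_mask(position: np.ndarray, min_descriptors: int = 1,
                max_descriptors: int | None = None) -> np.ndarray:
    """Binary mask: coordinate > 0.5 is on.

    If fewer than ``min_descriptors`` bits are set, the top coordinates by
    value are forced on (ties to the lower index); if more than
    ``max_descriptors`` are set, only the top ``max_descriptors`` survive.
    """
    position = np.asarray(position, float)
    mask = position > 0.5
    k = int(mask.sum())
    if k < min_descriptors:
        # stable argsort descending: lower index wins exact ties
        order = np.argsort(-position, kind="stable")
        mask = np.zeros_like(mask)
        mask[order[:min_descriptors]] = True
    elif max_descriptors is not None and k > max_descriptors:
        on = np.flatnonzero(mask)
        order = on[np.argsort(-position[on], kind="stable")]
        mask = np.zeros_like(mask)
        mask[order[:max_descriptors]] = True
    return mask


def fitness(
    mask: np.ndarray,
    dataset: QSRRDataset,
    svr_config: SVRConfig,
    cv_scheme: CVScheme,
    cache: dict[bytes, float] | None = None,
    counters: dict[str, int] | None = None,
) -> float:
    """RMSE_CV of an SVR on the masked training columns; +inf on degeneracy."""
    mask = np.asarray(mask, bool)
    if mask.sum() < 1:
        raise ValueError("mask selects no descriptors")
    key = np.packbits(mask).tobytes()
    if cache is not None and key in cache:
        if counters is not None:
            counters["cache_hits"] = counters.get("cache_hits", 0) + 1
        return cache[key]
    try:
        value = cv_rmse(dataset, mask, svr_config, cv_scheme)
        if not np.isfinite(value):
            value = np.inf
    except (ValueError, np.linalg.LinAlgError):
        value = np.inf
    if cache is not None:
        cache[key] = value
    if counters is not None:
        counters["evaluations"] = counters.get("evaluations", 0) + 1
    return value


def select_descriptors(
    dataset: QSRRDataset,
    ffa_config: FireflyConfig = QUINOLONE_FFA_PROFILE,
    svr_config: SVRConfig = SVRConfig(),
    cv_scheme: CVScheme = CVScheme("leave_one_out"),
    progress: Callable[[int, float, int], None] | None = None,
) -> SelectionResult:
    """Run the firefly wrapper and return the best descriptor subset found.

    Positions start uniform on [0,1]^p.  Each generation every firefly moves
    toward every brighter one (lower RMSE_CV = brighter; ties to the lower
    index) in fitness-sorted order; the incumbent best firefly takes only its
    randomization step.  Returns the best mask ever evaluated.
    ``progress(generation, best_fitness, best_mask_size)`` is called once per
    generation when given.
    """
    p = dataset.p
    if p == 0:
        raise ValueError("dataset has no descriptors")
    if not dataset.train_mask.any():
        raise ValueError("dataset has no training rows; assign a split first")
    cfg = ffa_config
    rng = np.random.default_rng(cfg.seed)
    cache: dict[bytes, float] = {}
    counters: dict[str, int] = {}

    def evaluate(position: np.ndarray) -> tuple[np.ndarray, float]:
        mask = decode_mask(position, cfg.min_descriptors, cfg.max_descriptors)
        return mask, fitness(mask, dataset, svr_config, cv_scheme, cache, counters)

    positions = rng.uniform(size=(cfg.n_fireflies, p))
    masks = np.zeros((cfg.n_fireflies, p), dtype=bool)
    fits = np.empty(cfg.n_fireflies)
    for i in range(cfg.n_fireflies):
        masks[i], fits[i] = evaluate(positions[i])

    best_i = int(np.argmin(fits))
    best_mask = masks[best_i].copy()
    best_fit = float(fits[best_i])
    history: list[float] = []

    for gen in range(cfg.generations):
        # brighter = lower RMSE_CV; stable sort breaks ties by lower index
        order = np.argsort(fits, kind="stable")
        new_positions = positions.copy()
        for rank_i, i in enumerate(order):
            if rank_i == 0:
                # incumbent: randomization step only (elitist best kept aside)
                u = rng.uniform(size=p)
                new_positions[i] = np.clip(
                    positions[i] + cfg.alpha * (u - 0.5), 0.0, 1.0
                )
                continue
            x = positions[i].copy()
            for j in order[:rank_i]:  # every brighter firefly
                x = move_firefly(x, positions[j], cfg, rng)
            new_positions[i] = x
        positions = new_positions
        for i in range(cfg.n_fireflies):
            masks[i], fits[i] = evaluate(positions[i])
        gen_best = int(np.argmin(fits))
        if fits[gen_best] < best_fit:
            best_fit = float(fits[gen_best])
            best_mask = masks[gen_best].copy()
        history.append(best_fit)
        if progress is not None:
            progress(gen, best_fit, int(best_mask.sum()))

    names = [dataset.descriptor_names[j] for j in np.flatnonzero(best_mask)]
    return SelectionResult(
        selected_descriptor_names=names,
        selected_mask=best_mask,
        final_fitness=best_fit,
        history=history,
        config=cfg,
        seed=cfg.seed,
        n_fitness_evaluations=counters.get("evaluations", 0),
        n_cache_hits=counters.get("cache_hits", 0),
    )
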