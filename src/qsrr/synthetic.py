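"""Synthetic descriptor/response generator.

Emulates the statistical shape of a molecular-descriptor QSRR problem: many
mutually correlated nuisance descriptors, a handful of informative ones
driving a smooth nonlinear response, additive Gaussian noise, and (optionally)
a mobile-phase composition covariate with a monotone effect on retention.
Everything is deterministic given the seed.

Two "paper-like" instance profiles are provided, sized like the two studies
the pipeline ships fixtures for: a quinolone-like instance (n=21 observations,
293 descriptors after variance filtering, 5 informative) and a
sulfonamide-like instance (n=39, 112 descriptors + acetonitrile-percentage
covariate, 2 informative + covariate).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .dataset import QSRRDataset, TRAIN, TEST

__all__ = [
    "SyntheticSpec",
    "SyntheticDataset",
    "generate_descriptors",
    "generate_response",
    "make_paper_like_instance",
    "make_planted_instance",
    "stratified_split",
]

#: acetonitrile levels (volume percent) used by the covariate mode
ACN_LEVELS = (30.0, 45.0, 50.0)


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic QSRR instance.

    noise_sd is in retention-factor units; auto-drawn nonlinear responses are
    rescaled to a k-like location/scale (mean ~1.2, SD ~0.5, matching the
    packaged retention tables) so the default noise_sd = 0.05 is ~10% of the
    signal SD.
    """

    n: int
    p: int
    informative_idx: tuple[int, ...]
    block_correlation: float = 0.0
    block_size: int = 10
    link: Literal["linear", "rbf_mixture"] = "rbf_mixture"
    noise_sd: float = 0.05
    covariate_mode: Literal["none", "mobile_phase_percent"] = "none"
    n_centers: int = 3
    response_loc: float = 1.2
    response_scale: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.informative_idx = tuple(int(i) for i in self.informative_idx)
        if self.n < 4 or self.p < 2:
            raise ValueError("need n >= 4 and p >= 2")
        if not (1 <= len(self.informative_idx) < self.p):
            raise ValueError("need 1 <= |informative_idx| < p")
        if any(not 0 <= i < self.p for i in self.informative_idx):
            raise ValueError("informative_idx out of range")
        if not 0 <= self.block_correlation < 1:
            raise ValueError("block_correlation must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class GroundTruth:
    informative_idx: tuple[int, ...]
    link: str
    noiseless_y: np.ndarray
    beta: np.ndarray | None = None          # linear link
    centers: np.ndarray | None = None       # rbf_mixture link
    weights: np.ndarray | None = None
    lengthscale: float | None = None
    scale: tuple[float, float] | None = None  # (a, b) in y = a*g(x) + b
    covariate_effect: float | None = None


@dataclass
class SyntheticDataset:
    dataset: QSRRDataset
    ground_truth: GroundTruth
    spec: SyntheticSpec


def generate_descriptors(spec: SyntheticSpec,
                         rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw an (n, p) standard-normal descriptor matrix in correlated blocks.

    Columns are grouped into consecutive blocks of ``block_size``; within a
    block every pair of columns has correlation ``block_correlation`` (one
    shared factor per block: x = sqrt(rho)*z_block + sqrt(1-rho)*e).
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    rho = spec.block_correlation
    X = np.empty((spec.n, spec.p))
    for start in range(0, spec.p, spec.block_size):
        width = min(spec.block_size, spec.p - start)
        shared = rng.standard_normal((spec.n, 1))
        noise = rng.standard_normal((spec.n, width))
        X[:, start:start + width] = np.sqrt(rho) * shared + np.sqrt(1 - rho) * noise
    if spec.covariate_mode == "mobile_phase_percent":
        # last column: mobile-phase percentage, three levels scaled to [0, 1]
        levels = np.asarray(ACN_LEVELS)
        reps = np.resize(levels, spec.n)
        lo, hi = levels.min(), levels.max()
        X[:, -1] = (reps - lo) / (hi - lo)
    return X


def _rbf_mixture(X_inf: np.ndarray, centers: np.ndarray, weights: np.ndarray,
                 lengthscale: float) -> np.ndarray:
    d2 = ((X_inf[:, None, :] - centers[None, :, :]) ** 2).sum(axis=-1)
    return (weights * np.exp(-d2 / (2.0 * lengthscale ** 2))).sum(axis=1)


def generate_response(
    X: np.ndarray,
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
    *,
    beta: np.ndarray | None = None,
    centers: np.ndarray | None = None,
    weights: np.ndarray | None = None,
    lengthscale: float | None = None,
) -> tuple[np.ndarray, GroundTruth]:
    """Build a response from the informative columns of ``X``.

    linear link:       y = X beta + eps, beta nonzero only on informative_idx.
    rbf_mixture link:  y = sum_m w_m exp(-||x_S - c_m||^2 / (2 l^2)) + eps over
    the informative sub-vector x_S, with centers drawn from the data rows and
    l = median pairwise distance of the informative sub-vectors.  When the
    mixture is auto-drawn it is affinely rescaled to a retention-factor-like
    location/scale; explicitly supplied centers/weights are used raw.  The
    mobile-phase covariate (when present) adds a monotone decreasing term,
    mimicking faster elution at higher organic-modifier percentage.
    """
    rng = np.random.default_rng(spec.seed + 1) if rng is None else rng
    idx = list(spec.informative_idx)
    X_inf = X[:, idx]
    explicit = centers is not None or weights is not None or beta is not None

    if spec.link == "linear":
        if beta is None:
            b_inf = rng.uniform(0.5, 1.5, size=len(idx)) * rng.choice([-1, 1], len(idx))
            beta = np.zeros(X.shape[1])
            beta[idx] = b_inf
        noiseless = X @ beta
        truth = GroundTruth(tuple(idx), "linear", None, beta=np.asarray(beta, float))
    elif spec.link == "rbf_mixture":
        if lengthscale is None:
            diffs = X_inf[:, None, :] - X_inf[None, :, :]
            dists = np.sqrt((diffs ** 2).sum(-1))
            lengthscale = float(np.median(dists[np.triu_indices(len(X_inf), 1)]))
            lengthscale = max(lengthscale, 1e-8)
        if centers is None:
            rows = rng.choice(X_inf.shape[0], size=spec.n_centers, replace=False)
            centers = X_inf[rows]
        if weights is None:
            weights = rng.uniform(0.5, 1.5, size=len(centers)) * rng.choice(
                [-1, 1], len(centers)
            )
        centers = np.asarray(centers, float)
        weights = np.asarray(weights, float)
        g = _rbf_mixture(X_inf, centers, weights, lengthscale)
        scale = None
        if not explicit:
            g_sd = g.std()
            a = spec.response_scale / g_sd if g_sd > 0 else 1.0
            b = spec.response_loc - a * g.mean()
            g = a * g + b
            scale = (float(a), float(b))
        noiseless = g
        truth = GroundTruth(tuple(idx), "rbf_mixture", None, centers=centers,
                            weights=weights, lengthscale=lengthscale, scale=scale)
    else:  # pragma: no cover - guarded by SyntheticSpec
        raise ValueError(f"unknown link {spec.link!r}")

    if spec.covariate_mode == "mobile_phase_percent":
        effect = 0.6  # k roughly halves from 30% to 50% ACN in the fixtures
        noiseless = noiseless - effect * X[:, -1]
        truth.covariate_effect = effect

    y = noiseless + rng.normal(0.0, spec.noise_sd, size=len(noiseless))
    truth.noiseless_y = noiseless
    return y, truth


def stratified_split(y: np.ndarray, n_test: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Train/test flags balancing the response distribution across sets.

    Observations are ranked by response and divided into ``n_test`` contiguous
    rank strata; one test observation is drawn per stratum, so both sets span
    the response range (same-distribution heuristic).
    """
    n = len(y)
    order = np.argsort(y, kind="stable")
    strata = np.array_split(order, n_test)
    test_rows = np.array([rng.choice(s) for s in strata])
    split = np.full(n, TRAIN, dtype=object)
    split[test_rows] = TEST
    return split


def make_planted_instance(
    seed: int,
    n: int = 40,
    p: int = 20,
    k_informative: int = 3,
    noise_sd: float = 0.05,
    link: Literal["linear", "rbf_mixture"] = "rbf_mixture",
    null: bool = False,
) -> tuple[QSRRDataset, set[int]]:
    """All-train benchmark instance with known informative descriptors.

    Returns the dataset and the planted informative column set.  With
    ``null=True`` the response is pure retention-factor-scale noise
    (mean 1.2, SD 0.5), independent of every descriptor.  Responses are
    shifted to be non-negative when the draw dips below zero, which preserves
    the link shape.
    """
    rng = np.random.default_rng(seed)
    inf = tuple(sorted(int(i) for i in
                       rng.choice(p, size=k_informative, replace=False)))
    spec = SyntheticSpec(n=n, p=p, informative_idx=inf, link=link,
                         noise_sd=noise_sd, seed=seed)
    X = generate_descriptors(spec, rng)
    y, _ = generate_response(X, spec, rng)
    if null:
        y = 1.2 + 0.5 * rng.standard_normal(n)
    if y.min() < 0:
        y = y - y.min() + 0.01
    ds = QSRRDataset([f"obs{i:03d}" for i in range(n)],
                     [f"D{j:03d}" for j in range(p)],
                     X, y, np.full(n, TRAIN, dtype=object))
    return ds, set(inf)


_PROFILES = {
    # n, p (after filtering), informative count, covariate, train/test sizes
    "quinolone": dict(n=21, p=293, k_inf=5, covariate="none", n_test=5),
    "sulfonamide": dict(n=39, p=113, k_inf=2, covariate="mobile_phase_percent",
                        n_test=9),
}


def make_paper_like_instance(which: Literal["quinolone", "sulfonamide"],
                             seed: int = 0,
                             noise_sd: float = 0.05) -> SyntheticDataset:
    """A synthetic instance sized like one of the two packaged studies.

    quinolone-like: n=21, p=293, 5 informative descriptors, no covariate,
    16/5 train-test split.  sulfonamide-like: n=39, p=113 (112 descriptors +
    the mobile-phase percentage as the final column), 2 informative
    descriptors + covariate, 30/9 split.
    """
    try:
        prof = _PROFILES[which]
    except KeyError:
        raise ValueError(f"unknown profile {which!r}") from None
    rng = np.random.default_rng(seed)
    p = prof["p"]
    # informative columns spread across blocks; covariate column never planted
    candidates = np.arange(p - (prof["covariate"] != "none"))
    inf = tuple(sorted(rng.choice(candidates, size=prof["k_inf"], replace=False)))
    spec = SyntheticSpec(
        n=prof["n"], p=p, informative_idx=inf, block_correlation=0.5,
        link="rbf_mixture", noise_sd=noise_sd, covariate_mode=prof["covariate"],
        seed=seed,
    )
    X = generate_descriptors(spec, rng)
    y, truth = generate_response(X, spec, rng)
    y = np.maximum(y, 0.0)  # retention factors are non-negative
    names = [f"D{j:03d}" for j in range(p)]
    if prof["covariate"] != "none":
        names[-1] = "acn_percent_scaled"
    split = stratified_split(y, prof["n_test"], rng)
    ids = [f"synth{which[:1].upper()}{i:02d}" for i in range(prof["n"])]
    ds = QSRRDataset(ids, names, X, y, split)
    return SyntheticDataset(ds, truth, spec)
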