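"""Binary particle-swarm wrapper feature selection over bone stress features.

Particles move in the continuous unit cube [0, 1]^d (d = number of candidate
bone features) under the standard global-best PSO velocity update

    V <- w V + c1 r1 (Pbest - X) + c2 r2 (Gbest - X),   X <- clip(X + V),

with velocities clamped and positions clipped to the cube.  A position is
decoded to a feature mask by thresholding each coordinate at 0.5 (>= 0.5
selects the feature).  The wrapper fitness of a mask balances predictive
error against parsimony:

    fitness = alpha * E_R + (1 - alpha) * |R| / |S|,

where E_R is the hold-out error rate of a k-nearest-neighbour learner trained
on the masked columns, |R| the number of selected features, |S| the total,
and alpha (default 0.9) weights error over subset size.  The empty mask is
assigned the worst fitness 1.0 by convention.  One stratified hold-out split
(fraction 0.2) is drawn per run seed and reused for every evaluation within
that run, so the objective is deterministic and comparable across particles;
mask evaluations are memoised.

Because single runs are stochastic, the final feature set is a consensus: the
three features selected most often across independent seeded runs (20 by
default), with count ties broken by mean stress magnitude then label order.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

from .errors import ValidationError
from .stress import FeatureMatrix

__all__ = [
    "SwarmConfig",
    "Swarm",
    "FitnessValue",
    "SelectionResult",
    "BpsoRun",
    "decode_solution",
    "fitness_value",
    "fitness",
    "HoldoutKnnEvaluator",
    "init_swarm",
    "step_swarm",
    "run_bpso",
    "consensus_features",
    "BpsoFeatureSelector",
]


@dataclass(frozen=True)
class SwarmConfig:
    """PSO hyperparameters and wrapper-evaluation settings.

    The swarm size is not part of the canonical parameterisation; 20
    particles is common practice and keeps 100 iterations at desk scale.
    With w = 0.9 and c1 = c2 = 2 unclamped velocities diverge, hence the
    velocity clamp (default 0.6) and position clipping.
    """

    dimensions: int
    n_particles: int = 20
    c1: float = 2.0
    c2: float = 2.0
    inertia: float = 0.9
    iterations: int = 100
    alpha: float = 0.9
    velocity_clamp: float = 0.6
    holdout_fraction: float = 0.2
    knn_k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if int(self.dimensions) < 1:
            raise ValidationError("dimensions must be >= 1")
        object.__setattr__(self, "dimensions", int(self.dimensions))
        if int(self.n_particles) < 1:
            raise ValidationError("n_particles must be >= 1")
        if int(self.iterations) < 1:
            raise ValidationError("iterations must be >= 1")
        if not 0.0 < self.alpha <= 1.0:
            raise ValidationError("alpha must lie in (0, 1]")
        if not 0.0 < self.holdout_fraction < 1.0:
            raise ValidationError("holdout_fraction must lie in (0, 1)")
        if self.velocity_clamp <= 0:
            raise ValidationError("velocity_clamp must be positive")
        if int(self.knn_k) < 1:
            raise ValidationError("knn_k must be >= 1")


@dataclass(frozen=True)
class FitnessValue:
    """Wrapper fitness of one mask: value = alpha*E_R + (1-alpha)*|R|/|S|."""

    value: float
    error_rate: float
    n_selected: int
    n_total: int


def decode_solution(position: np.ndarray) -> np.ndarray:
    """Decode a continuous position in [0, 1]^d to a boolean feature mask.

    A coordinate >= 0.5 selects the corresponding feature.
    """
    x = np.asarray(position, dtype=float)
    if x.ndim != 1:
        raise ValidationError("position must be a 1-D vector")
    if np.any(x < 0.0) or np.any(x > 1.0):
        raise ValidationError("position entries must lie in [0, 1]")
    return x >= 0.5


def fitness_value(
    error_rate: float, n_selected: int, n_total: int, alpha: float = 0.9
) -> FitnessValue:
    """Combine an error rate and a subset size into the wrapper fitness.

    The empty subset is the degenerate worst case and returns 1.0.
    """
    if n_selected == 0:
        return FitnessValue(1.0, 1.0, 0, n_total)
    value = alpha * error_rate + (1.0 - alpha) * n_selected / n_total
    return FitnessValue(value, error_rate, n_selected, n_total)


class HoldoutKnnEvaluator:
    """Deterministic wrapper-fitness evaluator over a fixed hold-out split.

    Draws one stratified hold-out split (``holdout_fraction`` of each class)
    from the run seed, standardises columns on the training portion, and
    scores masks by the hold-out error of a k-nearest-neighbour vote
    (Euclidean distance, majority vote, ties broken toward the class with the
    smaller summed neighbour distance).  Results are memoised per mask.
    """

    def __init__(self, data: FeatureMatrix, cfg: SwarmConfig):
        if cfg.dimensions != data.n_features:
            raise ValidationError("cfg.dimensions must equal the feature count")
        X = data.X.to_numpy(dtype=float)
        y_labels, y = np.unique(data.y, return_inverse=True)
        counts = np.bincount(y)
        if counts.min() < 2:
            raise ValidationError("each class needs at least 2 instances")
        rng = np.random.default_rng(cfg.seed)
        test_idx: list[np.ndarray] = []
        for cls in range(y_labels.size):
            members = np.flatnonzero(y == cls)
            perm = rng.permutation(members)
            n_test = min(members.size - 1, max(1, int(round(cfg.holdout_fraction * members.size))))
            test_idx.append(perm[:n_test])
        test = np.sort(np.concatenate(test_idx))
        train = np.setdiff1d(np.arange(y.size), test)
        mean = X[train].mean(axis=0)
        sd = X[train].std(axis=0)
        sd[sd == 0] = 1.0
        Z = (X - mean) / sd
        self._train, self._test = train, test
        self._Ztr, self._Zte = Z[train], Z[test]
        self._ytr, self._yte = y[train], y[test]
        self._n_classes = int(y_labels.size)
        self._k = min(cfg.knn_k, train.size)
        self._alpha = cfg.alpha
        self._d = cfg.dimensions
        self._cache: dict[bytes, FitnessValue] = {}

    def error_rate(self, mask: np.ndarray) -> float:
        """Hold-out KNN error rate of the masked feature subset."""
        mask = np.asarray(mask, dtype=bool)
        if mask.size != self._d:
            raise ValidationError("mask length must equal the feature count")
        if not mask.any():
            return 1.0
        A = self._Ztr[:, mask]
        B = self._Zte[:, mask]
        # squared Euclidean distances via GEMM; clip tiny negatives
        d2 = (B * B).sum(axis=1)[:, None] + (A * A).sum(axis=1)[None, :] - 2.0 * B @ A.T
        np.maximum(d2, 0.0, out=d2)
        k = self._k
        nn = np.argpartition(d2, kth=k - 1, axis=1)[:, :k]
        nn_labels = self._ytr[nn]
        nn_dist = np.take_along_axis(d2, nn, axis=1)
        votes = np.zeros((B.shape[0], self._n_classes), dtype=np.int64)
        dist_sums = np.zeros((B.shape[0], self._n_classes))
        for cls in range(self._n_classes):
            is_cls = nn_labels == cls
            votes[:, cls] = is_cls.sum(axis=1)
            dist_sums[:, cls] = np.where(is_cls, np.sqrt(nn_dist), 0.0).sum(axis=1)
        top = votes.max(axis=1, keepdims=True)
        tied = votes == top
        # distance-weighted tie-break: among top-voted classes, smallest summed distance
        dist_sums = np.where(tied, dist_sums, np.inf)
        pred = dist_sums.argmin(axis=1)
        return float(np.mean(pred != self._yte))

    def evaluate_mask(self, mask: np.ndarray) -> FitnessValue:
        mask = np.asarray(mask, dtype=bool)
        key = np.packbits(mask).tobytes()
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        if mask.any():
            fv = fitness_value(self.error_rate(mask), int(mask.sum()), self._d, self._alpha)
        else:
            fv = fitness_value(1.0, 0, self._d, self._alpha)
        self._cache[key] = fv
        return fv

    def __call__(self, position: np.ndarray) -> float:
        return self.evaluate_mask(decode_solution(position)).value


def fitness(mask: np.ndarray, data: FeatureMatrix, cfg: SwarmConfig) -> FitnessValue:
    """Wrapper fitness of one mask on one feature matrix (fresh evaluator)."""
    return HoldoutKnnEvaluator(data, cfg).evaluate_mask(mask)


@dataclass
class Swarm:
    """Particle positions/velocities with personal and global bests."""

    cfg: SwarmConfig
    rng: np.random.Generator
    positions: np.ndarray  # (n, d) in [0, 1]
    velocities: np.ndarray  # (n, d), |v| <= clamp
    pbest_positions: np.ndarray
    pbest_fitness: np.ndarray  # (n,)
    gbest_position: np.ndarray
    gbest_fitness: float
    gbest_trace: list[float] = dc_field(default_factory=list)


def init_swarm(cfg: SwarmConfig, evaluator: Callable[[np.ndarray], float]) -> Swarm:
    """Seeded swarm: positions uniform on [0,1]^d, velocities uniform in the clamp.

    Personal bests start at the initial positions; the global best is the best
    initial particle (first-found among equals).
    """
    rng = np.random.default_rng(cfg.seed)
    pos = rng.uniform(0.0, 1.0, size=(cfg.n_particles, cfg.dimensions))
    vel = rng.uniform(-cfg.velocity_clamp, cfg.velocity_clamp, size=pos.shape)
    fit = np.array([evaluator(p) for p in pos])
    best = int(np.argmin(fit))
    swarm = Swarm(
        cfg=cfg,
        rng=rng,
        positions=pos,
        velocities=vel,
        pbest_positions=pos.copy(),
        pbest_fitness=fit.copy(),
        gbest_position=pos[best].copy(),
        gbest_fitness=float(fit[best]),
    )
    swarm.gbest_trace.append(swarm.gbest_fitness)
    return swarm


def step_swarm(swarm: Swarm, evaluator: Callable[[np.ndarray], float]) -> Swarm:
    """One global-best PSO iteration (in place; the swarm is also returned).

    Personal and global bests update only on strict fitness improvement, so
    the global-best fitness trace is nonincreasing.
    """
    cfg = swarm.cfg
    r1 = swarm.rng.uniform(size=swarm.positions.shape)
    r2 = swarm.rng.uniform(size=swarm.positions.shape)
    swarm.velocities = (
        cfg.inertia * swarm.velocities
        + cfg.c1 * r1 * (swarm.pbest_positions - swarm.positions)
        + cfg.c2 * r2 * (swarm.gbest_position[None, :] - swarm.positions)
    )
    np.clip(swarm.velocities, -cfg.velocity_clamp, cfg.velocity_clamp, out=swarm.velocities)
    swarm.positions = np.clip(swarm.positions + swarm.velocities, 0.0, 1.0)
    fit = np.array([evaluator(p) for p in swarm.positions])
    improved = fit < swarm.pbest_fitness
    swarm.pbest_positions[improved] = swarm.positions[improved]
    swarm.pbest_fitness[improved] = fit[improved]
    best = int(np.argmin(swarm.pbest_fitness))
    if swarm.pbest_fitness[best] < swarm.gbest_fitness:
        swarm.gbest_fitness = float(swarm.pbest_fitness[best])
        swarm.gbest_position = swarm.pbest_positions[best].copy()
    swarm.gbest_trace.append(swarm.gbest_fitness)
    return swarm


@dataclass(frozen=True)
class BpsoRun:
    """Outcome of one seeded BPSO run."""

    mask: np.ndarray  # decoded global-best mask
    position: np.ndarray
    fitness: FitnessValue
    trace: np.ndarray  # global-best fitness per iteration (length iterations + 1)


def run_bpso(data: FeatureMatrix, cfg: SwarmConfig) -> BpsoRun:
    """Run one seeded BPSO search over the feature matrix (exactly cfg.iterations steps)."""
    evaluator = HoldoutKnnEvaluator(data, cfg)
    swarm = init_swarm(cfg, evaluator)
    for _ in range(cfg.iterations):
        step_swarm(swarm, evaluator)
    mask = decode_solution(swarm.gbest_position)
    return BpsoRun(
        mask=mask,
        position=swarm.gbest_position.copy(),
        fitness=evaluator.evaluate_mask(mask),
        trace=np.asarray(swarm.gbest_trace),
    )


@dataclass(frozen=True)
class SelectionResult:
    """Multi-seed selection summary: per-seed masks, counts, consensus top-3."""

    masks: np.ndarray  # (n_seeds, d) boolean
    counts: np.ndarray  # (d,) times each feature was selected
    feature_labels: tuple[str, ...]
    consensus: tuple[str, ...]  # top-3 labels (all labels when d < 3)

    def counts_by_label(self) -> dict[str, int]:
        return {lab: int(c) for lab, c in zip(self.feature_labels, self.counts)}


def consensus_features(
    masks: Sequence[np.ndarray],
    labels: Sequence[str],
    magnitudes: np.ndarray | None = None,
) -> SelectionResult:
    """Top-3 consensus of per-seed masks by selection count.

    Count ties are broken by mean stress magnitude descending (when supplied),
    then by label order.  With fewer than three features the consensus is all
    of them.
    """
    if len(masks) == 0:
        raise ValidationError("consensus requires at least one mask")
    M = np.asarray([np.asarray(m, dtype=bool) for m in masks])
    if M.ndim != 2 or M.shape[1] != len(labels):
        raise ValidationError("masks must share the feature count of `labels`")
    counts = M.sum(axis=0)
    d = len(labels)
    mag = np.zeros(d) if magnitudes is None else np.asarray(magnitudes, dtype=float)
    if mag.size != d:
        raise ValidationError("magnitudes must have one entry per feature")
    order = sorted(range(d), key=lambda i: (-counts[i], -mag[i], i))
    top = tuple(labels[i] for i in order[: min(3, d)])
    return SelectionResult(M, counts.astype(np.int64), tuple(labels), top)


class BpsoFeatureSelector(SelectorMixin, BaseEstimator):
    """Multi-seed BPSO wrapper feature selector (scikit-learn interface).

    ``fit(X, y)`` runs ``n_seeds`` independent seeded BPSO searches and keeps
    the top-3 consensus features; ``transform`` restricts ``X`` to them.

    Parameters mirror :class:`SwarmConfig`; ``random_state`` seeds run ``i``
    with ``random_state + i``.

    Attributes
    ----------
    support_ : boolean mask of consensus features
    counts_ : per-feature selection counts across seeds
    masks_ : (n_seeds, d) per-seed best masks
    traces_ : (n_seeds, iterations + 1) global-best fitness traces
    consensus_labels_ : consensus feature names
    """

    def __init__(
        self,
        n_seeds: int = 20,
        n_particles: int = 20,
        iterations: int = 100,
        c1: float = 2.0,
        c2: float = 2.0,
        inertia: float = 0.9,
        alpha: float = 0.9,
        velocity_clamp: float = 0.6,
        holdout_fraction: float = 0.2,
        knn_k: int = 5,
        random_state: int = 0,
    ):
        self.n_seeds = n_seeds
        self.n_particles = n_particles
        self.iterations = iterations
        self.c1 = c1
        self.c2 = c2
        self.inertia = inertia
        self.alpha = alpha
        self.velocity_clamp = velocity_clamp
        self.holdout_fraction = holdout_fraction
        self.knn_k = knn_k
        self.random_state = random_state

    def _config(self, dimensions: int, seed: int) -> SwarmConfig:
        return SwarmConfig(
            dimensions=dimensions,
            n_particles=self.n_particles,
            c1=self.c1,
            c2=self.c2,
            inertia=self.inertia,
            iterations=self.iterations,
            alpha=self.alpha,
            velocity_clamp=self.velocity_clamp,
            holdout_fraction=self.holdout_fraction,
            knn_k=self.knn_k,
            seed=seed,
        )

    def fit(self, X, y=None):
        if isinstance(X, FeatureMatrix):
            data = X
        else:
            frame = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
            if y is None:
                raise ValidationError("y is required")
            data = FeatureMatrix(frame.reset_index(drop=True), np.asarray(y))
        d = data.n_features
        runs = [
            run_bpso(data, self._config(d, int(self.random_state) + i))
            for i in range(int(self.n_seeds))
        ]
        labels = [str(c) for c in data.bone_labels]
        magnitudes = np.abs(data.X.to_numpy(dtype=float)).mean(axis=0)
        result = consensus_features([r.mask for r in runs], labels, magnitudes)
        self.n_features_in_ = d
        self.feature_names_in_ = np.asarray(labels, dtype=object)
        self.masks_ = result.masks
        self.counts_ = result.counts
        self.traces_ = np.vstack([r.trace for r in runs])
        self.consensus_labels_ = result.consensus
        self.support_ = np.isin(np.asarray(labels, dtype=object), result.consensus)
        self.selection_result_ = result
        return self

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_
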