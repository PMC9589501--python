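"""Structuring of per-bone node-stress exports.

A finite-element solver exports, for every bone, a scalar stress value at each
mesh node.  This module turns those exports into the objects the rest of the
pipeline consumes: descending stress rankings, Pareto-style equal-width
distributions, percentile bands, top-k node subsets, and the rank-aligned
feature matrix used for feature selection and landing-pattern classification.

Conventions
-----------
* Nodes are ranked by stress descending; ties are broken by node id ascending,
  so every ranking is a total order and all derived objects are deterministic.
* "Top-k" subsets are taken per bone, never pooled across bones, so every bone
  retains a feature column in every subset case.
* The rank-aligned feature matrix has one row per within-bone stress rank
  (per condition, per replicate sample): row r holds, in column b, the stress
  of bone b's rank-r node within the chosen subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "NodeStresses",
    "StressField",
    "NodeSubsetSpec",
    "ParetoDistribution",
    "FeatureMatrix",
    "rank_nodes",
    "select_top_k",
    "pareto_bins",
    "percentile_bands",
    "build_feature_matrix",
    "thin_ranks",
]

PERCENTILE_BAND_FRACTIONS = (0.50, 0.80, 0.90, 0.95)


@dataclass(frozen=True)
class NodeStresses:
    """Stress values at the mesh nodes of one bone (one condition, one sample)."""

    node_ids: np.ndarray
    stresses: np.ndarray

    def __post_init__(self) -> None:
        ids = np.asarray(self.node_ids, dtype=np.int64)
        st = np.asarray(self.stresses, dtype=float)
        if ids.ndim != 1 or st.ndim != 1 or ids.shape != st.shape:
            raise ValidationError("node_ids and stresses must be 1-D arrays of equal length")
        if ids.size == 0:
            raise ValidationError("a bone must contain at least one node")
        if np.unique(ids).size != ids.size:
            raise ValidationError("node_ids must be unique within a bone")
        if np.any(st < 0) or not np.all(np.isfinite(st)):
            raise ValidationError("stresses must be finite and nonnegative")
        object.__setattr__(self, "node_ids", ids)
        object.__setattr__(self, "stresses", st)

    def __len__(self) -> int:
        return int(self.node_ids.size)


@dataclass(frozen=True)
class StressField:
    """Mapping from bone label to node stresses for one condition and sample."""

    condition: str
    sample_id: int
    bones: Mapping[str, NodeStresses]

    def __post_init__(self) -> None:
        if not self.bones:
            raise ValidationError("a stress field must contain at least one bone")
        object.__setattr__(self, "bones", dict(self.bones))

    @property
    def bone_labels(self) -> tuple[str, ...]:
        return tuple(self.bones)

    @property
    def n_values(self) -> int:
        return sum(len(b) for b in self.bones.values())


@dataclass(frozen=True)
class NodeSubsetSpec:
    """Which nodes of each bone enter the analysis: all, or the top-k by stress."""

    mode: Literal["all", "top_k"] = "all"
    k: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("all", "top_k"):
            raise ValidationError(f"unknown subset mode {self.mode!r}")
        if self.mode == "top_k":
            if self.k is None or int(self.k) < 1:
                raise ValidationError("top_k subsets require k >= 1")
            object.__setattr__(self, "k", int(self.k))

    @classmethod
    def from_case(cls, case: str | int) -> "NodeSubsetSpec":
        """Parse a subset case as written in configs: ``all`` or an integer k."""
        if isinstance(case, str) and case.lower() == "all":
            return cls(mode="all")
        return cls(mode="top_k", k=int(case))

    @property
    def case_label(self) -> str:
        return "all" if self.mode == "all" else str(self.k)


@dataclass(frozen=True)
class ParetoDistribution:
    """Equal-width stress histogram enumerated from the highest range downward."""

    edges: np.ndarray  # length n_bins + 1, descending (or [c, c] when degenerate)
    counts: np.ndarray  # length n_bins, nonnegative ints

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)

    @property
    def n_nodes(self) -> int:
        return int(self.counts.sum())


def rank_nodes(bone: NodeStresses) -> np.ndarray:
    """Node ids ordered by stress descending, ties broken by node id ascending."""
    return bone.node_ids[rank_order(bone)]


def rank_order(bone: NodeStresses) -> np.ndarray:
    """Positional order realising the descending-stress / ascending-id ranking."""
    # lexsort: last key is primary
    return np.lexsort((bone.node_ids, -bone.stresses))


def ranked_stresses(bone: NodeStresses) -> np.ndarray:
    return bone.stresses[rank_order(bone)]


def select_top_k(field: StressField, spec: NodeSubsetSpec) -> StressField:
    """Restrict every bone of ``field`` to its k highest-stress nodes.

    With ``mode='all'`` (or k at least the bone size) the bone is kept whole.
    The returned bones are stored in descending-rank order; node identity is
    preserved.
    """
    if spec.mode == "all":
        return field
    bones: dict[str, NodeStresses] = {}
    for label, bone in field.bones.items():
        order = rank_order(bone)[: spec.k]
        bones[label] = NodeStresses(bone.node_ids[order], bone.stresses[order])
    return StressField(field.condition, field.sample_id, bones)


def pareto_bins(stresses: np.ndarray, n_bins: int = 30) -> ParetoDistribution:
    """Partition stresses into ``n_bins`` equal-width ranges, highest range first.

    The bins span [min, max]; every value falls in exactly one bin.  A
    degenerate input (min == max) collapses to a single bin holding all values.
    """
    values = np.asarray(stresses, dtype=float)
    if values.size == 0:
        raise ValidationError("pareto_bins requires a nonempty stress vector")
    if n_bins < 1:
        raise ValidationError("n_bins must be >= 1")
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        return ParetoDistribution(
            edges=np.array([hi, lo]), counts=np.array([values.size], dtype=np.int64)
        )
    ascending = np.linspace(lo, hi, n_bins + 1)
    counts, _ = np.histogram(values, bins=ascending)
    return ParetoDistribution(edges=ascending[::-1].copy(), counts=counts[::-1].astype(np.int64))


def percentile_bands(stresses: np.ndarray) -> dict[str, tuple[float, float]]:
    """Stress ranges of the descending-rank node bands reported per bone.

    Returns ``(low, high)`` ranges for the last 50/80/90/95% of nodes (the
    lower portion of the descending ranking) and for the first 5% (the top of
    the ranking).  For a "last f" band, the high end is the stress at
    descending rank ``ceil((1 - f) * n) + 1`` (1-based) and the low end is the
    minimum; the "first 5%" band covers the top ``ceil(0.05 * n)`` nodes.
    """
    values = np.asarray(stresses, dtype=float)
    if values.size == 0:
        raise ValidationError("percentile_bands requires a nonempty stress vector")
    s = np.sort(values)[::-1]
    n = s.size
    bands: dict[str, tuple[float, float]] = {}
    # epsilon guards the ceil against float error in (1 - f) * n
    for f in PERCENTILE_BAND_FRACTIONS:
        start = int(np.ceil((1.0 - f) * n - 1e-9))  # 0-based: rank ceil((1-f)n)+1
        start = min(start, n - 1)
        bands[f"last_{int(round(f * 100))}"] = (float(s[-1]), float(s[start]))
    m = max(1, int(np.ceil(0.05 * n - 1e-9)))
    bands["first_5"] = (float(s[m - 1]), float(s[0]))
    return bands


@dataclass(frozen=True)
class FeatureMatrix:
    """Labeled instances-by-bones table feeding selection and classification.

    ``X`` holds one column per bone (spec order preserved); ``y`` holds the
    condition label of each row.  For rank-aligned matrices ``ranks`` records
    the within-bone stress rank each row was built from (for sampled
    alignment, the row position inside its block) and ``sample_ids`` the
    replicate it came from.
    """

    X: pd.DataFrame
    y: np.ndarray
    ranks: np.ndarray | None = None
    sample_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        y = np.asarray(self.y)
        if len(self.X) != y.size:
            raise ValidationError("X and y must have the same number of rows")
        if len(self.X) == 0:
            raise ValidationError("feature matrix must contain at least one instance")
        if self.X.isna().any().any():
            raise ValidationError("feature matrix must not contain missing cells")
        _, counts = np.unique(y, return_counts=True)
        if counts.size < 2 or np.unique(counts).size != 1:
            raise ValidationError("labels must be balanced across two or more conditions")
        object.__setattr__(self, "y", y)

    @property
    def bone_labels(self) -> tuple[str, ...]:
        return tuple(self.X.columns)

    @property
    def n_features(self) -> int:
        return int(self.X.shape[1])

    @property
    def n_instances(self) -> int:
        return int(self.X.shape[0])

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.y))


def _subset_matrix(fields: Sequence[StressField], spec: NodeSubsetSpec,
                   bone_labels: Sequence[str]) -> list[dict[str, np.ndarray]]:
    out = []
    for f in fields:
        sub = select_top_k(f, spec)
        out.append({b: ranked_stresses(sub.bones[b]) for b in bone_labels})
    return out


def build_feature_matrix(
    fields_a: Sequence[StressField],
    fields_b: Sequence[StressField],
    spec: NodeSubsetSpec = NodeSubsetSpec(),
    summary: Literal["rank_aligned", "sampled", "mean", "max"] = "sampled",
    seed: int = 0,
) -> FeatureMatrix:
    """Assemble the labeled feature matrix from two conditions' stress fields.

    ``sampled`` (default) gives every bone one column and fills it, per
    condition, with that bone's subset stresses in an independent seeded
    random order (draws without replacement): per-bone marginals are exactly
    the subset values, while columns stay statistically independent within a
    condition, which multi-feature wrapper selection requires.

    ``rank_aligned`` matches nodes of equal within-bone stress rank across
    bones instead: instance r holds each bone's rank-r stress.  Sorted
    columns are comonotone, so each condition's instances lie on a smooth
    order-statistic curve; any two columns then separate two conditions
    almost perfectly regardless of planted effects, which makes this mode
    suitable for rank-profile inspection but degenerate for multi-feature
    classification (see the methods note).

    ``mean``/``max`` collapse each bone's subset to a scalar summary,
    yielding one instance per replicate sample.
    """
    if not fields_a or not fields_b:
        raise ValidationError("both conditions need at least one stress field")
    bone_labels = fields_a[0].bone_labels
    for f in list(fields_a) + list(fields_b):
        if f.bone_labels != bone_labels:
            raise ValidationError("all fields must share the same bone set and order")
    cond_a = fields_a[0].condition
    cond_b = fields_b[0].condition
    if cond_a == cond_b:
        raise ValidationError("the two conditions must carry distinct labels")

    rows: list[np.ndarray] = []
    labels: list[str] = []
    ranks: list[int] = []
    samples: list[int] = []
    if summary in ("rank_aligned", "sampled"):
        rng = np.random.default_rng(seed)
        per_cond = []
        for fields in (fields_a, fields_b):
            mats = _subset_matrix(fields, spec, bone_labels)
            per_cond.append(mats)
        k_eff = min(
            arr.size for mats in per_cond for m in mats for arr in m.values()
        )
        if spec.mode == "top_k" and k_eff < spec.k:
            raise ValidationError(
                f"every bone must hold at least k={spec.k} nodes for rank alignment"
            )
        for cond, fields, mats in zip((cond_a, cond_b), (fields_a, fields_b), per_cond):
            for fld, m in zip(fields, mats):
                cols = []
                for b in bone_labels:
                    col = m[b][:k_eff]
                    if summary == "sampled":
                        col = col[rng.permutation(k_eff)]
                    cols.append(col)
                rows.append(np.column_stack(cols))
                labels.extend([cond] * k_eff)
                ranks.extend(range(k_eff))
                samples.extend([fld.sample_id] * k_eff)
        X = pd.DataFrame(np.vstack(rows), columns=list(bone_labels))
        return FeatureMatrix(
            X, np.array(labels), ranks=np.array(ranks), sample_ids=np.array(samples)
        )
    if summary not in ("mean", "max"):
        raise ValidationError(f"unknown summary {summary!r}")
    reducer = np.mean if summary == "mean" else np.max
    for cond, fields in ((cond_a, fields_a), (cond_b, fields_b)):
        for fld in fields:
            m = _subset_matrix([fld], spec, bone_labels)[0]
            rows.append(np.array([reducer(m[b]) for b in bone_labels])[None, :])
            labels.append(cond)
            samples.append(fld.sample_id)
    X = pd.DataFrame(np.vstack(rows), columns=list(bone_labels))
    return FeatureMatrix(X, np.array(labels), sample_ids=np.array(samples))


def thin_ranks(fm: FeatureMatrix, max_per_condition: int) -> FeatureMatrix:
    """Deterministically thin a rank-aligned matrix to a desk-scale instance count.

    Keeps at most ``max_per_condition`` evenly spaced ranks per (condition,
    sample) block so the full rank profile — informative upper tail included —
    stays represented.  Matrices already small enough are returned unchanged.
    """
    if max_per_condition < 1:
        raise ValidationError("max_per_condition must be >= 1")
    if fm.ranks is None:
        return fm
    k = int(fm.ranks.max()) + 1
    if k <= max_per_condition:
        return fm
    keep_ranks = np.unique(np.linspace(0, k - 1, max_per_condition).round().astype(int))
    mask = np.isin(fm.ranks, keep_ranks)
    return FeatureMatrix(
        fm.X.loc[mask].reset_index(drop=True),
        fm.y[mask],
        ranks=fm.ranks[mask],
        sample_ids=None if fm.sample_ids is None else fm.sample_ids[mask],
    )
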