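"""File formats, run configuration and the run manifest.

All interchange is plain CSV/JSON/YAML: small volumes, easy inspection.
CSV dialect: UTF-8, comma-delimited, dot decimal, mandatory header.  Node ids
and phase indices are 0-based.

Formats
-------
stress CSV   : bone,node_id,condition,sample_id,stress_mpa
GRF CSV      : trial_id,sample_index,axis,value_n
waveform CSV : trial_id,axis,phase,value_n   (phase 0-100)
feature CSV  : condition,<bone columns...>   (one instance per row)
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .stress import FeatureMatrix, NodeStresses, StressField
from .synth import DEFAULT_BONE_LABELS, GrfSimSpec, RawTrial, StressSimSpec

__all__ = [
    "read_stress_csv",
    "write_stress_csv",
    "read_grf_csv",
    "write_grf_csv",
    "write_waveform_csv",
    "read_feature_csv",
    "write_feature_csv",
    "ComparisonConfig",
    "RunConfig",
    "load_config",
    "default_demo_config",
    "stage_seed",
    "RunManifest",
    "sha256_of",
]

STRESS_COLUMNS = ["bone", "node_id", "condition", "sample_id", "stress_mpa"]
GRF_COLUMNS = ["trial_id", "sample_index", "axis", "value_n"]
FLOAT_FORMAT = "%.17g"  # round-trip exact for IEEE doubles


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")


def read_stress_csv(path: str | Path) -> list[StressField]:
    """Parse a node-stress export into one StressField per (condition, sample).

    Rejects negative stresses and duplicate (bone, node_id, condition,
    sample_id) keys, naming the offending 1-based data row.
    """
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, STRESS_COLUMNS, path)
    neg = df.index[df["stress_mpa"] < 0]
    if len(neg):
        raise ValidationError(f"{path}: negative stress at row {int(neg[0]) + 1}")
    dup = df.duplicated(subset=["bone", "node_id", "condition", "sample_id"])
    if dup.any():
        raise ValidationError(
            f"{path}: duplicate (bone,node_id,condition,sample_id) at row "
            f"{int(df.index[dup][0]) + 1}"
        )
    fields: list[StressField] = []
    for (condition, sample_id), group in df.groupby(["condition", "sample_id"], sort=True):
        bones = {
            str(bone): NodeStresses(
                g["node_id"].to_numpy(np.int64), g["stress_mpa"].to_numpy(float)
            )
            for bone, g in group.groupby("bone", sort=False)
        }
        fields.append(StressField(str(condition), int(sample_id), bones))
    return fields


def write_stress_csv(fields: Sequence[StressField], path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for f in fields:
        for bone, ns in f.bones.items():
            rows.append(
                pd.DataFrame(
                    {
                        "bone": bone,
                        "node_id": ns.node_ids,
                        "condition": f.condition,
                        "sample_id": f.sample_id,
                        "stress_mpa": ns.stresses,
                    }
                )
            )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def read_grf_csv(path: str | Path) -> list[RawTrial]:
    """Parse raw GRF recordings; axes of a trial must have equal lengths."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, GRF_COLUMNS, path)
    trials = []
    for trial_id, group in df.groupby("trial_id", sort=True):
        axes = {}
        lengths = set()
        for axis, g in group.groupby("axis", sort=False):
            g = g.sort_values("sample_index")
            axes[str(axis)] = g["value_n"].to_numpy(float)
            lengths.add(len(g))
        if len(lengths) != 1:
            raise ValidationError(f"{path}: ragged axis lengths in trial {trial_id}")
        trials.append(RawTrial(int(trial_id), axes))
    return trials


def write_grf_csv(trials: Sequence[RawTrial], path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for t in trials:
        for axis, series in t.axes.items():
            rows.append(
                pd.DataFrame(
                    {
                        "trial_id": t.trial_id,
                        "sample_index": np.arange(series.size),
                        "axis": axis,
                        "value_n": series,
                    }
                )
            )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def write_waveform_csv(
    waveforms: Mapping[int, Mapping[str, np.ndarray]], path: str | Path
) -> Path:
    """Write 101-point waveforms: ``waveforms[trial_id][axis] -> (101,)``."""
    path = Path(path)
    rows = []
    for trial_id, axes in waveforms.items():
        for axis, values in axes.items():
            rows.append(
                pd.DataFrame(
                    {
                        "trial_id": trial_id,
                        "axis": axis,
                        "phase": np.arange(len(values)),
                        "value_n": np.asarray(values, dtype=float),
                    }
                )
            )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def write_feature_csv(fm: FeatureMatrix, path: str | Path) -> Path:
    path = Path(path)
    out = fm.X.copy()
    out.insert(0, "condition", fm.y)
    out.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def read_feature_csv(path: str | Path) -> FeatureMatrix:
    path = Path(path)
    df = pd.read_csv(path)
    if "condition" not in df.columns:
        raise ValidationError(f"{path}: missing 'condition' column")
    y = df["condition"].to_numpy()
    X = df.drop(columns="condition")
    return FeatureMatrix(X, y)


@dataclass(frozen=True)
class ComparisonConfig:
    """One two-condition comparison with its planted effects."""

    name: str
    conditions: tuple[str, str]
    effect_map: Mapping[str, float] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.conditions) != 2:
            raise ValidationError("a comparison needs exactly two condition labels")
        object.__setattr__(self, "conditions", tuple(self.conditions))
        object.__setattr__(self, "effect_map", dict(self.effect_map))


@dataclass(frozen=True)
class RunConfig:
    """Structured configuration of a full pipeline run.

    ``select_max_instances`` and ``recognition_max_instances`` bound the
    rank-aligned instances per condition entering wrapper selection and CV
    recognition (evenly thinned ranks, deterministic); see the methods note.
    """

    seed: int = 0
    out_dir: str = "run"
    bone_labels: tuple[str, ...] = DEFAULT_BONE_LABELS
    nodes_per_bone: int = 3300
    base_scale: float = 0.1
    tail_shape: float = 1.4
    node_noise_cv: float = 0.1
    samples_per_condition: int = 1
    effect_locus: str = "tail"
    comparisons: tuple[ComparisonConfig, ...] = ()
    cases: tuple[str, ...] = ("all", "2000", "1000", "500", "200")
    heights_m: tuple[float, ...] = (0.8, 1.0, 1.2)
    grf_n_trials: int = 20
    grf_sampling_rate: float = 1000.0
    grf_phase_duration: float = 0.25
    grf_trial_noise_cv: float = 0.05
    event_phase: int = 100
    n_bpso_seeds: int = 20
    n_particles: int = 20
    bpso_iterations: int = 100
    alpha: float = 0.9
    velocity_clamp: float = 0.6
    holdout_fraction: float = 0.2
    knn_k: int = 5
    cv_folds: int = 10
    select_max_instances: int = 200
    recognition_max_instances: int = 200
    highlight_margin: float = 0.10

    def __post_init__(self) -> None:
        if not self.comparisons:
            raise ValidationError("config must define at least one comparison")
        object.__setattr__(
            self,
            "comparisons",
            tuple(
                c if isinstance(c, ComparisonConfig) else ComparisonConfig(**c)
                for c in self.comparisons
            ),
        )
        object.__setattr__(self, "bone_labels", tuple(self.bone_labels))
        object.__setattr__(self, "cases", tuple(str(c) for c in self.cases))
        object.__setattr__(self, "heights_m", tuple(self.heights_m))

    def stress_spec(self, comparison: ComparisonConfig, seed: int) -> StressSimSpec:
        return StressSimSpec(
            bone_labels=self.bone_labels,
            nodes_per_bone=self.nodes_per_bone,
            base_scale=self.base_scale,
            tail_shape=self.tail_shape,
            effect_map=comparison.effect_map,
            effect_locus=self.effect_locus,
            node_noise_cv=self.node_noise_cv,
            samples_per_condition=self.samples_per_condition,
            condition_labels=comparison.conditions,
            seed=seed,
        )

    def grf_spec(self, height_m: float, seed: int) -> GrfSimSpec:
        return GrfSimSpec(
            n_trials=self.grf_n_trials,
            sampling_rate=self.grf_sampling_rate,
            phase_duration=self.grf_phase_duration,
            height_factor=float(np.sqrt(height_m / 1.0)),
            trial_noise_cv=self.grf_trial_noise_cv,
            seed=seed,
        )

    def to_dict(self) -> dict[str, Any]:
        d = {
            k: getattr(self, k)
            for k in self.__dataclass_fields__
        }
        d["comparisons"] = [
            {"name": c.name, "conditions": list(c.conditions), "effect_map": dict(c.effect_map)}
            for c in self.comparisons
        ]
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML (or JSON — YAML is a superset) run configuration."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: configuration must be a mapping")
    return RunConfig(**raw)


def default_demo_config(seed: int = 0, out_dir: str = "run") -> RunConfig:
    """The shipped demonstration configuration.

    Two comparisons of landing heights with planted tail-locus effects —
    stronger between 0.8 and 1.0 m (MP4/PP2 x1.5, MP3/PP3 x1.3) than between
    1.0 and 1.2 m (x1.25 / x1.15) — over the five node-subset cases.
    """
    return RunConfig(
        seed=seed,
        out_dir=out_dir,
        comparisons=(
            ComparisonConfig(
                name="0.8m_vs_1.0m",
                conditions=("0.8m", "1.0m"),
                effect_map={"MP4": 1.5, "PP2": 1.5, "MP3": 1.3, "PP3": 1.3},
            ),
            ComparisonConfig(
                name="1.0m_vs_1.2m",
                conditions=("1.0m", "1.2m"),
                effect_map={"MP4": 1.25, "PP2": 1.25, "MP3": 1.15, "PP3": 1.15},
            ),
        ),
    )


def stage_seed(master_seed: int, stage_index: int) -> int:
    """Derived per-stage seed: counter scheme over a seed sequence, < 2**31."""
    ss = np.random.SeedSequence(entropy=[int(master_seed), int(stage_index)])
    return int(ss.generate_state(1)[0] % (2**31))


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Record of one pipeline run: config, seeds, artifacts, timings, version."""

    config: dict[str, Any]
    seeds: dict[str, int]
    artifacts: dict[str, str]  # relative path -> sha256
    timings_s: dict[str, float]
    version: str

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return path

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        with open(path, "r", encoding="utf-8") as fh:
            return cls(**json.load(fh))

    def verify(self, root: str | Path) -> None:
        """Re-hash every listed artifact under ``root``; raise on mismatch."""
        root = Path(root)
        for rel, digest in self.artifacts.items():
            actual = sha256_of(root / rel)
            if actual != digest:
                raise ValidationError(f"artifact {rel}: checksum mismatch")
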