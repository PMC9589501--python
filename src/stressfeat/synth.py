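"""Seeded synthetic stress fields and landing GRF trials.

The generators stand in for a CT-derived finite-element model of a cat's
right forepaw and for force-platform recordings of its landings.  They emulate
the statistical structure the downstream pipeline assumes:

* per-bone node-stress distributions that are strongly right-skewed, so that a
  small fraction of nodes carries most of the summed stress;
* two landing conditions that differ by planted multiplicative shifts in
  designated bones, applied either to the whole bone or only to its
  high-stress tail (where landing-pattern information concentrates);
* bell-shaped multi-axis ground-reaction-force pulses over a landing phase,
  sampled at force-platform rates, whose peak scales with landing height.

Node stresses are drawn log-normally: ``tail_shape`` is the log-scale standard
deviation and ``base_scale`` the median, so the default ``tail_shape = 1.4``
places more than half of the summed stress in the top decile of nodes.

Each condition draws its own independent latent stress field (each landing
condition corresponds to an independent solve of the FE model under its own
load), so under the null (all shifts 1.0) the two conditions are exchangeable
samples of one distribution; correlated latent fields would make the two
conditions' rank profiles smooth displacements of each other and bias
rank-aligned null classification systematically below chance.  Replicate
samples within a condition share that condition's latent field and multiply
every node by i.i.d. unit-mean log-normal noise with coefficient of
variation ``node_noise_cv``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .stress import NodeStresses, StressField

__all__ = [
    "DEFAULT_BONE_LABELS",
    "StressSimSpec",
    "GrfSimSpec",
    "RawTrial",
    "gen_stress_field",
    "gen_grf_trials",
]

# Metacarpals, proximal phalanges and distal phalanges surrounding the paw pad.
DEFAULT_BONE_LABELS: tuple[str, ...] = (
    "MP1", "MP2", "MP3", "MP4", "MP5",
    "PP2", "PP3", "PP4", "PP5",
    "DP2", "DP3", "DP5",
)

TAIL_FRACTION = 0.10  # "tail" effect locus: top decile of condition-A stress ranks


def _lognormal_noise_sigma(cv: float) -> float:
    return math.sqrt(math.log1p(cv * cv))


@dataclass(frozen=True)
class StressSimSpec:
    """Calibration of the synthetic per-bone node-stress generator.

    Parameters
    ----------
    bone_labels : ordered bone names (default: the 12 paw-pad bones).
    nodes_per_bone : mesh nodes exported per bone.
    base_scale : median node stress, MPa.
    tail_shape : log-sd of the log-normal stress law; larger = heavier tail.
    effect_map : bone label -> multiplicative shift (>= 0) applied under
        condition B; 1.0 leaves a bone uninformative.
    effect_locus : ``"tail"`` shifts only the top decile of condition B's own
        stress ranking (the high-stress nodes); ``"global"`` shifts every node.
    node_noise_cv : CV of per-sample multiplicative replicate noise.
    samples_per_condition : replicate fields generated per condition.
    condition_labels : the two condition names, e.g. landing heights.
    """

    bone_labels: tuple[str, ...] = DEFAULT_BONE_LABELS
    nodes_per_bone: int = 3300
    base_scale: float = 0.1
    tail_shape: float = 1.4
    effect_map: Mapping[str, float] = dc_field(default_factory=dict)
    effect_locus: str = "tail"
    node_noise_cv: float = 0.1
    samples_per_condition: int = 1
    condition_labels: tuple[str, str] = ("A", "B")
    seed: int = 0

    def __post_init__(self) -> None:
        labels = tuple(self.bone_labels)
        if not labels or len(set(labels)) != len(labels):
            raise ValidationError("bone_labels must be nonempty and unique")
        object.__setattr__(self, "bone_labels", labels)
        if int(self.nodes_per_bone) < 1:
            raise ValidationError("nodes_per_bone must be >= 1")
        object.__setattr__(self, "nodes_per_bone", int(self.nodes_per_bone))
        if self.base_scale <= 0 or self.tail_shape <= 0:
            raise ValidationError("base_scale and tail_shape must be positive")
        if self.node_noise_cv < 0:
            raise ValidationError("node_noise_cv must be nonnegative")
        if int(self.samples_per_condition) < 1:
            raise ValidationError("samples_per_condition must be >= 1")
        object.__setattr__(self, "samples_per_condition", int(self.samples_per_condition))
        if self.effect_locus not in ("tail", "global"):
            raise ValidationError(f"unknown effect_locus {self.effect_locus!r}")
        effect = dict(self.effect_map)
        unknown = set(effect) - set(labels)
        if unknown:
            raise ValidationError(f"effect_map names unknown bones: {sorted(unknown)}")
        if any(s < 0 for s in effect.values()):
            raise ValidationError("effect shifts must be >= 0")
        object.__setattr__(self, "effect_map", effect)
        if len(self.condition_labels) != 2 or self.condition_labels[0] == self.condition_labels[1]:
            raise ValidationError("condition_labels must be two distinct names")
        object.__setattr__(self, "condition_labels", tuple(self.condition_labels))


def gen_stress_field(spec: StressSimSpec) -> tuple[list[StressField], list[StressField]]:
    """Generate replicate stress fields for the two conditions.

    Returns ``(fields_a, fields_b)`` with ``samples_per_condition`` fields
    each.  Every condition draws an independent latent field per bone (its
    own FE solve); replicate samples within a condition share that latent
    field.  Node id sets are identical everywhere.  Under condition B the
    bones named in ``effect_map`` have their tail (top decile of B's own
    ranking) or all nodes scaled by the planted shift.  Identical spec and
    seed reproduce the output bit for bit.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.nodes_per_bone
    node_ids = np.arange(n, dtype=np.int64)
    mu = math.log(spec.base_scale)
    sigma_noise = _lognormal_noise_sigma(spec.node_noise_cv)
    mu_noise = -0.5 * sigma_noise * sigma_noise
    n_tail = max(1, int(math.ceil(TAIL_FRACTION * n)))

    base: dict[str, np.ndarray] = {}
    shifted: dict[str, np.ndarray] = {}
    for bone in spec.bone_labels:
        base[bone] = rng.lognormal(mean=mu, sigma=spec.tail_shape, size=n)
        bb = rng.lognormal(mean=mu, sigma=spec.tail_shape, size=n)
        s = float(spec.effect_map.get(bone, 1.0))
        if s != 1.0:
            if spec.effect_locus == "global":
                bb = bb * s
            else:
                order = np.lexsort((node_ids, -bb))
                bb[order[:n_tail]] = bb[order[:n_tail]] * s
        shifted[bone] = bb

    def _sample_fields(cond: str, latent: dict[str, np.ndarray]) -> list[StressField]:
        fields = []
        for sample_id in range(spec.samples_per_condition):
            bones = {}
            for bone in spec.bone_labels:
                if spec.node_noise_cv > 0:
                    noise = rng.lognormal(mean=mu_noise, sigma=sigma_noise, size=n)
                    values = latent[bone] * noise
                else:
                    values = latent[bone].copy()
                bones[bone] = NodeStresses(node_ids, values)
            fields.append(StressField(cond, sample_id, bones))
        return fields

    cond_a, cond_b = spec.condition_labels
    return _sample_fields(cond_a, base), _sample_fields(cond_b, shifted)


@dataclass(frozen=True)
class RawTrial:
    """One force-platform recording: three axis series at a fixed sampling rate."""

    trial_id: int
    axes: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        axes = {k: np.asarray(v, dtype=float) for k, v in self.axes.items()}
        lengths = {v.size for v in axes.values()}
        if not axes or len(lengths) != 1:
            raise ValidationError("trial axes must be nonempty and of equal length")
        if lengths.pop() < 2:
            raise ValidationError("trial series must hold at least 2 samples")
        object.__setattr__(self, "axes", axes)

    @property
    def n_samples(self) -> int:
        return int(next(iter(self.axes.values())).size)


@dataclass(frozen=True)
class GrfSimSpec:
    """Calibration of the synthetic ground-reaction-force trial generator.

    Each trial is a quiet pre-contact baseline followed by a smooth,
    asymmetric landing-phase pulse per axis (a normalised beta-shaped bump,
    rising faster than it decays).  ``height_factor`` scales all peak
    amplitudes, emulating landing height; ``trial_noise_cv`` drives per-trial
    log-normal amplitude variation plus mild pulse-shape jitter, so the sample
    CV of vertical peaks matches ``trial_noise_cv``.
    """

    n_trials: int = 20
    sampling_rate: float = 1000.0  # Hz
    phase_duration: float = 0.25  # s, landing phase
    baseline_duration: float = 0.05  # s of pre-contact quiet signal
    peak_amplitude_by_axis: Mapping[str, float] = dc_field(
        default_factory=lambda: {"x": 15.0, "y": 25.0, "z": 120.0}
    )
    vertical_axis: str = "z"
    height_factor: float = 1.0
    trial_noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if int(self.n_trials) < 2:
            raise ValidationError("n_trials must be >= 2 (PCA needs multiple trials)")
        object.__setattr__(self, "n_trials", int(self.n_trials))
        if self.sampling_rate <= 0 or self.phase_duration <= 0:
            raise ValidationError("sampling_rate and phase_duration must be positive")
        if self.phase_duration * self.sampling_rate < 10:
            raise ValidationError("phase_duration x sampling_rate must cover >= 10 samples")
        peaks = dict(self.peak_amplitude_by_axis)
        if len(peaks) != 3 or any(p <= 0 for p in peaks.values()):
            raise ValidationError("peak_amplitude_by_axis needs three positive amplitudes")
        if self.vertical_axis not in peaks:
            raise ValidationError("vertical_axis must name one of the amplitude axes")
        object.__setattr__(self, "peak_amplitude_by_axis", peaks)
        if self.height_factor <= 0:
            raise ValidationError("height_factor must be positive")
        if self.trial_noise_cv < 0:
            raise ValidationError("trial_noise_cv must be nonnegative")
        if self.baseline_duration < 0:
            raise ValidationError("baseline_duration must be nonnegative")

    @property
    def axis_labels(self) -> tuple[str, ...]:
        return tuple(self.peak_amplitude_by_axis)


def _beta_pulse(n: int, p: float, q: float) -> np.ndarray:
    """Smooth asymmetric bump on (0, 1], normalised to unit peak."""
    t = np.linspace(0.0, 1.0, n)
    shape = t**p * (1.0 - t) ** q
    peak = shape.max()
    return shape / peak if peak > 0 else shape


def gen_grf_trials(spec: GrfSimSpec) -> list[RawTrial]:
    """Generate seeded raw GRF trials (three axes per trial).

    The vertical series starts at zero (below any contact threshold), crosses
    it on the pulse's rising edge, and peaks at
    ``peak_amplitude * height_factor`` times a unit-mean per-trial amplitude
    factor, so peaks scale monotonically with ``height_factor``.
    """
    rng = np.random.default_rng(spec.seed)
    n_pre = int(round(spec.baseline_duration * spec.sampling_rate))
    n_phase = int(round(spec.phase_duration * spec.sampling_rate))
    p0, q0 = 2.0, 3.0
    sigma_amp = _lognormal_noise_sigma(spec.trial_noise_cv)
    mu_amp = -0.5 * sigma_amp * sigma_amp
    trials = []
    for trial_id in range(spec.n_trials):
        axes = {}
        for axis, peak in spec.peak_amplitude_by_axis.items():
            amp = rng.lognormal(mean=mu_amp, sigma=sigma_amp) if sigma_amp > 0 else 1.0
            jit_p = rng.normal(0.0, spec.trial_noise_cv) if spec.trial_noise_cv > 0 else 0.0
            jit_q = rng.normal(0.0, spec.trial_noise_cv) if spec.trial_noise_cv > 0 else 0.0
            pulse = _beta_pulse(n_phase, p0 * math.exp(jit_p), q0 * math.exp(jit_q))
            series = np.concatenate(
                [np.zeros(n_pre), peak * spec.height_factor * amp * pulse]
            )
            axes[axis] = series
        trials.append(RawTrial(trial_id, axes))
    return trials
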