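"""GRF signal conditioning and principal-waveform reconstruction.

Force-platform trials are conditioned the way gait analyses condition them:
first ground contact is the first sample whose vertical force strictly
exceeds a 10 N threshold, series are low-pass filtered with a fourth-order
zero-phase Butterworth filter (50 Hz cut-off), and the landing-phase segment
is linearly resampled onto 101 points representing the 0-100% phase.

The trial-by-phase matrix of a movement axis is then decomposed by
mean-centred PCA (no variance scaling; all phase points share units of N).
The first principal component carries the dominant waveform mode, so each
trial's rank-1 reconstruction ``mean + score_1 * component_1`` and their
average — the principal GRF — summarise the condition's characteristic force
curve.  Event values (e.g. the force at the phase of maximum elbow flexion)
are read off the 101-point waveforms directly; the event phase is an input,
not estimated here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

from .errors import ValidationError
from .synth import RawTrial

__all__ = [
    "PcaDecomposition",
    "PrincipalWaveform",
    "PrincipalWaveformPCA",
    "detect_contact",
    "butterworth_lowpass",
    "time_normalize",
    "pca_decompose",
    "reconstruct_rank1",
    "extract_event_value",
    "condition_trial",
    "waveform_matrix",
]

N_PHASE_POINTS = 101
CONTACT_THRESHOLD_N = 10.0
FILTER_ORDER = 4
FILTER_CUTOFF_HZ = 50.0


def detect_contact(
    vertical_series: np.ndarray, threshold: float = CONTACT_THRESHOLD_N
) -> int | None:
    """Index of first ground contact: smallest i with series[i] > threshold.

    The inequality is strict (a sample exactly at the threshold is not
    contact).  Returns ``None`` when the series never crosses the threshold.
    """
    series = np.asarray(vertical_series, dtype=float)
    if series.size == 0:
        raise ValidationError("contact detection requires a nonempty series")
    above = series > threshold
    if not above.any():
        return None
    return int(np.argmax(above))


def butterworth_lowpass(
    series: np.ndarray,
    order: int = FILTER_ORDER,
    cutoff: float = FILTER_CUTOFF_HZ,
    fs: float = 1000.0,
) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass filter.

    Edge effects are handled by reflective padding of ``3 * order`` samples.
    Output length equals input length; DC gain is unity.
    """
    x = np.asarray(series, dtype=float)
    if order < 1:
        raise ValidationError("filter order must be >= 1")
    if cutoff <= 0 or cutoff >= fs / 2.0:
        raise ValidationError("cutoff must lie strictly inside (0, fs/2)")
    padlen = 3 * order
    if x.size <= padlen:
        raise ValidationError(f"series must be longer than {padlen} samples")
    b, a = signal.butter(order, cutoff, btype="low", fs=fs)
    return signal.filtfilt(b, a, x, padtype="even", padlen=padlen)


def time_normalize(segment: np.ndarray) -> np.ndarray:
    """Resample a segment onto 101 equally spaced phase points (0-100%).

    Linear interpolation on the sample index; the first and last outputs equal
    the first and last inputs exactly.
    """
    x = np.asarray(segment, dtype=float)
    if x.size < 2:
        raise ValidationError("time normalization requires at least 2 samples")
    phase = np.linspace(0.0, x.size - 1.0, N_PHASE_POINTS)
    out = np.interp(phase, np.arange(x.size), x)
    out[0], out[-1] = x[0], x[-1]
    return out


@dataclass(frozen=True)
class PcaDecomposition:
    """Mean-centred PCA of a trials-by-101 waveform matrix."""

    mean_waveform: np.ndarray  # (101,)
    components: np.ndarray  # (n_components, 101), orthonormal rows
    scores: np.ndarray  # (n_trials, n_components)
    explained_variance_ratio: np.ndarray  # nonincreasing, sums <= 1

    @property
    def n_components(self) -> int:
        return int(self.components.shape[0])


@dataclass(frozen=True)
class PrincipalWaveform:
    """Rank-1 reconstructions of all trials plus their average, the principal GRF."""

    reconstructions: np.ndarray  # (n_trials, 101)
    principal_grf: np.ndarray  # (101,)


class PrincipalWaveformPCA(TransformerMixin, BaseEstimator):
    """PCA of time-normalised GRF trials with rank-1 waveform reconstruction.

    A scikit-learn style transformer: ``fit(W)`` on a trials-by-101 matrix
    stores the mean waveform, orthonormal components (right singular vectors
    of the centred matrix, sign-fixed so each component's largest-magnitude
    entry is positive) and the per-trial scores; ``transform`` projects new
    trials onto the components.  ``reconstruct_rank1`` rebuilds every fitted
    trial from its first score alone and averages them into the principal GRF.

    Parameters
    ----------
    n_components : int or None
        Number of components to keep; ``None`` keeps ``min(n_trials - 1,
        n_phase_points)``.
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X: np.ndarray, y: None = None) -> "PrincipalWaveformPCA":
        W = np.asarray(X, dtype=float)
        if W.ndim != 2 or W.shape[0] < 2:
            raise ValidationError("PCA requires a 2-D matrix with >= 2 trials")
        n_comp = self.n_components
        max_comp = min(W.shape[0] - 1, W.shape[1])
        if n_comp is None:
            n_comp = max_comp
        if not 1 <= n_comp <= max_comp:
            raise ValidationError(f"n_components must be in [1, {max_comp}]")
        pca = PCA(n_components=n_comp, svd_solver="full")
        scores = pca.fit_transform(W)
        components = pca.components_.copy()
        # sign convention: the largest-magnitude entry of each component is positive
        flip = np.sign(components[np.arange(n_comp), np.abs(components).argmax(axis=1)])
        flip[flip == 0] = 1.0
        components *= flip[:, None]
        scores = scores * flip[None, :]
        self.mean_ = pca.mean_
        self.components_ = components
        self.scores_ = scores
        self.explained_variance_ratio_ = pca.explained_variance_ratio_.copy()
        self.n_components_ = n_comp
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "components_")
        W = np.asarray(X, dtype=float)
        return (W - self.mean_) @ self.components_.T

    def decomposition_(self) -> PcaDecomposition:
        check_is_fitted(self, "components_")
        return PcaDecomposition(
            mean_waveform=self.mean_.copy(),
            components=self.components_.copy(),
            scores=self.scores_.copy(),
            explained_variance_ratio=self.explained_variance_ratio_.copy(),
        )

    def reconstruct_rank1(self) -> PrincipalWaveform:
        check_is_fitted(self, "components_")
        return reconstruct_rank1(self.decomposition_())


def pca_decompose(W: np.ndarray, n_components: int | None = None) -> PcaDecomposition:
    """Mean-centred PCA of a trials-by-101 waveform matrix (>= 2 trials)."""
    return PrincipalWaveformPCA(n_components=n_components).fit(W).decomposition_()


def reconstruct_rank1(d: PcaDecomposition) -> PrincipalWaveform:
    """Rebuild each trial from its first principal component score only.

    The per-trial reconstruction is ``mean_waveform + score_1 * component_1``;
    the principal GRF is the unweighted mean of the reconstructions (equal to
    the mean waveform, since centred scores average to zero).
    """
    if d.n_components < 1:
        raise ValidationError("reconstruction requires at least one component")
    recon = d.mean_waveform[None, :] + np.outer(d.scores[:, 0], d.components[0])
    return PrincipalWaveform(reconstructions=recon, principal_grf=recon.mean(axis=0))


def extract_event_value(waveform: np.ndarray, event_phase: int) -> float:
    """Value of a 101-point waveform at an integer phase (0-100%)."""
    w = np.asarray(waveform, dtype=float)
    if w.size != N_PHASE_POINTS:
        raise ValidationError(f"waveform must hold exactly {N_PHASE_POINTS} points")
    if not 0 <= int(event_phase) <= 100:
        raise ValidationError("event_phase must lie in [0, 100]")
    return float(w[int(event_phase)])


def condition_trial(
    trial: RawTrial,
    fs: float,
    vertical_axis: str = "z",
    threshold: float = CONTACT_THRESHOLD_N,
    cutoff: float = FILTER_CUTOFF_HZ,
    order: int = FILTER_ORDER,
    phase_samples: int | None = None,
) -> dict[str, np.ndarray]:
    """Filter, segment at first contact, and 101-point-normalise one trial.

    The landing-phase segment starts at the contact index of the filtered
    vertical series and spans ``phase_samples`` samples (to the end of the
    recording if ``None`` or out of range).  Returns one 101-point waveform
    per axis.
    """
    if vertical_axis not in trial.axes:
        raise ValidationError(f"trial {trial.trial_id} has no axis {vertical_axis!r}")
    filtered = {
        axis: butterworth_lowpass(series, order=order, cutoff=cutoff, fs=fs)
        for axis, series in trial.axes.items()
    }
    contact = detect_contact(filtered[vertical_axis], threshold=threshold)
    if contact is None:
        raise ValidationError(
            f"trial {trial.trial_id}: vertical force never exceeds {threshold} N"
        )
    stop = trial.n_samples
    if phase_samples is not None:
        stop = min(stop, contact + int(phase_samples))
    if stop - contact < 2:
        raise ValidationError(f"trial {trial.trial_id}: landing segment too short")
    return {axis: time_normalize(series[contact:stop]) for axis, series in filtered.items()}


def waveform_matrix(conditioned: list[dict[str, np.ndarray]], axis: str) -> np.ndarray:
    """Stack one axis of conditioned trials into a trials-by-101 matrix."""
    if not conditioned:
        raise ValidationError("no conditioned trials supplied")
    return np.vstack([c[axis] for c in conditioned])
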