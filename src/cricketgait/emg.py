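"""EMG burst analysis: spike trains, spectra, cross-spectrum synchrony.

Muscle activity during walking is burst-structured at the gait frequency.
Thresholding the rectified signal yields a 0/1 spike train; averaged
periodograms locate the gait rhythm; the cross-spectrum between two channels
at that frequency gives their coherence and relative activation phase.  The
synchronisation index I_sync = cos(theta_hat) maps an average phase to
+1 (in-phase) ... -1 (anti-phase).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .circular import (
    CircularSummary,
    WWTestResult,
    watson_williams,
    wrap_to_pi,
)

__all__ = [
    "EMGRecord",
    "SpikeTrain",
    "SpectrumResult",
    "CrossSpectrumResult",
    "SyncIndex",
    "extract_spike_train",
    "power_spectrum",
    "select_peak_frequency",
    "cross_spectrum_phase",
    "sync_index",
    "virtual_antagonist_phase",
    "watson_williams",
    "mad_threshold",
]

DEFAULT_SEGMENT_S = 1.2  # ~4 gait cycles at 3.3 Hz
DEFAULT_OVERLAP = 0.5
DEFAULT_COHERENCE_FLOOR = 0.3
MIN_TRIAL_CYCLES = 5  # a trial is >5 gait periods of walking


@dataclass
class EMGRecord:
    """One muscle channel: signed amplitude samples at a fixed rate."""

    muscle: str
    fs: float
    samples: np.ndarray
    t0: float = 0.0

    def __post_init__(self):
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("EMG samples must be finite")


@dataclass
class SpikeTrain:
    """Binary 0/1 series at the EMG sampling rate."""

    muscle: str
    fs: float
    values: np.ndarray
    threshold: float


@dataclass
class SpectrumResult:
    frequencies: np.ndarray  # Hz
    power: np.ndarray  # units^2/Hz


@dataclass
class CrossSpectrumResult:
    frequencies: np.ndarray
    coherence: np.ndarray  # magnitude-squared, [0, 1]
    phase: np.ndarray  # rad, (-pi, pi]; positive = second channel lags first


@dataclass(frozen=True)
class SyncIndex:
    value: float  # cos(theta_hat), [-1, 1]
    theta_hat: float


def mad_threshold(samples, k: float = 3.0) -> float:
    """Default spike threshold: k robust standard deviations of the channel.

    The robust sd is the normal-consistent scaled median absolute
    deviation, MAD/0.6745, so with burst-sparse signals the threshold sits
    ~k sigma above the baseline noise.
    """
    x = np.asarray(samples, dtype=float)
    return k * float(np.median(np.abs(x - np.median(x)))) / 0.6745


def extract_spike_train(rec: EMGRecord, threshold: float | None = None) -> SpikeTrain:
    """Binarize an EMG channel: 1 where the rectified amplitude exceeds threshold.

    The default threshold is 3x the channel's median absolute deviation.
    An all-zero result triggers a warning (threshold too high).
    """
    if threshold is None:
        threshold = mad_threshold(rec.samples)
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    values = (np.abs(rec.samples) > threshold).astype(np.int8)
    if not values.any():
        warnings.warn(
            f"channel {rec.muscle}: spike train is all zeros (threshold too high?)",
            stacklevel=2,
        )
    return SpikeTrain(muscle=rec.muscle, fs=rec.fs, values=values, threshold=float(threshold))


def _nperseg(fs: float, segment_s: float, n: int) -> int:
    nper = int(round(segment_s * fs))
    return min(max(nper, 8), n)


def power_spectrum(
    samples,
    fs: float,
    segment_s: float = DEFAULT_SEGMENT_S,
    overlap: float = DEFAULT_OVERLAP,
) -> SpectrumResult:
    """Averaged-periodogram power spectral density (Welch, Hann taper).

    The mean is removed per segment; segments overlap by ``overlap``.
    """
    x = np.asarray(samples, dtype=float).ravel()
    nper = int(round(segment_s * fs))
    if x.size < 2 * nper:
        raise ValueError("signal shorter than two spectral segments")
    f, p = signal.welch(
        x, fs=fs, nperseg=nper, noverlap=int(nper * overlap),
        window="hann", detrend="constant",
    )
    return SpectrumResult(frequencies=f, power=p)


def select_peak_frequency(spec: SpectrumResult, band: tuple[float, float] = (1.0, 10.0)) -> float:
    """Dominant frequency within a band (argmax of density; ties -> lowest)."""
    lo, hi = band
    mask = (spec.frequencies >= lo) & (spec.frequencies <= hi)
    if not mask.any():
        raise ValueError(f"band {band} contains no spectrum bins")
    f_band = spec.frequencies[mask]
    return float(f_band[np.argmax(spec.power[mask])])


def cross_spectrum(
    a,
    b,
    fs: float,
    segment_s: float = DEFAULT_SEGMENT_S,
    overlap: float = DEFAULT_OVERLAP,
) -> CrossSpectrumResult:
    """Magnitude-squared coherence and cross-spectrum phase over all bins.

    Phase sign convention: positive phase means channel ``b`` lags channel
    ``a`` (b's activity occurs later).
    """
    x = np.asarray(a, dtype=float).ravel()
    y = np.asarray(b, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("channels must have equal length")
    nper = int(round(segment_s * fs))
    if x.size < 2 * nper:
        raise ValueError("signals shorter than two spectral segments")
    nov = int(nper * overlap)
    kw = dict(fs=fs, nperseg=nper, noverlap=nov, window="hann", detrend="constant")
    f, pxy = signal.csd(x, y, **kw)
    _, coh = signal.coherence(x, y, **kw)
    # scipy's csd uses conj(X)*Y: a pure lag of b gives a negative angle
    phase = wrap_to_pi(-np.angle(pxy))
    return CrossSpectrumResult(frequencies=f, coherence=np.clip(coh, 0.0, 1.0), phase=phase)


def cross_spectrum_phase(
    a,
    b,
    fs: float,
    f0: float,
    segment_s: float = DEFAULT_SEGMENT_S,
    overlap: float = DEFAULT_OVERLAP,
    coherence_floor: float = DEFAULT_COHERENCE_FLOOR,
) -> tuple[float, float, bool]:
    """Coherence and relative phase at the bin containing frequency ``f0``.

    Returns ``(coherence, phase, low_confidence)``; the flag is raised when
    the coherence at the bin is below ``coherence_floor``.
    """
    cs = cross_spectrum(a, b, fs, segment_s=segment_s, overlap=overlap)
    i = int(np.argmin(np.abs(cs.frequencies - f0)))
    coh = float(cs.coherence[i])
    low = coh < coherence_floor
    if low:
        warnings.warn(
            f"coherence {coh:.2f} at {cs.frequencies[i]:.2f} Hz below floor "
            f"{coherence_floor}: phase is low-confidence",
            stacklevel=2,
        )
    return coh, float(cs.phase[i]), low


def sync_index(summary: CircularSummary) -> SyncIndex:
    """Synchronisation index I_sync = cos(theta_hat) of an average phase."""
    if not summary.defined:
        raise ValueError("sync index undefined: circular mean has zero resultant")
    return SyncIndex(value=float(np.cos(summary.theta_hat)), theta_hat=summary.theta_hat)


def virtual_antagonist_phase(phase: float) -> float:
    """Hypothetical antagonist activation phase: add pi, wrap to (-pi, pi].

    Used to infer e.g. protractor timing from a recorded retractor under a
    quasi-anti-phase assumption.
    """
    if not np.isfinite(phase):
        raise ValueError("phase must be finite")
    return float(wrap_to_pi(np.asarray(phase) + np.pi))
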