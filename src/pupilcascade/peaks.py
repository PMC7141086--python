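"""Candidate dilation-peak detection on the detrended pupil signal.

Local maxima are located at negative-going zero crossings of the smoothed
first derivative; an extremum becomes a *candidate peak* only if its height
exceeds 1.5 standard deviations of the (zero-mean) detrended trial.  Each
candidate is then characterized by a least-squares parabola over a 2.5-s
window around the peak, from which the full width at half maximum is read
off.  Only maxima are considered: the cascade classifies dilations, not
constrictions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter1d

logger = logging.getLogger(__name__)


@dataclass
class PeakConfig:
    amplitude_gate_sd: float = 1.5
    fit_window_seconds: float = 2.5
    derivative_smoothing_sd_samples: float = 2.0  # 80 ms at 25 Hz
    #: Minimum separation between candidates (seconds).  An evoked response
    #: spans 2-2.5 s, so two dilation peaks closer than one response span
    #: are the same physiological event; among conflicting extrema the
    #: highest is kept.  ``None`` defaults to ``fit_window_seconds``.
    min_separation_seconds: float | None = None

    def __post_init__(self) -> None:
        if self.min_separation_seconds is None:
            self.min_separation_seconds = self.fit_window_seconds
        for name, v in self.__dict__.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class CandidatePeak:
    """A local maximum passing the amplitude gate.

    ``parabola`` holds (a, b, c) of the local model
    y = a + b*(t - peak_time) + c*(t - peak_time)^2 once fitted (c < 0 for
    a maximum); ``fwhm`` is the width (seconds) where the fitted parabola
    falls to half its height above the window baseline.
    """

    peak_index: int
    peak_time: float
    amplitude_sd: float
    parabola: Optional[Tuple[float, float, float]] = None
    fwhm: Optional[float] = None
    fit_rmse: Optional[float] = None


def smoothed_derivative(signal: np.ndarray, config: PeakConfig | None = None) -> np.ndarray:
    """First central difference (per-sample units) convolved with a Gaussian
    kernel; same length as the input, edges handled by nearest padding."""
    if config is None:
        config = PeakConfig()
    signal = np.asarray(signal, dtype=float)
    if len(signal) < 3:
        raise ValueError("need at least 3 samples for a central difference")
    deriv = np.empty_like(signal)
    deriv[1:-1] = 0.5 * (signal[2:] - signal[:-2])
    deriv[0] = signal[1] - signal[0]
    deriv[-1] = signal[-1] - signal[-2]
    return gaussian_filter1d(deriv, config.derivative_smoothing_sd_samples, mode="nearest")


def find_candidates(
    detrended: np.ndarray,
    sampling_rate: float,
    config: PeakConfig | None = None,
) -> List[CandidatePeak]:
    """Locate candidate dilation peaks in a detrended (zero-mean) signal.

    Extrema live on the Gaussian-smoothed signal (zero crossings of the
    smoothed derivative are exactly its stationary points), so the amplitude
    gate reads the *smoothed* value at the extremum and compares it against
    ``amplitude_gate_sd`` times the standard deviation of the whole
    detrended trial.  Detection is therefore invariant to signal scale and
    insensitive to single-sample noise excursions.
    """
    if config is None:
        config = PeakConfig()
    detrended = np.asarray(detrended, dtype=float)
    if len(detrended) < 3:
        return []
    sd = detrended.std()
    if sd == 0:
        return []
    smooth = gaussian_filter1d(
        detrended, config.derivative_smoothing_sd_samples, mode="nearest"
    )
    deriv = smoothed_derivative(detrended, config)
    # negative-going zero crossings: derivative > 0 then <= 0
    crossing = np.flatnonzero((deriv[:-1] > 0) & (deriv[1:] <= 0))
    candidates: List[CandidatePeak] = []
    for i in crossing:
        # the extremum sits at whichever side of the crossing is higher
        peak = i if smooth[i] >= smooth[i + 1] else i + 1
        if smooth[peak] > config.amplitude_gate_sd * sd:
            candidates.append(
                CandidatePeak(
                    peak_index=int(peak),
                    peak_time=peak / sampling_rate,
                    amplitude_sd=float(smooth[peak] / sd),
                )
            )
    candidates = _enforce_separation(
        candidates, config.min_separation_seconds or config.fit_window_seconds
    )
    candidates.sort(key=lambda c: c.peak_time)
    return candidates


def _enforce_separation(
    candidates: List[CandidatePeak], min_separation: float
) -> List[CandidatePeak]:
    """Local-dominance suppression: a candidate survives iff no other
    candidate within ``min_separation`` seconds is higher (ties broken
    toward the earlier peak).  The decision depends only on candidates in a
    fixed neighbourhood, so detection stays translation-equivariant."""
    kept = []
    for cand in candidates:
        dominated = any(
            o is not cand
            and abs(o.peak_time - cand.peak_time) < min_separation
            and (
                o.amplitude_sd > cand.amplitude_sd
                or (o.amplitude_sd == cand.amplitude_sd and o.peak_time < cand.peak_time)
            )
            for o in candidates
        )
        if not dominated:
            kept.append(cand)
    return kept


def fit_parabola(
    signal: np.ndarray,
    peak_index: int,
    sampling_rate: float,
    config: PeakConfig | None = None,
) -> Optional[CandidatePeak]:
    """Least-squares quadratic fit in a ±fit_window/2 window around the peak.

    The FWHM is computed from the fitted parabola as the width where it
    falls to half its height above the window baseline (the parabola's
    minimum over the window): with peak height h above baseline and
    curvature c < 0, fwhm = 2*sqrt(h / (2|c|)).  Candidates whose fitted
    vertex is not a maximum (c >= 0), or whose edge-truncated window holds
    fewer than 5 samples, are discarded (returns None).
    """
    if config is None:
        config = PeakConfig()
    signal = np.asarray(signal, dtype=float)
    half = int(round(config.fit_window_seconds / 2 * sampling_rate))
    lo = max(0, peak_index - half)
    hi = min(len(signal), peak_index + half + 1)
    if hi - lo < 5:
        logger.info("candidate at index %d dropped: window too short", peak_index)
        return None
    t_peak = peak_index / sampling_rate
    t_rel = (np.arange(lo, hi) - peak_index) / sampling_rate
    w = signal[lo:hi]
    # normal-equations quadratic fit y = a + b*t_rel + c*t_rel^2
    X = np.column_stack([np.ones_like(t_rel), t_rel, t_rel**2])
    (a, b, c), *_ = np.linalg.lstsq(X, w, rcond=None)
    if c >= 0:
        logger.info("candidate at index %d dropped: fitted vertex not a maximum", peak_index)
        return None
    fitted = X @ np.array([a, b, c])
    rmse = float(np.sqrt(np.mean((w - fitted) ** 2)))
    vertex_height = a - b**2 / (4 * c)
    baseline = float(fitted.min())
    h = vertex_height - baseline
    fwhm = float(2.0 * np.sqrt(h / (2.0 * abs(c)))) if h > 0 else 0.0
    sd = signal.std()
    return CandidatePeak(
        peak_index=peak_index,
        peak_time=t_peak,
        amplitude_sd=float(signal[peak_index] / sd) if sd > 0 else 0.0,
        parabola=(float(a), float(b), float(c)),
        fwhm=fwhm,
        fit_rmse=rmse,
    )


def detect_peaks(
    detrended: np.ndarray,
    sampling_rate: float,
    config: PeakConfig | None = None,
) -> List[CandidatePeak]:
    """Full detection pass: find gated candidates, then fit each one.

    Candidates whose parabola fit fails (edge truncation below 5 samples or
    non-maximum vertex) are dropped, matching the candidate definition used
    for classification.
    """
    if config is None:
        config = PeakConfig()
    fitted = []
    for cand in find_candidates(detrended, sampling_rate, config):
        peak = fit_parabola(detrended, cand.peak_index, sampling_rate, config)
        if peak is not None:
            peak.amplitude_sd = cand.amplitude_sd
            fitted.append(peak)
    return fitted
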