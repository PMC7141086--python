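"""Per-candidate feature construction and hazard labelling.

For every candidate peak, the signal within 1.5 s before/after the peak
(75 samples at 25 Hz) is decomposed with db4 wavelets to level 4.  The
coarse time course — the A4 reconstruction within the window — yields three
features (amplitude above the window baseline, mean level, baseline-
subtracted area), and the detail coefficients D1-D4 contribute their four
relative energies, for a 7-dimensional feature vector per candidate.
Candidates whose window would extend beyond the trace are dropped (never
zero-padded silently).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .core import EventAnnotation
from .peaks import CandidatePeak
from .wavelet import band_energies, decompose, reconstruct_band

logger = logging.getLogger(__name__)

LABEL_HAZARD = "hazard"
LABEL_NOISE = "noise"
LABEL_UNLABELED = "unlabeled"

FEATURE_NAMES = ["amplitude", "mean", "area", "re_d1", "re_d2", "re_d3", "re_d4"]

#: Half-window in seconds: signal within 1.5 s before/after the peak.
FEATURE_HALF_WINDOW = 1.5
FEATURE_WAVELET = "db4"
FEATURE_LEVEL = 4
#: Default hazard-matching tolerance (seconds): an evoked response spans
#: 2-2.5 s, so a matching candidate peak must fall within 2.5 s of onset.
MATCH_TOLERANCE = 2.5


@dataclass
class PeakFeatureVector:
    subject_id: str
    peak_time: float
    amplitude: float  # A4 max minus A4 window minimum, signal units
    mean: float  # mean of the A4 reconstruction over the window
    area: float  # trapezoidal integral of (A4 - window min), units x seconds
    rel_energy: Tuple[float, float, float, float]  # D1..D4 shares of total energy
    label: str = LABEL_UNLABELED

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.amplitude, self.mean, self.area, *self.rel_energy], dtype=float
        )


def extract_features(
    detrended: np.ndarray,
    peak: CandidatePeak,
    sampling_rate: float,
    subject_id: str = "",
) -> Optional[PeakFeatureVector]:
    """Build the 7-feature vector for one candidate; None if the ±1.5 s
    window does not fit inside the trace."""
    detrended = np.asarray(detrended, dtype=float)
    # 1.5 s before/after the peak: 37 + 1 + 37 = 75 samples at 25 Hz
    half = int(np.floor(FEATURE_HALF_WINDOW * sampling_rate + 1e-9))
    lo, hi = peak.peak_index - half, peak.peak_index + half + 1
    if lo < 0 or hi > len(detrended):
        logger.info(
            "candidate at t=%.2f s dropped: feature window outside trace", peak.peak_time
        )
        return None
    window = detrended[lo:hi]
    with warnings.catch_warnings():
        # level 4 on a 75-sample window: boundary effects reach all
        # coefficients, which is inherent to the chosen window/level pair
        warnings.simplefilter("ignore", UserWarning)
        dec = decompose(window, wavelet_name=FEATURE_WAVELET, level=FEATURE_LEVEL)
    a4 = reconstruct_band(dec, f"A_{FEATURE_LEVEL}")
    baseline = float(a4.min())
    amplitude = float(a4.max() - baseline)
    mean = float(a4.mean())
    area = float(np.trapezoid(a4 - baseline, dx=1.0 / sampling_rate))
    energies = band_energies(dec)
    return PeakFeatureVector(
        subject_id=subject_id,
        peak_time=peak.peak_time,
        amplitude=amplitude,
        mean=mean,
        area=area,
        rel_energy=tuple(float(e) for e in energies.rel_detail[:4]),
    )


def match_events(
    candidates: List[PeakFeatureVector],
    annotation: EventAnnotation,
    tolerance: float = MATCH_TOLERANCE,
) -> dict:
    """Greedy earliest-candidate matching of events to candidates.

    A candidate matches an event iff its peak time lies in
    [onset, onset + tolerance]; per event the *earliest* unclaimed matching
    candidate wins and each event is matched at most once.  Returns
    event_id -> matched PeakFeatureVector (or None for a missed event).
    """
    ordered = sorted(candidates, key=lambda c: c.peak_time)
    claimed: set = set()
    matches: dict = {}
    for event in annotation.events:
        match = next(
            (
                c
                for c in ordered
                if id(c) not in claimed
                and event.onset_time <= c.peak_time <= event.onset_time + tolerance
            ),
            None,
        )
        matches[event.event_id] = match
        if match is not None:
            claimed.add(id(match))
    return matches


def label_candidates(
    candidates: List[PeakFeatureVector],
    annotation: EventAnnotation,
    tolerance: float = MATCH_TOLERANCE,
) -> Tuple[List[PeakFeatureVector], List[str]]:
    """Label candidates as hazard/noise against annotated onsets.

    Matching follows :func:`match_events`; every unmatched candidate is
    labelled noise.  Returns the time-sorted labelled candidates and the
    ids of unmatched events (missed detections).
    """
    ordered = sorted(candidates, key=lambda c: c.peak_time)
    for c in ordered:
        c.label = LABEL_NOISE
    matches = match_events(ordered, annotation, tolerance)
    unmatched = []
    for event_id, match in matches.items():
        if match is None:
            unmatched.append(event_id)
        else:
            match.label = LABEL_HAZARD
    return ordered, unmatched


def features_to_frame(features: List[PeakFeatureVector]) -> pd.DataFrame:
    """Tabulate feature vectors with the on-disk column schema."""
    rows = [
        {
            "subject": f.subject_id,
            "peak_time": f.peak_time,
            "amplitude": f.amplitude,
            "mean": f.mean,
            "area": f.area,
            "re_d1": f.rel_energy[0],
            "re_d2": f.rel_energy[1],
            "re_d3": f.rel_energy[2],
            "re_d4": f.rel_energy[3],
            "label": f.label,
        }
        for f in features
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "subject",
            "peak_time",
            "amplitude",
            "mean",
            "area",
            "re_d1",
            "re_d2",
            "re_d3",
            "re_d4",
            "label",
        ],
    )
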