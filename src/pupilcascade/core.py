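"""Core data model: pupil traces, event annotations, and evaluation reports.

A :class:`PupilTrace` holds one trial's pupil-size time series on a strictly
uniform grid together with a per-sample validity mask (blinks and tracking
losses are *masked*, never dropped, so the grid stays uniform for the
frequency-domain stages).  Pupil "size" may be a diameter or an area in
arbitrary eye-tracker units; the pipeline is unit-agnostic because every
threshold downstream is expressed in per-trial standard deviations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

logger = logging.getLogger(__name__)

#: Tolerance (seconds) when checking that the time grid is uniform.
GRID_TOL = 1e-9


@dataclass
class PupilTrace:
    """Timestamped pupil-size samples with a validity mask for one trial.

    Parameters
    ----------
    subject_id : str
        Opaque identifier for the subject/trial.
    sampling_rate : float
        Samples per second (25 Hz for the target eye tracker).
    t : ndarray
        Sample times in seconds, strictly increasing, uniform grid.
    y : ndarray
        Pupil size in arbitrary units (diameter or area; declared in
        ``meta['signal_kind']`` when known).
    valid : ndarray of bool
        Per-sample validity; False for blinks/tracking losses.
    meta : dict
        Free-form metadata (signal kind, source file, ...).
    """

    subject_id: str
    sampling_rate: float
    t: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (len(self.t) == len(self.y) == len(self.valid)):
            raise ValueError("t, y and valid must have equal length")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(self.t) >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValueError("timestamps must be strictly increasing")
            expected = 1.0 / self.sampling_rate
            if np.any(np.abs(dt - expected) > max(GRID_TOL, 0.01 * expected)):
                raise ValueError(
                    "non-uniform time grid or sampling-rate mismatch: observed "
                    f"median step {np.median(dt):.6g} s, expected {expected:.6g} s"
                )
        if np.any(~np.isfinite(self.y[self.valid])):
            raise ValueError("y must be finite wherever valid is true")

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        """Span of the trace in seconds (n / rate)."""
        return self.n_samples / self.sampling_rate

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    def copy(self) -> "PupilTrace":
        return PupilTrace(
            subject_id=self.subject_id,
            sampling_rate=self.sampling_rate,
            t=self.t.copy(),
            y=self.y.copy(),
            valid=self.valid.copy(),
            meta=dict(self.meta),
        )


@dataclass(frozen=True)
class HazardEvent:
    """A single annotated hazardous situation."""

    onset_time: float
    event_id: str
    adequacy: Optional[bool] = None  # driving-response judgement; carried, never computed


@dataclass
class EventAnnotation:
    """Ground-truth hazard onsets for one subject's trial, sorted by onset."""

    subject_id: str
    events: list  # list[HazardEvent]

    def __post_init__(self) -> None:
        ids = [e.event_id for e in self.events]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate event_id for subject {self.subject_id}")
        # stable sort: equal onsets keep their file order
        self.events = sorted(self.events, key=lambda e: e.onset_time)

    @property
    def onsets(self) -> np.ndarray:
        return np.array([e.onset_time for e in self.events], dtype=float)

    def shifted(self, offset: float) -> "EventAnnotation":
        """Return a copy with every onset shifted by ``offset`` seconds."""
        return EventAnnotation(
            subject_id=self.subject_id,
            events=[
                HazardEvent(e.onset_time + offset, e.event_id, e.adequacy)
                for e in self.events
            ],
        )


@dataclass
class SubjectMetrics:
    """Confusion counts and derived rates for one held-out subject.

    ``fn`` counts both hazard-labelled candidates predicted noise and hazard
    events that produced no candidate at all (missed detections), so
    sensitivity is an event-level quantity.  Rates with a zero denominator are
    ``None`` (undefined, not 0).
    """

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    sensitivity: Optional[float] = None
    specificity: Optional[float] = None
    precision: Optional[float] = None


@dataclass
class EvaluationReport:
    """Per-subject and pooled detection/classification performance.

    ``candidate_counts`` maps subject_id -> (D, F): the number of candidate
    peaks before classification and the number of false positives after it.
    ``roc`` is a list of (false_positive_rate, true_positive_rate, threshold)
    triples from sweeping the decision threshold over all observed scores.
    """

    per_subject: dict = field(default_factory=dict)  # subject_id -> SubjectMetrics
    pooled: SubjectMetrics = field(default_factory=SubjectMetrics)
    roc: list = field(default_factory=list)
    auc: Optional[float] = None
    candidate_counts: dict = field(default_factory=dict)  # subject -> (D, F)
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        def metrics_dict(m: SubjectMetrics) -> dict:
            return {
                "tp": m.tp,
                "fp": m.fp,
                "tn": m.tn,
                "fn": m.fn,
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
                "precision": m.precision,
            }

        return {
            "per_subject": {s: metrics_dict(m) for s, m in self.per_subject.items()},
            "pooled": metrics_dict(self.pooled),
            "roc": [list(p) for p in self.roc],
            "auc": self.auc,
            "candidate_counts": {
                s: {"n_candidates": d, "n_false_positives": f}
                for s, (d, f) in self.candidate_counts.items()
            },
            "warnings": list(self.warnings),
        }


def compute_rates(tp: int, fp: int, tn: int, fn: int) -> SubjectMetrics:
    """Fill a :class:`SubjectMetrics` from confusion counts.

    sensitivity = tp/(tp+fn), specificity = tn/(tn+fp), precision = tp/(tp+fp);
    undefined (zero-denominator) rates stay ``None``.
    """
    m = SubjectMetrics(tp=tp, fp=fp, tn=tn, fn=fn)
    if tp + fn > 0:
        m.sensitivity = tp / (tp + fn)
    if tn + fp > 0:
        m.specificity = tn / (tn + fp)
    if tp + fp > 0:
        m.precision = tp / (tp + fp)
    return m
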