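"""Artifact rejection, interpolation, QC and trimming for pupil traces.

The cleaning cascade applies, in precedence order:

1. blink / tracking-loss samples (invalid on input),
2. a margin of 2 samples (40 ms at 25 Hz) before and after each blink run,
   because a half-closed eyelid biases the reported pupil size low,
3. samples differing by more than 10% (relative) from the last still-valid
   preceding value — transient detector glitches,
4. samples more than 3 standard deviations from the trial mean, with the
   statistics computed once over the samples surviving rules 1-3
   (physiologically unlikely sizes, e.g. the detector locking onto the iris).

Gaps are then filled by linear interpolation between the neighbouring valid
samples (constant extension at the trace ends).  A trial is accepted only if
at least 75% of its samples are genuinely valid — interpolated samples count
as invalid for this quality gate.  The first 30 s (acclimation phase) are
discarded before any of this.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .core import PupilTrace

logger = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    trim_seconds: float = 30.0
    jump_fraction: float = 0.10
    blink_margin_samples: int = 2
    outlier_sd: float = 3.0
    min_valid_fraction: float = 0.75
    #: After this many consecutive jump-flagged samples the reference
    #: re-anchors to the current sample: detector glitches span at most a
    #: handful of samples, so a longer excursion is a genuine level change,
    #: not an artifact.  Prevents unbounded cascade invalidation.
    max_jump_run: int = 5

    def __post_init__(self) -> None:
        if not (0 < self.jump_fraction < 1):
            raise ValueError("jump_fraction must be in (0, 1)")
        for name in ("trim_seconds", "blink_margin_samples", "outlier_sd", "min_valid_fraction"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class PreprocessReport:
    """Sample accounting for one trial; counts are non-overlapping by
    precedence (blink > margin > jump > outlier)."""

    n_total: int = 0
    n_blink: int = 0
    n_margin: int = 0
    n_jump: int = 0
    n_outlier: int = 0
    n_interpolated: int = 0
    valid_fraction: float = 0.0
    accepted: bool = False

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def trim_acclimation(trace: PupilTrace, config: PreprocessConfig) -> PupilTrace:
    """Drop the noisy acclimation phase (t < trim_seconds) and re-origin time.

    Event onsets must be shifted by the same amount downstream
    (:meth:`EventAnnotation.shifted` with ``-trim_seconds``).
    """
    if trace.duration <= config.trim_seconds:
        raise ValueError(
            f"trace of {trace.duration:.1f} s is shorter than the "
            f"{config.trim_seconds:.1f} s trim window"
        )
    keep = trace.t >= config.trim_seconds
    first = int(np.argmax(keep))
    return PupilTrace(
        subject_id=trace.subject_id,
        sampling_rate=trace.sampling_rate,
        t=trace.t[keep] - trace.t[first],
        y=trace.y[keep],
        valid=trace.valid[keep],
        meta=dict(trace.meta, trimmed_seconds=config.trim_seconds),
    )


def flag_invalid(
    trace: PupilTrace, config: PreprocessConfig
) -> Tuple[np.ndarray, PreprocessReport]:
    """Apply the artifact rules; returns the final validity mask and report."""
    n = trace.n_samples
    y = trace.y
    blink = ~trace.valid  # rule 1: blinks / tracking losses from the device

    # rule 2: margin around each blink run
    margin = np.zeros(n, dtype=bool)
    if config.blink_margin_samples > 0 and blink.any():
        m = config.blink_margin_samples
        padded = np.flatnonzero(blink)
        for offset in range(1, m + 1):
            margin[np.clip(padded - offset, 0, n - 1)] = True
            margin[np.clip(padded + offset, 0, n - 1)] = True
        margin &= ~blink

    # rule 3: relative jump from the last still-valid value; a flagged sample
    # never becomes the new reference, so one glitch cannot cascade — but a
    # run longer than max_jump_run is a real level change and re-anchors
    jump = np.zeros(n, dtype=bool)
    alive = ~(blink | margin)
    ref = np.nan
    run = 0
    for i in range(n):
        if not alive[i]:
            continue
        is_jump = (
            np.isfinite(ref)
            and ref != 0
            and abs(y[i] - ref) / abs(ref) > config.jump_fraction
            and run < config.max_jump_run
        )
        if is_jump:
            jump[i] = True
            run += 1
        else:
            ref = y[i]
            run = 0

    # rule 4: one statistical pass over the samples surviving rules 1-3
    outlier = np.zeros(n, dtype=bool)
    alive = ~(blink | margin | jump)
    if alive.any():
        mu = y[alive].mean()
        sd = y[alive].std()
        if sd > 0:
            outlier = alive & (np.abs(y - mu) > config.outlier_sd * sd)

    valid = ~(blink | margin | jump | outlier)
    report = PreprocessReport(
        n_total=n,
        n_blink=int(blink.sum()),
        n_margin=int(margin.sum()),
        n_jump=int(jump.sum()),
        n_outlier=int(outlier.sum()),
        n_interpolated=int(n - valid.sum()),
        valid_fraction=float(valid.sum() / n) if n else 0.0,
    )
    report.accepted = qc_accept(report, config)
    return valid, report


def interpolate_gaps(trace: PupilTrace, mask: np.ndarray) -> PupilTrace:
    """Fill invalid samples by linear interpolation between valid neighbours.

    Leading/trailing invalid runs take the nearest valid value (constant
    extension).  The output trace has no non-finite values; its ``valid``
    mask is the input mask, so interpolated samples remain identifiable.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 2:
        raise ValueError("need at least two valid samples to interpolate")
    y = trace.y.copy()
    idx = np.flatnonzero(mask)
    y[~mask] = np.interp(np.flatnonzero(~mask), idx, y[idx])
    return PupilTrace(
        subject_id=trace.subject_id,
        sampling_rate=trace.sampling_rate,
        t=trace.t.copy(),
        y=y,
        valid=mask.copy(),
        meta=dict(trace.meta, interpolated=True),
    )


def qc_accept(report: PreprocessReport, config: PreprocessConfig) -> bool:
    """Trial quality gate: accepted iff valid_fraction >= min_valid_fraction
    (boundary inclusive); interpolated samples count as invalid."""
    return report.valid_fraction >= config.min_valid_fraction


def preprocess_trace(
    trace: PupilTrace, config: PreprocessConfig | None = None
) -> Tuple[PupilTrace, PreprocessReport]:
    """Full cleaning pass: trim, flag, interpolate.  Returns the continuous
    cleaned trace and the QC report (check ``report.accepted``)."""
    if config is None:
        config = PreprocessConfig()
    trimmed = trim_acclimation(trace, config)
    mask, report = flag_invalid(trimmed, config)
    cleaned = interpolate_gaps(trimmed, mask)
    return cleaned, report
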