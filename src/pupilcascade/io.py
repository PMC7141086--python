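"""Readers and writers for traces, event annotations, features and reports.

All on-disk formats are plain text: trace CSV with columns ``t,y[,valid]``,
events CSV with columns ``subject,event,onset[,adequate]``, feature CSV with
one row per candidate peak, and a JSON report mirroring
:class:`~pupilcascade.core.EvaluationReport`.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .core import EvaluationReport, EventAnnotation, HazardEvent, PupilTrace

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


def read_trace(path: PathLike, sampling_rate: float, subject_id: Optional[str] = None) -> PupilTrace:
    """Read a pupil trace from a delimited text file.

    The file must have a header naming at least the time and pupil-size
    columns (``t``/``time`` and ``y``/``pupil``); an optional ``valid``
    column carries 0/1 flags.  Without a validity column, a sample is valid
    where y is finite and > 0 (a reported size of zero means tracking loss).

    Raises
    ------
    ValueError
        On non-monotone timestamps, or if the observed sampling rate differs
        from ``sampling_rate`` by more than 1%.
    """
    path = Path(path)
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    tcol = next((cols[k] for k in ("t", "time", "timestamp") if k in cols), None)
    ycol = next((cols[k] for k in ("y", "pupil", "pupil_size", "size") if k in cols), None)
    if tcol is None or ycol is None:
        raise ValueError(f"{path}: header must name time and pupil-size columns")
    t = df[tcol].to_numpy(dtype=float)
    y = df[ycol].to_numpy(dtype=float)
    if len(t) >= 2:
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError(f"{path}: non-monotone timestamps")
        observed = 1.0 / np.median(dt)
        if abs(observed - sampling_rate) > 0.01 * sampling_rate:
            raise ValueError(
                f"{path}: sampling-rate mismatch: observed {observed:.4g} Hz, "
                f"expected {sampling_rate:.4g} Hz"
            )
    if "valid" in cols:
        valid = df[cols["valid"]].to_numpy().astype(bool)
        valid &= np.isfinite(y)
    else:
        valid = np.isfinite(y) & (y > 0)
    return PupilTrace(
        subject_id=subject_id or path.stem,
        sampling_rate=sampling_rate,
        t=t,
        y=y,
        valid=valid,
        meta={"source": str(path)},
    )


def write_trace(trace: PupilTrace, path: PathLike) -> None:
    """Write a trace as CSV with columns ``t,y,valid`` (UTF-8, '.' decimal)."""
    df = pd.DataFrame(
        {"t": trace.t, "y": trace.y, "valid": trace.valid.astype(int)}
    )
    df.to_csv(path, index=False, float_format="%.9f")


def read_events(path: PathLike) -> list:
    """Read hazard annotations; returns a list of :class:`EventAnnotation`.

    Expected columns: ``subject,event,onset[,adequate]``.  Events are sorted
    by onset per subject; a duplicated event id within a subject is an error.
    An empty file yields an empty list with a logged warning.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        logger.warning("%s: empty event file", path)
        return []
    if df.empty:
        logger.warning("%s: event file has no rows", path)
        return []
    cols = {c.lower().strip(): c for c in df.columns}
    for required in ("subject", "event", "onset"):
        if required not in cols:
            raise ValueError(f"{path}: missing column '{required}'")
    annotations = []
    for subject, group in df.groupby(cols["subject"], sort=False):
        events = []
        for _, row in group.iterrows():
            adequacy = None
            if "adequate" in cols and not pd.isna(row[cols["adequate"]]):
                adequacy = bool(int(row[cols["adequate"]]))
            events.append(
                HazardEvent(
                    onset_time=float(row[cols["onset"]]),
                    event_id=str(row[cols["event"]]),
                    adequacy=adequacy,
                )
            )
        annotations.append(EventAnnotation(subject_id=str(subject), events=events))
    return annotations


def write_events(annotations: list, path: PathLike) -> None:
    rows = []
    for ann in annotations:
        for e in ann.events:
            rows.append(
                {
                    "subject": ann.subject_id,
                    "event": e.event_id,
                    "onset": e.onset_time,
                    "adequate": "" if e.adequacy is None else int(e.adequacy),
                }
            )
    pd.DataFrame(rows, columns=["subject", "event", "onset", "adequate"]).to_csv(
        path, index=False
    )


FEATURE_COLUMNS = [
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
]


def write_features(df: pd.DataFrame, path: PathLike) -> None:
    """Write the per-candidate feature table (schema :data:`FEATURE_COLUMNS`)."""
    df.to_csv(path, index=False, columns=FEATURE_COLUMNS, float_format="%.9g")


def read_features(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(FEATURE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing feature columns {sorted(missing)}")
    return df


def write_report(report: EvaluationReport, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)


def write_subject_table(report: EvaluationReport, path: PathLike) -> None:
    """Per-subject candidate/false-positive counts (columns Subj., F, D)."""
    rows = [
        {"subject": s, "F": f, "D": d}
        for s, (d, f) in sorted(report.candidate_counts.items())
    ]
    pd.DataFrame(rows, columns=["subject", "F", "D"]).to_csv(path, index=False)
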