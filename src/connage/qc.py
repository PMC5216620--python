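"""Motion QC (framewise displacement, exclusion) and signal cleaning.

FD is the mean over successive volumes of the Euclidean norm of the
parameter differences, computed separately for the translation triplet (mm)
and the rotation triplet (degrees). Subjects whose trace exceeds 1 mm
translation or 1 degree rotation in any direction are excluded (strict
inequality). Cleaning order is band-pass filter then nuisance regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .errors import InsufficientDataError, InvalidBandError
from .types import BoldTimeSeries, MotionTrace, SubjectRecord

DEFAULT_THRESHOLD_TRANS_MM = 1.0
DEFAULT_THRESHOLD_ROT_DEG = 1.0


@dataclass
class QCResult:
    subject_id: str
    fd_translation: float
    fd_rotation: float
    max_abs_translation: float
    max_abs_rotation: float
    excluded: bool
    reason: str = ""


def compute_fd(trace: MotionTrace) -> tuple[float, float]:
    """Framewise displacement for the translation and rotation triplets."""
    vals = trace.values
    if vals.shape[0] < 2:
        raise InsufficientDataError("FD needs at least 2 volumes")
    diffs = np.diff(vals, axis=0)
    fd_t = float(np.mean(np.linalg.norm(diffs[:, :3], axis=1)))
    fd_r = float(np.mean(np.linalg.norm(diffs[:, 3:], axis=1)))
    return fd_t, fd_r


def apply_exclusion(
    records: list[SubjectRecord],
    traces: dict[str, MotionTrace],
    threshold_trans: float = DEFAULT_THRESHOLD_TRANS_MM,
    threshold_rot: float = DEFAULT_THRESHOLD_ROT_DEG,
) -> tuple[list[SubjectRecord], dict[str, QCResult]]:
    """Partition subjects into kept / excluded by maximum head motion."""
    kept: list[SubjectRecord] = []
    results: dict[str, QCResult] = {}
    for rec in records:
        trace = traces.get(rec.subject_id)
        if trace is None:
            results[rec.subject_id] = QCResult(
                rec.subject_id, np.nan, np.nan, np.nan, np.nan,
                excluded=True, reason="missing-motion",
            )
            continue
        fd_t, fd_r = compute_fd(trace)
        max_t = float(np.abs(trace.translations).max())
        max_r = float(np.abs(trace.rotations).max())
        excluded = max_t > threshold_trans or max_r > threshold_rot
        reason = ""
        if max_t > threshold_trans:
            reason = "max-translation"
        elif max_r > threshold_rot:
            reason = "max-rotation"
        results[rec.subject_id] = QCResult(
            rec.subject_id, fd_t, fd_r, max_t, max_r, excluded, reason
        )
        if not excluded:
            kept.append(rec)
    return kept, results


def qc_report_frame(results: dict[str, QCResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "fd_translation": r.fd_translation,
                "fd_rotation": r.fd_rotation,
                "max_abs_translation": r.max_abs_translation,
                "max_abs_rotation": r.max_abs_rotation,
                "excluded": r.excluded,
                "reason": r.reason,
            }
            for r in results.values()
        ]
    )


def bandpass(ts: BoldTimeSeries, low: float = 0.01, high: float = 0.08,
             order: int = 2) -> BoldTimeSeries:
    """Zero-phase Butterworth band-pass; output is mean-centered."""
    nyquist = 1.0 / (2.0 * ts.tr)
    if not (0 < low < high < nyquist):
        raise InvalidBandError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < {nyquist} Hz"
        )
    b, a = signal.butter(order, [low / nyquist, high / nyquist], btype="band")
    padlen = min(3 * (max(len(a), len(b)) - 1), ts.n_timepoints - 1)
    filtered = signal.filtfilt(b, a, ts.values, axis=0, padlen=padlen)
    filtered = filtered - filtered.mean(axis=0, keepdims=True)
    return BoldTimeSeries(filtered, tr=ts.tr, node_labels=list(ts.node_labels))


def regress_nuisance(
    ts: BoldTimeSeries,
    confounds: np.ndarray,
    include_global: bool = False,
) -> BoldTimeSeries:
    """Residualize every node on [intercept | confounds | global signal]."""
    confounds = np.asarray(confounds, dtype=float)
    if confounds.ndim == 1:
        confounds = confounds[:, None]
    if confounds.shape[0] != ts.n_timepoints:
        raise InsufficientDataError("confound length must match time series")
    if confounds.shape[1] < 1:
        raise InsufficientDataError("need at least one confound column")
    if not np.all(np.isfinite(confounds)):
        raise InvalidBandError("confounds must be finite")
    cols = [np.ones((ts.n_timepoints, 1)), confounds]
    if include_global:
        cols.append(ts.values.mean(axis=1, keepdims=True))
    design = np.hstack(cols)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        warnings.warn("rank-deficient nuisance design; using pseudo-inverse",
                      RuntimeWarning, stacklevel=2)
    beta, *_ = np.linalg.lstsq(design, ts.values, rcond=None)
    resid = ts.values - design @ beta
    return BoldTimeSeries(resid, tr=ts.tr, node_labels=list(ts.node_labels))
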