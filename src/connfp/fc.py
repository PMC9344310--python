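"""Functional connectivity from ROI timeseries.

Two metrics: full Pearson correlation between every ROI pair, and partial
correlation controlling for the signal in all remaining ROIs (computed from
the precision matrix of the sample covariance). In both, negative
correlations are set to zero after the computation — anticorrelations are
not treated as connections — and the diagonal is zeroed. No scrubbing or
filtering is applied here; timeseries arrive fully preprocessed.
"""

from __future__ import annotations

import numpy as np

from .exceptions import ValidationError
from .io import FUNCTIONAL_PARTIAL, FUNCTIONAL_PEARSON, ConnectomeMatrix

__all__ = ["pearson_fc", "partial_fc"]


def _check_timeseries(ts: np.ndarray, min_samples: int) -> np.ndarray:
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValidationError(f"timeseries must be 2-D (ROI x time), got {ts.ndim}-D")
    n, t = ts.shape
    if t < min_samples:
        raise ValidationError(f"need at least {min_samples} samples, got {t}")
    sd = ts.std(axis=1)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        raise ValidationError(
            f"constant signal in ROI(s) {constant.tolist()}: correlation undefined"
        )
    return ts


def _finalize(r: np.ndarray, modality: str, subject_id: str, timepoint: int
              ) -> ConnectomeMatrix:
    r = np.clip(r, 0.0, 1.0)        # negatives are not connections
    np.fill_diagonal(r, 0.0)
    r = 0.5 * (r + r.T)
    return ConnectomeMatrix(
        subject_id=subject_id, timepoint=timepoint, modality=modality, weights=r
    )


def pearson_fc(
    ts: np.ndarray, subject_id: str = "subject", timepoint: int = 1
) -> ConnectomeMatrix:
    """Pearson-correlation FC: entry (i, j) = max(0, corr(ROI_i, ROI_j))."""
    ts = _check_timeseries(ts, min_samples=3)
    r = np.corrcoef(ts)
    return _finalize(r, FUNCTIONAL_PEARSON, subject_id, timepoint)


def partial_fc(
    ts: np.ndarray,
    subject_id: str = "subject",
    timepoint: int = 1,
    ridge: float = 0.0,
) -> ConnectomeMatrix:
    """Partial-correlation FC, conditioning each pair on all other ROIs.

    From the precision matrix ``P`` of the sample covariance:
    ``pc(i, j) = -P_ij / sqrt(P_ii * P_jj)``, negatives then zeroed.
    Requires more samples than ROIs; ``ridge`` adds ``ridge * mean(diag) * I``
    to the covariance for near-singular cases (off by default).
    """
    ts = _check_timeseries(ts, min_samples=3)
    n, t = ts.shape
    if ridge < 0:
        raise ValidationError("ridge must be >= 0")
    if t <= n and ridge == 0:
        raise ValidationError(
            f"sample covariance of {n} ROIs from {t} samples is singular; "
            "provide more samples than ROIs or enable the ridge flag"
        )
    cov = np.cov(ts)
    if n == 1:
        raise ValidationError("partial correlation needs at least 2 ROIs")
    if ridge > 0:
        cov = cov + ridge * float(np.mean(np.diagonal(cov))) * np.eye(n)
    try:
        prec = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        raise ValidationError(
            "sample covariance is singular; use more samples than ROIs "
            "or the ridge regularization flag"
        ) from None
    d = np.sqrt(np.diagonal(prec))
    pc = -prec / np.outer(d, d)
    return _finalize(pc, FUNCTIONAL_PARTIAL, subject_id, timepoint)
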