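"""Connectome similarity and identifiability.

The core procedure: threshold each subject's timepoint-1 connectome to a
target network density, binarize it into an edge mask, and compute the
Spearman rank correlation between the masked timepoint-1 and timepoint-2
edge-weight vectors for every subject pair. In the resulting N x N
similarity matrix (rows = timepoint-1 subjects, columns = timepoint-2
subjects) a subject is *identified* when their self-similarity (diagonal)
strictly exceeds every self-to-other similarity in their row; the
identifiability rate is the fraction of subjects so matched.

Density is counted over all possible node pairs n(n-1)/2, following the
usual graph-theoretic meaning of network density. For cross-subject
entries the mask of the ROW subject's timepoint-1 connectome is applied by
default, so each row compares one fixed edge set; union and intersection
conventions are available for sensitivity analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError
from .io import ConnectomeMatrix

logger = logging.getLogger(__name__)

MASK_CONVENTIONS = ("row", "union", "intersection")

__all__ = [
    "SimilarityMatrix",
    "IdentifiabilityResult",
    "ThresholdSweepResult",
    "density_mask",
    "top_k_mask",
    "masked_spearman",
    "similarity_matrix",
    "identifiability",
    "row_max_normalize",
    "zscore_rows",
    "threshold_sweep",
]


@dataclass
class SimilarityMatrix:
    """N x N Spearman similarity; rows = timepoint 1, columns = timepoint 2."""

    values: np.ndarray
    subjects: list[str]
    density: Optional[float]
    modality: str
    kind: str = "spearman"  # or "normalized" / "zscore" after transforms

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError("similarity matrix must be square")
        if v.shape[0] != len(self.subjects):
            raise ValidationError("subject list does not match matrix size")
        if self.kind == "spearman" and np.nanmax(np.abs(v)) > 1 + 1e-9:
            raise ValidationError("Spearman similarities must lie in [-1, 1]")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def self_similarities(self) -> np.ndarray:
        return np.diagonal(self.values).copy()

    @property
    def other_similarities(self) -> np.ndarray:
        off = ~np.eye(self.n, dtype=bool)
        return self.values[off]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subjects, columns=self.subjects)


@dataclass
class IdentifiabilityResult:
    """Outcome of the row-wise strict-maximum identification rule."""

    n_matched: int
    n_total: int
    rate: float
    self_similarities: np.ndarray
    other_similarities: np.ndarray
    matched: np.ndarray  # boolean per subject, row order


@dataclass
class ThresholdSweepResult:
    table: pd.DataFrame          # columns: density, n_matched, n_total, rate
    best_densities: list[float]  # argmax set (plateau if contiguous)


def _weights(w: ConnectomeMatrix | np.ndarray) -> np.ndarray:
    if isinstance(w, ConnectomeMatrix):
        return w.weights
    return np.asarray(w, dtype=float)


def top_k_mask(values: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask of the ``k`` largest entries of a 1-D array.

    Ties at the cutoff are broken by ascending position (deterministic),
    which for upper-triangle edge vectors means ascending (i, j)
    lexicographic node-pair order.
    """
    values = np.asarray(values, dtype=float)
    if not 0 <= k <= values.size:
        raise ValidationError(f"k={k} out of range for {values.size} values")
    order = np.argsort(-values, kind="stable")
    mask = np.zeros(values.size, dtype=bool)
    mask[order[:k]] = True
    return mask


def density_mask(w: ConnectomeMatrix | np.ndarray, density: float) -> np.ndarray:
    """Binary symmetric mask keeping the top-density fraction of node pairs.

    Retains the ``ceil(density * n(n-1)/2)`` largest upper-triangle weights.
    Zero-weight pairs can be retained when the density exceeds the nonzero
    fraction (logged); the diagonal is never retained.
    """
    if not 0 < density <= 1:
        raise ValidationError(f"density must be in (0, 1], got {density}")
    weights = _weights(w)
    n = weights.shape[0]
    iu = np.triu_indices(n, k=1)
    edge = weights[iu]
    k = math.ceil(density * edge.size)
    flat = top_k_mask(edge, k)
    n_zero = int(np.count_nonzero(edge[flat] == 0))
    if n_zero:
        logger.info(
            "density %.3g retains %d zero-weight pairs (density exceeds the "
            "nonzero edge fraction)", density, n_zero,
        )
    mask = np.zeros((n, n), dtype=bool)
    mask[iu] = flat
    return mask | mask.T


def masked_spearman(
    w1: ConnectomeMatrix | np.ndarray,
    w2: ConnectomeMatrix | np.ndarray,
    mask: Optional[np.ndarray] = None,
) -> float:
    """Spearman rank correlation of the two masked upper-triangle edge vectors.

    ``mask=None`` compares all off-diagonal pairs. Ties receive average
    ranks. At least 3 retained pairs are required.
    """
    a, b = _weights(w1), _weights(w2)
    if a.shape != b.shape:
        raise ValidationError(f"shape mismatch {a.shape} vs {b.shape}")
    n = a.shape[0]
    iu = np.triu_indices(n, k=1)
    if mask is None:
        keep = np.ones(iu[0].size, dtype=bool)
    else:
        keep = np.asarray(mask, dtype=bool)[iu]
    if keep.sum() < 3:
        raise ValidationError(
            f"mask retains {int(keep.sum())} pairs; at least 3 are required"
        )
    rho = stats.spearmanr(a[iu][keep], b[iu][keep]).statistic
    return float(rho)


def _pair_mask(
    masks: Sequence[np.ndarray], i: int, j: int, convention: str
) -> np.ndarray:
    if convention == "row":
        return masks[i]
    if convention == "union":
        return masks[i] | masks[j]
    if convention == "intersection":
        return masks[i] & masks[j]
    raise ValidationError(
        f"mask convention must be one of {MASK_CONVENTIONS}, got {convention!r}"
    )


def similarity_matrix(
    cohort_tp1: Sequence[ConnectomeMatrix],
    cohort_tp2: Sequence[ConnectomeMatrix],
    density: Optional[float] = 0.25,
    mask_convention: str = "row",
) -> SimilarityMatrix:
    """Pairwise masked Spearman similarity between the two timepoints.

    Entry (i, j) correlates subject i's timepoint-1 connectome with subject
    j's timepoint-2 connectome over the edge mask derived from timepoint-1
    connectomes at the given density (row convention: subject i's mask).
    ``density=None`` computes unmasked Spearman over all pairs.
    """
    if len(cohort_tp1) != len(cohort_tp2) or not cohort_tp1:
        raise ValidationError("timepoint lists must be non-empty and equal length")
    ids1 = [c.subject_id for c in cohort_tp1]
    ids2 = [c.subject_id for c in cohort_tp2]
    if ids1 != ids2:
        raise ValidationError(
            "subject sets/order differ between timepoints: "
            f"{ids1[:3]}... vs {ids2[:3]}..."
        )
    modality = cohort_tp1[0].modality
    n_nodes = cohort_tp1[0].n_nodes
    for c in list(cohort_tp1) + list(cohort_tp2):
        if c.modality != modality:
            raise ValidationError("mixed modalities in similarity computation")
        if c.n_nodes != n_nodes:
            raise ValidationError("mixed atlas sizes in similarity computation")

    n = len(cohort_tp1)
    if density is None:
        masks = None
    else:
        masks = [density_mask(c, density) for c in cohort_tp1]
    values = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            m = None if masks is None else _pair_mask(masks, i, j, mask_convention)
            values[i, j] = masked_spearman(cohort_tp1[i], cohort_tp2[j], m)
    return SimilarityMatrix(
        values=values, subjects=ids1, density=density, modality=modality
    )


def identifiability(s: SimilarityMatrix) -> IdentifiabilityResult:
    """Strict row-wise match rule: matched iff s(i,i) > s(i,j) for all j != i.

    Ties count as non-matches (logged).
    """
    v = s.values
    n = s.n
    matched = np.zeros(n, dtype=bool)
    for i in range(n):
        others = np.delete(v[i], i)
        best_other = others.max()
        if v[i, i] > best_other:
            matched[i] = True
        elif v[i, i] == best_other:
            logger.info(
                "subject %s: self-similarity ties the best other (%.6g); "
                "counted as a non-match", s.subjects[i], best_other,
            )
    n_matched = int(matched.sum())
    return IdentifiabilityResult(
        n_matched=n_matched,
        n_total=n,
        rate=n_matched / n,
        self_similarities=s.self_similarities,
        other_similarities=s.other_similarities,
        matched=matched,
    )


def row_max_normalize(s: SimilarityMatrix) -> SimilarityMatrix:
    """Divide each row by its maximum, so each row's best match is 1."""
    v = s.values
    row_max = v.max(axis=1)
    if np.any(row_max <= 0):
        bad = [s.subjects[i] for i in np.flatnonzero(row_max <= 0)]
        raise ValidationError(f"row maximum <= 0 for subjects {bad}")
    return replace(s, values=v / row_max[:, None], kind="normalized")


def zscore_rows(s: SimilarityMatrix) -> SimilarityMatrix:
    """Standardize each row to mean 0, sample s.d. 1 (N-1 denominator).

    A monotone per-row transform, so the identification outcome is
    unchanged.
    """
    v = s.values
    if v.shape[1] < 3:
        raise ValidationError("z-scoring needs at least 3 entries per row")
    sd = v.std(axis=1, ddof=1)
    if np.any(sd == 0):
        bad = [s.subjects[i] for i in np.flatnonzero(sd == 0)]
        raise ValidationError(f"zero-variance row for subjects {bad}")
    z = (v - v.mean(axis=1, keepdims=True)) / sd[:, None]
    return replace(s, values=z, kind="zscore")


def threshold_sweep(
    cohort_tp1: Sequence[ConnectomeMatrix],
    cohort_tp2: Sequence[ConnectomeMatrix],
    densities: Sequence[float],
    mask_convention: str = "row",
) -> ThresholdSweepResult:
    """Identifiability rate at each density, plus the argmax density set."""
    if len(densities) == 0:
        raise ValidationError("densities must be non-empty")
    rows = []
    for d in densities:
        sim = similarity_matrix(
            cohort_tp1, cohort_tp2, density=float(d), mask_convention=mask_convention
        )
        res = identifiability(sim)
        rows.append((float(d), res.n_matched, res.n_total, res.rate))
    table = pd.DataFrame(rows, columns=["density", "n_matched", "n_total", "rate"])
    best = table["rate"].max()
    best_densities = [float(d) for d in table.loc[table["rate"] == best, "density"]]
    return ThresholdSweepResult(table=table, best_densities=best_densities)
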