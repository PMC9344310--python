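"""Regional (cluster-wise) fingerprint analysis.

Repeats the full similarity/identifiability procedure inside each named
anatomical cluster. By default a cluster's connectome is its within-cluster
k x k submatrix, with the density threshold recomputed on the cluster's own
pair count k(k-1)/2; a cluster-to-whole-brain edge scope (all pairs
touching the cluster) is available for sensitivity analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as _sps

from .exceptions import ValidationError
from .io import ClusterDefinition, ConnectomeMatrix
from .similarity import (
    IdentifiabilityResult,
    SimilarityMatrix,
    identifiability,
    similarity_matrix,
    top_k_mask,
    zscore_rows,
)

EDGE_SCOPES = ("within", "to_all")

__all__ = ["RegionalResult", "cluster_submatrix", "regional_pipeline"]


@dataclass
class RegionalResult:
    cluster: ClusterDefinition
    similarity: SimilarityMatrix
    identifiability: IdentifiabilityResult
    zscores: SimilarityMatrix


def cluster_submatrix(
    w: ConnectomeMatrix, cluster: ClusterDefinition
) -> ConnectomeMatrix:
    """Restrict a connectome to within-cluster node pairs (k x k submatrix)."""
    idx = np.asarray(cluster.node_indices, dtype=int)
    if idx.max() >= w.n_nodes:
        raise ValidationError(
            f"cluster {cluster.name!r} index {idx.max()} out of range "
            f"for {w.n_nodes}-node connectome"
        )
    sub = w.weights[np.ix_(idx, idx)]
    labels = [w.node_labels[i] for i in idx]
    return ConnectomeMatrix(
        subject_id=w.subject_id,
        timepoint=w.timepoint,
        modality=w.modality,
        weights=sub,
        node_labels=labels,
    )


def _cluster_edge_positions(n: int, cluster: ClusterDefinition) -> np.ndarray:
    """Positions, in the upper-triangle edge vector, of pairs touching the cluster."""
    member = np.zeros(n, dtype=bool)
    member[list(cluster.node_indices)] = True
    iu = np.triu_indices(n, k=1)
    return np.flatnonzero(member[iu[0]] | member[iu[1]])


def _to_all_similarity(
    cohort_tp1: Sequence[ConnectomeMatrix],
    cohort_tp2: Sequence[ConnectomeMatrix],
    cluster: ClusterDefinition,
    density: Optional[float],
) -> SimilarityMatrix:
    """Similarity over all edges with at least one endpoint in the cluster.

    The row subject's timepoint-1 weights on the eligible edges define the
    density mask, mirroring the global row convention.
    """
    n_nodes = cohort_tp1[0].n_nodes
    pos = _cluster_edge_positions(n_nodes, cluster)
    iu = np.triu_indices(n_nodes, k=1)
    vec1 = [c.weights[iu][pos] for c in cohort_tp1]
    vec2 = [c.weights[iu][pos] for c in cohort_tp2]
    if density is None:
        masks = [np.ones(pos.size, dtype=bool)] * len(vec1)
    else:
        k = math.ceil(density * pos.size)
        if k < 3:
            raise ValidationError(
                f"cluster {cluster.name!r}: density {density} retains {k} "
                "edge pairs; at least 3 are required"
            )
        masks = [top_k_mask(v, k) for v in vec1]
    n = len(vec1)
    values = np.empty((n, n))
    for i in range(n):
        m = masks[i]
        for j in range(n):
            values[i, j] = _sps.spearmanr(vec1[i][m], vec2[j][m]).statistic
    return SimilarityMatrix(
        values=values,
        subjects=[c.subject_id for c in cohort_tp1],
        density=density,
        modality=cohort_tp1[0].modality,
    )


def regional_pipeline(
    cohort_tp1: Sequence[ConnectomeMatrix],
    cohort_tp2: Sequence[ConnectomeMatrix],
    clusters: Sequence[ClusterDefinition],
    density: Optional[float] = 0.25,
    mask_convention: str = "row",
    edge_scope: str = "within",
) -> dict[str, RegionalResult]:
    """Rerun similarity, identification and z-scoring inside each cluster."""
    if edge_scope not in EDGE_SCOPES:
        raise ValidationError(f"edge_scope must be one of {EDGE_SCOPES}")
    results: dict[str, RegionalResult] = {}
    for cl in clusters:
        if edge_scope == "within":
            k = cl.size
            if density is not None:
                retained = math.ceil(density * k * (k - 1) / 2)
                if retained < 3:
                    raise ValidationError(
                        f"cluster {cl.name!r} ({k} nodes): density {density} "
                        f"retains {retained} pairs; at least 3 are required"
                    )
            sub1 = [cluster_submatrix(c, cl) for c in cohort_tp1]
            sub2 = [cluster_submatrix(c, cl) for c in cohort_tp2]
            sim = similarity_matrix(
                sub1, sub2, density=density, mask_convention=mask_convention
            )
        else:
            sim = _to_all_similarity(cohort_tp1, cohort_tp2, cl, density)
        results[cl.name] = RegionalResult(
            cluster=cl,
            similarity=sim,
            identifiability=identifiability(sim),
            zscores=zscore_rows(sim),
        )
    return results
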