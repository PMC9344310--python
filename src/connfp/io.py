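"""Core data types and plain-text I/O.

Three kinds of objects flow through the pipeline:

* :class:`ConnectomeMatrix` — a symmetric, non-negative, zero-diagonal
  weighted adjacency matrix for one subject at one timepoint, either
  structural (tractography-derived edge weights) or functional
  (timeseries-correlation edge weights, negatives already zeroed).
* :class:`CohortPanel` — per-subject metadata: sex, gestational age (GA)
  at birth, post-menstrual age (PMA) at each of the two scans, the derived
  interval between scans in days, and optional mean framewise displacement
  (FD) per scan.
* :class:`ClusterDefinition` — a named anatomical cluster given as node
  indices into the atlas.

Connectomes and timeseries are delimited numeric text (comma or tab,
auto-detected, optional single header row of node labels); the cohort table
is a delimited table with named columns; cluster files are JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

logger = logging.getLogger(__name__)

SYMMETRY_TOL = 1e-10

STRUCTURAL = "structural"
FUNCTIONAL_PEARSON = "functional_pearson"
FUNCTIONAL_PARTIAL = "functional_partial"
MODALITIES = (STRUCTURAL, FUNCTIONAL_PEARSON, FUNCTIONAL_PARTIAL)
FUNCTIONAL_MODALITIES = (FUNCTIONAL_PEARSON, FUNCTIONAL_PARTIAL)

#: Names and sizes of the seven anatomical clusters of the 90-node atlas.
STUDY_CLUSTER_NAMES = (
    "central",
    "frontal",
    "limbic",
    "occipital",
    "parietal",
    "deep_grey",
    "temporal",
)
STUDY_CLUSTER_SIZES = (8, 22, 14, 14, 10, 8, 14)
STUDY_ATLAS_SIZE = 90


@dataclass
class ConnectomeMatrix:
    """Symmetric weighted adjacency for one subject/timepoint/modality.

    Invariants enforced on construction: the matrix is square with at least
    3 nodes, symmetric to within ``1e-10`` (small asymmetries are averaged
    away), has a zero diagonal (nonzero diagonals are zeroed — functional
    inputs routinely carry 1.0 there), and all weights are non-negative.
    Functional modalities are additionally bounded by 1.
    """

    subject_id: str
    timepoint: int
    modality: str
    weights: np.ndarray
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.timepoint not in (1, 2):
            raise ValidationError(f"timepoint must be 1 or 2, got {self.timepoint!r}")
        if self.modality not in MODALITIES:
            raise ValidationError(f"unknown modality {self.modality!r}")
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise FormatError(f"connectome must be square, got shape {w.shape}")
        n = w.shape[0]
        if n < 2:
            raise ValidationError(f"connectome needs at least 2 nodes, got {n}")
        asym = np.abs(w - w.T).max()
        if asym > SYMMETRY_TOL:
            raise ValidationError(
                f"matrix asymmetry {asym:.3g} exceeds tolerance {SYMMETRY_TOL:g} "
                f"(subject {self.subject_id}, tp {self.timepoint})"
            )
        w = 0.5 * (w + w.T)
        if np.abs(np.diagonal(w)).max() > 0:
            logger.warning(
                "nonzero diagonal in connectome for subject %s tp %d; zeroing "
                "(the diagonal is excluded from all analyses)",
                self.subject_id,
                self.timepoint,
            )
            np.fill_diagonal(w, 0.0)
        if w.min() < 0:
            raise ValidationError(
                f"negative weight {w.min():.3g} in {self.modality} connectome "
                f"(subject {self.subject_id}); functional negatives must be "
                "zeroed upstream and structural weights are non-negative"
            )
        if self.modality in FUNCTIONAL_MODALITIES and w.max() > 1 + 1e-8:
            raise ValidationError(
                f"functional weight {w.max():.6g} exceeds 1 (subject {self.subject_id})"
            )
        if self.modality in FUNCTIONAL_MODALITIES:
            np.clip(w, 0.0, 1.0, out=w)
        self.weights = w
        if not self.node_labels:
            self.node_labels = [f"n{i:03d}" for i in range(n)]
        elif len(self.node_labels) != n:
            raise ValidationError(
                f"{len(self.node_labels)} node labels for {n} nodes"
            )

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


def _sniff_delimiter(first_line: str) -> str:
    return "\t" if "\t" in first_line else ","


def _looks_numeric(tokens: Iterable[str]) -> bool:
    for t in tokens:
        try:
            float(t)
        except ValueError:
            return False
    return True


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read a delimited numeric matrix with an optional header row of labels.

    Returns ``(values, labels)``; ``labels`` is empty when no header is
    present. Raises :class:`FormatError` for ragged or non-numeric bodies.
    """
    path = Path(path)
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty file")
    delim = _sniff_delimiter(lines[0])
    first = [t.strip() for t in lines[0].split(delim)]
    labels: list[str] = []
    body = lines
    if not _looks_numeric(first):
        labels = first
        body = lines[1:]
        if not body:
            raise FormatError(f"{path}: header row but no data")
    rows = []
    width = None
    for i, ln in enumerate(body):
        toks = [t.strip() for t in ln.split(delim)]
        if width is None:
            width = len(toks)
        elif len(toks) != width:
            raise FormatError(
                f"{path}: ragged row {i} ({len(toks)} fields, expected {width})"
            )
        try:
            rows.append([float(t) for t in toks])
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric value in row {i}: {exc}") from None
    return np.asarray(rows, dtype=float), labels


def read_connectome(
    path: str | Path,
    subject_id: str,
    timepoint: int,
    modality: str,
) -> ConnectomeMatrix:
    """Read a delimited square matrix file as a validated connectome."""
    values, labels = read_matrix(path)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise FormatError(
            f"{path}: connectome must be square, got shape {values.shape}"
        )
    return ConnectomeMatrix(
        subject_id=subject_id,
        timepoint=timepoint,
        modality=modality,
        weights=values,
        node_labels=labels,
    )


def write_connectome(
    cm: ConnectomeMatrix, path: str | Path, delimiter: str = ",", header: bool = True
) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if header:
            fh.write(delimiter.join(cm.node_labels) + "\n")
        for row in cm.weights:
            fh.write(delimiter.join(repr(float(v)) for v in row) + "\n")


def read_timeseries(path: str | Path) -> np.ndarray:
    """Read a ROI×time timeseries matrix (delimited, optional header)."""
    values, _ = read_matrix(path)
    return values


def write_timeseries(ts: np.ndarray, path: str | Path, delimiter: str = ",") -> None:
    np.savetxt(path, np.asarray(ts, dtype=float), delimiter=delimiter, fmt="%.10g")


# ---------------------------------------------------------------------------
# Cohort metadata
# ---------------------------------------------------------------------------

REQUIRED_COHORT_COLUMNS = ("subject_id", "sex", "ga_birth", "pma_scan1", "pma_scan2")
OPTIONAL_COHORT_COLUMNS = ("mean_fd_tp1", "mean_fd_tp2")


@dataclass
class CohortPanel:
    """Per-subject metadata table.

    ``table`` holds one validated row per subject in input order, with
    ``days_between_scans`` derived as ``(pma_scan2 - pma_scan1) * 7``.
    Rows that violate a row-level invariant (scan ordering, GA vs PMA) are
    dropped into ``rejected`` with a named reason rather than raising.
    """

    table: pd.DataFrame
    rejected: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["subject_id", "reason"])
    )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CohortPanel":
        missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"cohort table missing required columns: {missing}")
        df = df.copy()
        df["subject_id"] = df["subject_id"].astype(str)
        dupes = df["subject_id"][df["subject_id"].duplicated()].unique()
        if len(dupes):
            raise ValidationError(f"duplicate subject_id values: {list(dupes)}")
        df["sex"] = df["sex"].astype(str).str.upper().str.strip()
        bad_sex = set(df["sex"]) - {"M", "F"}
        if bad_sex:
            raise ValidationError(f"sex must be M or F, got {sorted(bad_sex)}")
        for col in ("ga_birth", "pma_scan1", "pma_scan2"):
            df[col] = pd.to_numeric(df[col])
        for col in OPTIONAL_COHORT_COLUMNS:
            if col in df.columns:
                df[col] = pd.to_numeric(df[col])

        reasons = []
        keep = np.ones(len(df), dtype=bool)
        for k, row in enumerate(df.itertuples(index=False)):
            if not row.pma_scan2 > row.pma_scan1:
                keep[k] = False
                reasons.append((row.subject_id, "pma_scan2 <= pma_scan1"))
            elif not row.ga_birth <= row.pma_scan1:
                keep[k] = False
                reasons.append((row.subject_id, "ga_birth > pma_scan1"))
        accepted = df.loc[keep].reset_index(drop=True)
        accepted["days_between_scans"] = (
            accepted["pma_scan2"] - accepted["pma_scan1"]
        ) * 7.0
        rejected = pd.DataFrame(reasons, columns=["subject_id", "reason"])
        for sid, reason in reasons:
            logger.warning("cohort row rejected: subject %s (%s)", sid, reason)
        return cls(table=accepted, rejected=rejected)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.table["subject_id"])

    @property
    def n_subjects(self) -> int:
        return len(self.table)

    def column(self, name: str) -> np.ndarray:
        return self.table[name].to_numpy(dtype=float)

    def has_fd(self) -> bool:
        return all(c in self.table.columns for c in OPTIONAL_COHORT_COLUMNS)

    def subset(self, subject_ids: Sequence[str]) -> "CohortPanel":
        ids = set(subject_ids)
        sub = self.table[self.table["subject_id"].isin(ids)].reset_index(drop=True)
        return CohortPanel(table=sub)


def read_cohort_table(path: str | Path) -> CohortPanel:
    """Read a delimited cohort metadata table (see :class:`CohortPanel`)."""
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [str(c).strip() for c in df.columns]
    return CohortPanel.from_dataframe(df)


def write_cohort_table(panel: CohortPanel, path: str | Path) -> None:
    panel.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Anatomical clusters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClusterDefinition:
    """A named anatomical cluster: member node indices (0-based) into the atlas."""

    name: str
    node_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.node_indices) == 0:
            raise ValidationError(f"cluster {self.name!r} is empty")
        if len(set(self.node_indices)) != len(self.node_indices):
            raise ValidationError(f"cluster {self.name!r} has repeated indices")
        if min(self.node_indices) < 0:
            raise ValidationError(f"cluster {self.name!r} has a negative index")

    @property
    def size(self) -> int:
        return len(self.node_indices)


def _validate_clusters(
    clusters: Sequence[ClusterDefinition], atlas_size: int
) -> None:
    seen: dict[int, str] = {}
    for cl in clusters:
        if max(cl.node_indices) >= atlas_size:
            raise ValidationError(
                f"cluster {cl.name!r} index {max(cl.node_indices)} out of range "
                f"for atlas of {atlas_size} nodes"
            )
        for idx in cl.node_indices:
            if idx in seen:
                raise ValidationError(
                    f"clusters {seen[idx]!r} and {cl.name!r} overlap at node {idx}"
                )
            seen[idx] = cl.name
    names = [cl.name for cl in clusters]
    if atlas_size == STUDY_ATLAS_SIZE and set(names) == set(STUDY_CLUSTER_NAMES):
        expected = dict(zip(STUDY_CLUSTER_NAMES, STUDY_CLUSTER_SIZES))
        for cl in clusters:
            if cl.size != expected[cl.name]:
                raise ValidationError(
                    f"study cluster {cl.name!r} has {cl.size} nodes, "
                    f"expected {expected[cl.name]}"
                )
        if len(seen) != STUDY_ATLAS_SIZE:
            raise ValidationError(
                f"study clusters cover {len(seen)} of {STUDY_ATLAS_SIZE} nodes"
            )


def read_clusters(path: str | Path) -> list[ClusterDefinition]:
    """Read a JSON cluster file.

    The file maps cluster names to index lists, with two reserved keys:
    ``atlas_size`` (number of atlas nodes; default ``max index + 1``) and
    ``index_base`` (0 or 1; default 1, matching atlas table conventions).
    For a 90-node atlas carrying all seven study cluster names, the printed
    size vector (8, 22, 14, 14, 10, 8, 14), disjointness and full coverage
    are enforced.
    """
    path = Path(path)
    try:
        with open(path) as fh:
            raw = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON: {exc}") from None
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: expected a JSON object")
    index_base = int(raw.pop("index_base", 1))
    if index_base not in (0, 1):
        raise FormatError(f"{path}: index_base must be 0 or 1")
    atlas_size = raw.pop("atlas_size", None)
    clusters = []
    for name, indices in raw.items():
        if not isinstance(indices, list):
            raise FormatError(f"{path}: cluster {name!r} must map to a list")
        clusters.append(
            ClusterDefinition(
                name=str(name),
                node_indices=tuple(int(i) - index_base for i in indices),
            )
        )
    if not clusters:
        raise FormatError(f"{path}: no clusters defined")
    if atlas_size is None:
        atlas_size = 1 + max(max(cl.node_indices) for cl in clusters)
    _validate_clusters(clusters, int(atlas_size))
    return clusters


def write_clusters(
    clusters: Sequence[ClusterDefinition],
    path: str | Path,
    atlas_size: int,
    index_base: int = 0,
) -> None:
    payload: dict = {"atlas_size": atlas_size, "index_base": index_base}
    for cl in clusters:
        payload[cl.name] = [i + index_base for i in cl.node_indices]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def study_clusters() -> list[ClusterDefinition]:
    """The seven-cluster partition of the 90-node atlas used throughout.

    The cluster names and sizes (central 8, frontal 22, limbic 14,
    occipital 14, parietal 10, deep grey 8, temporal 14) follow the study
    atlas; the node-to-cluster assignment here is a synthetic stand-in — a
    contiguous block partition in that order — since the synthetic cohort
    carries no anatomical node identity. Analyses of real connectomes
    should supply the true assignment via a cluster file.
    """
    clusters = []
    start = 0
    for name, size in zip(STUDY_CLUSTER_NAMES, STUDY_CLUSTER_SIZES):
        clusters.append(
            ClusterDefinition(name=name, node_indices=tuple(range(start, start + size)))
        )
        start += size
    assert start == STUDY_ATLAS_SIZE
    return clusters
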