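"""Synthetic paired-timepoint cohort generator.

Emulates the statistical structure of a preterm longitudinal cohort: each
subject is scanned once in the preterm period (PMA ~29–37.5 weeks) and once
at term-equivalent age (~38.4–45 weeks), with a structural connectome and a
BOLD-like ROI timeseries per scan.

Structural model (log-additive, so weights are positive without clipping
and edge *ranks* — all that a Spearman-based similarity sees — carry the
signal). A group backbone ``B`` fixes which edges exist; on each backbone
edge the log-weight at a scan of post-menstrual age ``p`` is

    log W = b + gamma * (p - 40) * D + alpha_sc * F_i + sigma_sc * eps

where ``b`` is the shared backbone log-weight, ``D`` a shared developmental
gradient, ``F_i`` the subject's stable fingerprint field, and ``eps`` fresh
scan noise. ``alpha_sc`` dials the structural fingerprint strength, ``gamma``
the per-week developmental drift, ``sigma_sc`` the scan-to-scan noise.

Functional model (latent factor, so every correlation matrix is positive
definite for ``psi > 0``). The loading matrix at age ``p`` is

    L_i(p) = L_group + alpha_fc * L_i + gamma * (p - 40) * L_dev

and the BOLD-like timeseries are i.i.d. draws from the zero-mean
multivariate normal with correlation ``corr(L L' + psi I)``. The subject
term ``alpha_fc * L_i`` is deliberately weak by default: the study regime
has a strong structural but immature functional fingerprint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io import STRUCTURAL, CohortPanel, ConnectomeMatrix

__all__ = ["SyntheticParams", "SyntheticCohort", "simulate_cohort", "simulate_timeseries"]


@dataclass(frozen=True)
class SyntheticParams:
    """Parameters of the generative cohort model (defaults = study regime)."""

    n_subjects: int = 26
    n_nodes: int = 90
    backbone_density: float = 0.6
    alpha_sc: float = 0.5
    alpha_fc: float = 0.08
    gamma: float = 0.05
    sigma_sc: float = 0.2
    n_latent: int = 10
    n_timepoints: int = 2300
    psi: float = 0.5
    pma1_range: tuple[float, float] = (29.3, 37.4)
    pma2_range: tuple[float, float] = (38.4, 45.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
        if self.n_nodes < 3:
            raise ValidationError("n_nodes must be >= 3")
        if not 0 < self.backbone_density <= 1:
            raise ValidationError("backbone_density must be in (0, 1]")
        for name in ("alpha_sc", "alpha_fc", "sigma_sc", "psi"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.psi <= 0:
            raise ValidationError("psi must be > 0 (positive-definite correlation)")
        if self.n_timepoints <= self.n_nodes:
            raise ValidationError(
                "n_timepoints must exceed n_nodes so partial correlation is well-posed"
            )
        for name in ("pma1_range", "pma2_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValidationError(f"{name} must be a non-degenerate (lo, hi) range")
        if self.pma1_range[1] >= self.pma2_range[0]:
            raise ValidationError("pma1_range must lie entirely below pma2_range")


@dataclass
class SyntheticCohort:
    """A simulated cohort: metadata panel, connectomes, timeseries, truth."""

    params: SyntheticParams
    panel: CohortPanel
    sc: dict[tuple[str, int], ConnectomeMatrix]
    ts: dict[tuple[str, int], Optional[np.ndarray]]
    ground_truth: dict

    def sc_pair(self) -> tuple[list[ConnectomeMatrix], list[ConnectomeMatrix]]:
        """Structural connectomes as (timepoint-1 list, timepoint-2 list)."""
        ids = self.panel.subject_ids
        return [self.sc[s, 1] for s in ids], [self.sc[s, 2] for s in ids]

    def ts_pair(self) -> tuple[list[np.ndarray], list[np.ndarray]]:
        ids = self.panel.subject_ids
        tp1 = [self.ts[s, 1] for s in ids]
        tp2 = [self.ts[s, 2] for s in ids]
        if any(t is None for t in tp1 + tp2):
            raise ValidationError("cohort was simulated without timeseries")
        return tp1, tp2


def simulate_timeseries(
    correlation: np.ndarray,
    n_timepoints: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Draw ``n_timepoints`` i.i.d. samples from N(0, correlation).

    Returns an ``n_nodes x n_timepoints`` matrix whose sample correlation
    converges to ``correlation`` as the number of samples grows.
    """
    corr = np.asarray(correlation, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValidationError("correlation must be square")
    if np.abs(corr - corr.T).max() > 1e-10:
        raise ValidationError("correlation must be symmetric")
    if np.abs(np.diagonal(corr) - 1.0).max() > 1e-8:
        raise ValidationError("correlation must have unit diagonal")
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        raise ValidationError("correlation matrix is not positive definite") from None
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return chol @ rng.standard_normal((corr.shape[0], n_timepoints))


def _to_correlation(cov: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diagonal(cov))
    corr = cov / np.outer(d, d)
    np.fill_diagonal(corr, 1.0)
    return 0.5 * (corr + corr.T)


def simulate_cohort(
    params: SyntheticParams, timeseries: bool = True
) -> SyntheticCohort:
    """Generate a paired-timepoint cohort under the documented model.

    The draw order is fixed, so a given seed yields a bit-identical cohort;
    timeseries draws use per-scan child seeds, so ``timeseries=False``
    (a fast path for structural-only experiments) leaves everything else
    unchanged.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    n, m = p.n_nodes, p.n_nodes * (p.n_nodes - 1) // 2
    iu = np.triu_indices(n, k=1)

    present = rng.random(m) < p.backbone_density
    if present.sum() < 3:
        raise ValidationError("backbone has fewer than 3 edges; raise backbone_density")
    b = rng.standard_normal(m)           # backbone log-weights
    drift = rng.standard_normal(m)       # shared developmental gradient D
    L_group = rng.standard_normal((n, p.n_latent))
    L_dev = rng.standard_normal((n, p.n_latent))

    pma1 = rng.uniform(*p.pma1_range, size=p.n_subjects)
    pma2 = rng.uniform(*p.pma2_range, size=p.n_subjects)
    ga = pma1 - rng.uniform(0.5, 4.0, size=p.n_subjects)
    ids = [f"sub-{i + 1:03d}" for i in range(p.n_subjects)]
    sexes = ["M" if i % 2 == 0 else "F" for i in range(p.n_subjects)]

    sc: dict[tuple[str, int], ConnectomeMatrix] = {}
    ts: dict[tuple[str, int], Optional[np.ndarray]] = {}
    truth: dict = {
        "backbone_present": present,
        "backbone_logweights": b,
        "drift": drift,
        "fingerprint_sc": {},
        "fingerprint_fc": {},
    }

    for i, sid in enumerate(ids):
        f_i = rng.standard_normal(m)
        l_i = rng.standard_normal((n, p.n_latent))
        truth["fingerprint_sc"][sid] = f_i
        truth["fingerprint_fc"][sid] = l_i
        for tp, age in ((1, pma1[i]), (2, pma2[i])):
            eps = rng.standard_normal(m)
            logw = (
                b
                + p.gamma * (age - 40.0) * drift
                + p.alpha_sc * f_i
                + p.sigma_sc * eps
            )
            edge_w = np.where(present, np.exp(logw), 0.0)
            w = np.zeros((n, n))
            w[iu] = edge_w
            w += w.T
            sc[sid, tp] = ConnectomeMatrix(
                subject_id=sid, timepoint=tp, modality=STRUCTURAL, weights=w
            )
            ts_seed = int(rng.integers(0, 2**31 - 1))
            if timeseries:
                load = L_group + p.alpha_fc * l_i + p.gamma * (age - 40.0) * L_dev
                cov = load @ load.T + p.psi * np.eye(n)
                corr = _to_correlation(cov)
                ts[sid, tp] = simulate_timeseries(corr, p.n_timepoints, ts_seed)
            else:
                ts[sid, tp] = None

    panel = CohortPanel.from_dataframe(
        pd.DataFrame(
            {
                "subject_id": ids,
                "sex": sexes,
                "ga_birth": ga,
                "pma_scan1": pma1,
                "pma_scan2": pma2,
            }
        )
    )
    if panel.n_subjects != p.n_subjects:  # pragma: no cover - by construction
        raise ValidationError("generated panel failed its own invariants")
    return SyntheticCohort(params=p, panel=panel, sc=sc, ts=ts, ground_truth=truth)
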