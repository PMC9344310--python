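"""Association statistics: similarity versus age, scan interval, and motion.

Models:

* Partial correlation between PMA at scan 1 (or days between scans) and
  self-similarity, controlling for the other — Pearson correlation of
  least-squares residuals, p from the t distribution with n - k - 2
  degrees of freedom (k = number of covariates).
* GLM: ordinary least squares of self-similarity on PMA at timepoint 1 and
  days between scans (with intercept).
* LME: linear mixed-effects model for the self-to-other similarities — one
  observation per ordered off-diagonal pair, cross-subject scan interval
  (column subject's scan 2 minus row subject's scan 1, in days) as fixed
  effect, random intercept per timepoint-1 subject, fitted by REML. PMA at
  timepoint 1 enters as an additional fixed effect by default.
* Bonferroni correction over the seven-cluster family.
* Motion: correlation of mean framewise displacement with self-similarity
  and selection of a low-motion subgroup (both scans below a threshold).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .exceptions import ValidationError
from .io import CohortPanel
from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "RegressionResult",
    "PartialCorrelationResult",
    "MotionResult",
    "partial_corr",
    "glm_self_similarity",
    "lme_self_to_other",
    "bonferroni",
    "motion_analysis",
]


@dataclass
class RegressionResult:
    terms: list[str]
    beta: dict[str, float]
    p_value: dict[str, float]
    n_obs: int
    model: str  # "ols" or "lme"
    extra: dict | None = None

    def __post_init__(self) -> None:
        for t in self.terms:
            if t not in self.beta or t not in self.p_value:
                raise ValidationError(f"missing coefficient for term {t!r}")
        for t, p in self.p_value.items():
            if not (np.isnan(p) or 0 <= p <= 1):
                raise ValidationError(f"p-value for {t!r} outside [0, 1]: {p}")


@dataclass
class PartialCorrelationResult:
    r: float
    p_value: float
    n: int
    covariates: list[str]


def _residualize(y: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    x = np.column_stack([np.ones(len(y)), covariates])
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta


def partial_corr(
    x: Sequence[float],
    y: Sequence[float],
    covariates: Optional[np.ndarray] = None,
    covariate_names: Optional[Sequence[str]] = None,
    method: str = "pearson",
) -> PartialCorrelationResult:
    """Correlation of x and y after removing covariates from both.

    With no covariates this is the plain correlation. ``method='spearman'``
    rank-transforms the residuals before correlating.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D vectors")
    n = x.size
    if covariates is None or (hasattr(covariates, "size") and covariates.size == 0):
        cov = np.empty((n, 0))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.shape[0] != n:
            raise ValidationError("covariates must have one row per observation")
    k = cov.shape[1]
    if n <= k + 3:
        raise ValidationError(f"need n > k + 3 observations (n={n}, k={k})")
    if k and np.linalg.matrix_rank(np.column_stack([np.ones(n), cov])) < k + 1:
        raise ValidationError("covariate matrix is rank deficient")
    rx = _residualize(x, cov)
    ry = _residualize(y, cov)
    # a variable fully explained by the covariates leaves numerically zero
    # residuals; its partial correlation with anything is 0 by convention
    for resid, orig in ((rx, x), (ry, y)):
        scale = float(np.std(orig)) or 1.0
        if np.std(resid) <= 1e-10 * scale:
            names = list(covariate_names) if covariate_names else [
                f"c{i}" for i in range(k)
            ]
            return PartialCorrelationResult(r=0.0, p_value=1.0, n=n, covariates=names)
    if method == "spearman":
        rx = sps.rankdata(rx)
        ry = sps.rankdata(ry)
    elif method != "pearson":
        raise ValidationError("method must be 'pearson' or 'spearman'")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - k - 2
    r_clip = min(max(r, -0.9999999999), 0.9999999999)
    t = r_clip * np.sqrt(df / (1 - r_clip**2))
    p = float(2 * sps.t.sf(abs(t), df))
    names = list(covariate_names) if covariate_names else [f"c{i}" for i in range(k)]
    return PartialCorrelationResult(r=r, p_value=p, n=n, covariates=names)


def glm_self_similarity(
    self_sim: Sequence[float],
    pma1: Sequence[float],
    days: Sequence[float],
) -> RegressionResult:
    """OLS of self-similarity on PMA at scan 1 and days between scans."""
    y = np.asarray(self_sim, dtype=float)
    pma1 = np.asarray(pma1, dtype=float)
    days = np.asarray(days, dtype=float)
    if not (len(y) == len(pma1) == len(days)):
        raise ValidationError("input vectors must have equal length")
    if len(y) < 5:
        raise ValidationError("need at least 5 observations")
    X = sm.add_constant(
        pd.DataFrame({"pma_scan1": pma1, "days_between_scans": days})
    )
    cond = np.linalg.cond(np.asarray(X, dtype=float))
    if cond > 1e8:
        logger.warning(
            "design matrix condition number %.3g: pma_scan1 and "
            "days_between_scans are nearly collinear", cond,
        )
    fit = sm.OLS(y, X).fit()
    terms = list(X.columns)
    return RegressionResult(
        terms=terms,
        beta={t: float(fit.params[t]) for t in terms},
        p_value={t: float(fit.pvalues[t]) for t in terms},
        n_obs=int(fit.nobs),
        model="ols",
        extra={"condition_number": float(cond), "r_squared": float(fit.rsquared)},
    )


def self_to_other_frame(s: SimilarityMatrix, panel: CohortPanel) -> pd.DataFrame:
    """Long table of the N(N-1) off-diagonal similarities.

    Each row pairs subject i's timepoint-1 scan with subject j's
    timepoint-2 scan (i != j): the cross-subject scan interval is
    ``(pma_scan2[j] - pma_scan1[i]) * 7`` days, and the grouping label is
    the timepoint-1 subject i.
    """
    ids = s.subjects
    panel_ids = panel.subject_ids
    if set(ids) - set(panel_ids):
        raise ValidationError("similarity subjects missing from cohort panel")
    tab = panel.table.set_index("subject_id")
    pma1 = tab.loc[ids, "pma_scan1"].to_numpy(dtype=float)
    pma2 = tab.loc[ids, "pma_scan2"].to_numpy(dtype=float)
    rows = []
    for i, sid_i in enumerate(ids):
        for j, sid_j in enumerate(ids):
            if i == j:
                continue
            rows.append(
                (
                    sid_i,
                    sid_j,
                    s.values[i, j],
                    (pma2[j] - pma1[i]) * 7.0,
                    pma1[i],
                )
            )
    return pd.DataFrame(
        rows,
        columns=["subject_tp1", "subject_tp2", "similarity", "days", "pma_scan1"],
    )


def lme_self_to_other(
    s: SimilarityMatrix,
    panel: CohortPanel,
    include_pma: bool = True,
    reml: bool = True,
) -> RegressionResult:
    """Mixed model for self-to-other similarity vs cross-subject interval.

    Random intercept per timepoint-1 subject; fixed effects: days (and PMA
    at timepoint 1 unless ``include_pma=False``). A near-zero random-effect
    variance is returned with a warning rather than raised.
    """
    frame = self_to_other_frame(s, panel)
    fixed = ["days"] + (["pma_scan1"] if include_pma else [])
    exog = sm.add_constant(frame[fixed])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(
            endog=frame["similarity"].to_numpy(),
            exog=exog,
            groups=frame["subject_tp1"].to_numpy(),
        )
        fit = model.fit(reml=reml)
    re_var = float(np.asarray(fit.cov_re).ravel()[0])
    if re_var < 1e-12:
        logger.warning(
            "random-intercept variance estimated at boundary (%.3g); "
            "fixed effects coincide with OLS", re_var,
        )
    terms = ["const"] + fixed
    return RegressionResult(
        terms=terms,
        beta={t: float(fit.params[t]) for t in terms},
        p_value={t: float(fit.pvalues[t]) for t in terms},
        n_obs=int(len(frame)),
        model="lme",
        extra={
            "random_intercept_var": re_var,
            "residual_var": float(fit.scale),
            "n_groups": int(frame["subject_tp1"].nunique()),
        },
    )


def bonferroni(
    p_values: Sequence[float], m: Optional[int] = None, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Bonferroni adjustment: ``min(1, p * m)`` and significance at alpha."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValidationError(f"family size m={m} smaller than {p.size} tests")
    adjusted = np.minimum(1.0, p * m)
    return adjusted, adjusted < alpha


@dataclass
class MotionResult:
    correlation: PartialCorrelationResult      # mean FD (both scans) vs self-sim
    per_timepoint: dict[int, PartialCorrelationResult]
    subgroup: CohortPanel                      # both scans' mean FD < threshold
    fd_threshold: float


def motion_analysis(
    self_sim: Sequence[float],
    panel: CohortPanel,
    fd_threshold: float = 0.3,
) -> MotionResult:
    """Association of head motion with self-similarity + low-motion subgroup.

    ``self_sim`` is ordered like ``panel``. The headline correlation uses
    each subject's mean FD averaged over the two scans; per-scan
    correlations are also reported. The subgroup keeps subjects whose mean
    FD is below the threshold at both timepoints.
    """
    if not panel.has_fd():
        raise ValidationError("cohort panel lacks mean_fd_tp1/mean_fd_tp2 columns")
    y = np.asarray(self_sim, dtype=float)
    if y.size != panel.n_subjects:
        raise ValidationError("self_sim length must match the panel")
    fd1 = panel.column("mean_fd_tp1")
    fd2 = panel.column("mean_fd_tp2")
    mean_fd = 0.5 * (fd1 + fd2)
    corr = partial_corr(mean_fd, y)
    per_tp = {1: partial_corr(fd1, y), 2: partial_corr(fd2, y)}
    keep = (fd1 < fd_threshold) & (fd2 < fd_threshold)
    ids = [sid for sid, k in zip(panel.subject_ids, keep) if k]
    if not ids:
        logger.warning(
            "FD threshold %.3g mm leaves an empty subgroup", fd_threshold
        )
    subgroup = panel.subset(ids)
    return MotionResult(
        correlation=corr,
        per_timepoint=per_tp,
        subgroup=subgroup,
        fd_threshold=fd_threshold,
    )
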