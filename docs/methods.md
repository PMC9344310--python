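# Methods

This note documents the models and numerical choices behind `connfp`: the
fingerprinting procedure itself, the generative model that stands in for
MRI-derived cohorts, the association statistics, and the places where the
design was genuinely open and a choice had to be made.

## 1. The fingerprinting procedure

**Connectome contract.** A connectome is a symmetric non-negative weighted
adjacency matrix with zero diagonal. Asymmetries up to `1e-10` are averaged
away; anything larger is rejected rather than silently symmetrized, since
it usually signals a file mix-up. Nonzero diagonals (functional matrices
routinely carry 1.0) are zeroed: no analysis ever reads the diagonal.
Functional weights are additionally bounded by 1; negatives must already be
zeroed (the FC builders do this). Structural weights may be on any
monotone scale (raw or log streamline weights) — every similarity here is a
rank correlation, so monotone rescaling is irrelevant, and the reader
deliberately does not try to guess the scale.

**Density masking.** "Network density d" counts over all possible node
pairs: the mask keeps the `ceil(d·n(n−1)/2)` largest upper-triangle weights
of the *timepoint-1* matrix. Ties at the cutoff are broken by ascending
(i, j) lexicographic pair order — arbitrary but deterministic; with
continuous weights ties essentially never occur. If d exceeds the nonzero
fraction, zero-weight pairs are retained (and logged) rather than silently
shrinking the mask, so the retained-pair count is always exactly the
advertised function of d and n.

**Mask convention for cross-subject entries.** Thresholding is specified
per subject at timepoint 1, which leaves open whose mask applies when
comparing subject i's scan 1 to subject j's scan 2. The default is the ROW
subject's mask (subject i's): every entry in row i then compares the same
edge set, which is what makes the row-wise match criterion, row-max
normalization and row z-scores commensurable. Union and intersection masks
are available (`mask_convention=`) for sensitivity analysis; self
comparisons are identical under all three.

**Identification.** Strict inequality: a tie between self-similarity and
the best other is a non-match (logged). Ties have probability zero for
continuous data; the policy only matters for degenerate inputs and keeps
the rate conservative.

**Row transforms.** Row-max normalization divides each row by its maximum
(requires positive row maxima); z-scoring standardizes each row with the
sample (N−1) standard deviation. Both are strictly monotone within a row,
hence provably identification-preserving — asserted as a property test
rather than assumed.

**Regional analysis.** A cluster's connectome is its within-cluster k×k
submatrix; the density threshold is recomputed on the cluster's own
k(k−1)/2 pair count, and the whole procedure is rerun. The alternative
reading — all edges with at least one endpoint in the cluster — is
implemented behind `edge_scope="to_all"`; the within-cluster form is the
default because "repeating the analysis in a cluster" most directly means
analysing that cluster's internal connectome. Clusters whose pair count
would retain fewer than 3 edges at the requested density are rejected.
The built-in seven-cluster definition (central 8, frontal 22, limbic 14,
occipital 14, parietal 10, deep grey 8, temporal 14 nodes; 90 total) uses
a contiguous block partition as a synthetic stand-in for the anatomical
assignment, which users with real atlas tables supply as a JSON cluster
file (1-based indices by default, `index_base: 0` supported).

## 2. Functional connectivity

Pearson FC is `max(0, corr(ROI_i, ROI_j))`. Partial-correlation FC comes
from the precision matrix of the sample covariance,
`pc(i,j) = −P_ij/√(P_ii P_jj)`, negatives zeroed afterwards — zeroing
happens strictly after the correlation computation, never inside it.
Partial correlation requires more samples than ROIs; an optional ridge term
(`ridge·mean(diag(cov))·I`, default off) handles near-singular covariances,
off by default because the intended data regime (2300 samples, 90 ROIs) is
far from singular. Constant-signal ROIs are an error naming the offending
ROI index. No scrubbing, filtering or detrending is applied — timeseries
arrive fully preprocessed.

## 3. The synthetic cohort generator

The generator emulates the *statistical* structure of a preterm
longitudinal cohort, not its biology: N subjects, PMA at scan 1 uniform in
[29.3, 37.4] weeks, PMA at scan 2 uniform in [38.4, 45.0] weeks, GA at
birth 0.5–4 weeks below PMA at scan 1, sex alternating (generated only to
exercise the metadata path; no sex effect is modelled).

**Structural.** A group backbone B keeps each of the n(n−1)/2 edges with
probability `backbone_density` (0.6) and gives kept edges log-weights
b ~ N(0,1). At a scan of age p (weeks),

    log W = b + gamma·(p − 40)·D + alpha_sc·F_i + sigma_sc·eps

with D a shared developmental gradient, F_i the subject's stable
fingerprint field, eps fresh noise per scan (all i.i.d. N(0,1) per edge).
The model is log-additive so weights are positive without clipping; since
the analysis is rank-based, only the induced edge ranks matter.

**Functional.** Loadings L_i(p) = L_group + alpha_fc·L_i + gamma·(p−40)·L_dev
(n×k matrices, k = `n_latent` = 10), covariance L·Lᵀ + psi·I (psi = 0.5 > 0
guarantees positive definiteness), converted to a correlation matrix, from
which `n_timepoints` (2300) i.i.d. BOLD-like samples are drawn. The sample
FC therefore carries estimation noise on top of the loading structure,
exactly as real FC does.

**Defaults and what they target.** The defaults encode the study regime
the package is meant to emulate: a strong structural fingerprint and a
barely-present functional one.

| parameter | default | role |
|---|---|---|
| `alpha_sc` | 0.5 | structural fingerprint strength; with `sigma_sc=0.2` and `gamma=0.05` gives whole-brain structural identifiability near 1.0 and mean self/other Spearman ≈ 0.69/0.44 at N=26–45 |
| `alpha_fc` | 0.08 | functional fingerprint strength; calibrated once so the functional identifiability rate at N≈26–31 sits near 10% — just above the 1/N chance level — matching the immature-functional-fingerprint regime |
| `gamma` | 0.05/week | shared developmental drift; makes similarity decay with the PMA gap between the two scans, which is what drives the negative interval effect on functional self-to-other similarity |
| `sigma_sc` | 0.2 | scan-to-scan log-noise |
| `psi` | 0.5 | unique variance of the FC factor model |
| `n_timepoints` | 2300 | BOLD samples per scan (15 min at TR ≈ 0.39 s) |

No quantitative description of inter-subject weight dispersion exists to
fit against, so these are regime-matching choices, fixed once and
documented here; they are not re-tuned per analysis.

**What the generator does not model** — and hence what passing tests do
not establish about real data: haemodynamics and autocorrelated BOLD noise
(samples are i.i.d.), motion artefacts (mean FD enters only as a metadata
covariate; the motion unit tests plant their own confound), spatial node
geometry and distance-dependent connectivity, lognormal weight/degree
distributions of real tractography, and any sex or GA-at-birth effect.
Results on synthetic cohorts validate the *procedure* (calibration,
monotonicity, invariances, coefficient recovery), not empirical claims
about infants.

**Determinism.** One `numpy` Generator drives all draws in a fixed order;
per-scan timeseries use child seeds drawn from that stream, so skipping
timeseries (`timeseries=False`, the fast path for structural-only work)
leaves everything else bit-identical. The same seed yields a bit-identical
cohort.

## 4. Association statistics

**Partial correlation** is Pearson correlation of least-squares residuals
(the standard definition; a Spearman variant sits behind `method=`), with
p from the t distribution on n − k − 2 degrees of freedom. If either
variable is numerically fully explained by the covariates, r = 0 and p = 1
are returned by convention rather than correlating residual noise at
machine precision.

**GLM.** OLS of self-similarity on PMA at scan 1 and days between scans,
with intercept; near-collinearity is logged (condition number) but the fit
is still returned.

**LME for self-to-other similarity.** One observation per ordered
off-diagonal pair (N(N−1) rows); the predictor is the *cross-subject*
interval — column subject's PMA at scan 2 minus row subject's PMA at
scan 1, times 7 — the only definition under which an interval exists
between different subjects' scans. Random intercept per timepoint-1
subject, REML via `statsmodels.MixedLM`. PMA at scan 1 is included as a
second fixed effect by default because the interval-only and
interval-plus-age forms answer different questions and the age-adjusted
form is the more conservative default; `include_pma=False`
(`lme_form: days_only`) gives the pure-interval model. A random-intercept
variance estimated at the boundary is returned with a warning, where the
fixed effects coincide with OLS.

**Multiple comparisons.** Bonferroni with family size m = 7 (the clusters)
per modality and per predictor, α = 0.05. The family is configurable
(`bonferroni_m`) since the appropriate family depends on the hypotheses a
user actually tests.

**Motion.** The headline FD association uses each subject's mean FD
averaged over the two scans (per-scan correlations are also reported), as
a plain correlation; the low-motion subgroup keeps subjects below the
threshold (default 0.3 mm) at *both* scans. A zero threshold yields an
empty subgroup with a warning, not an error.

## 5. Numerical and degenerate-input policy

- Spearman ties receive average ranks (scipy); the brute-force oracle in
  the test suite recomputes average ranks independently and agrees to
  1e-12 on short vectors.
- Similarity needs ≥ 3 retained pairs; z-scoring needs ≥ 3 columns and
  nonzero row variance; row-max normalization needs positive row maxima.
  All violations raise typed errors rather than emitting NaN.
- Cohort rows violating scan ordering (PMA₂ ≤ PMA₁) or GA > PMA₁ are
  dropped with named reasons; duplicate subject ids and missing columns
  abort the load. Validation is row-order independent.
- The report bundle written by `run_analysis` is a pure function of
  (config, input bytes, seed): manifests carry no timestamps and omit the
  output path itself.

## 6. Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run entirely on simulated
cohorts sized to the study design they emulate: 45 subjects for the
structural arm, 31 for the functional arm, 26 for the joint association
models; calibration checks use 100–200 cohorts of N = 10 (null rate) and
50 seeds × N = 20 (monotonicity in `alpha_sc`). Unit tests use smaller
atlases (10–40 nodes) where the property under test does not depend on
atlas size.
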