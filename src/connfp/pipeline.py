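"""End-to-end analysis orchestration.

``run_analysis`` drives the full procedure from a single config: obtain a
cohort (simulated or read from disk), build functional connectomes from
timeseries, compute similarity matrices and identifiability per modality
(density-thresholded and unmasked), rerun the analysis per anatomical
cluster, fit the age/interval association models, and write every result
as delimited or JSON text plus a run manifest. The report bundle is a pure
function of (config, input bytes, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import ConfigError
from .fc import partial_fc, pearson_fc
from .io import (
    FUNCTIONAL_PARTIAL,
    FUNCTIONAL_PEARSON,
    STRUCTURAL,
    STUDY_ATLAS_SIZE,
    CohortPanel,
    ConnectomeMatrix,
    read_clusters,
    read_cohort_table,
    read_connectome,
    read_timeseries,
    study_clusters,
    write_cohort_table,
    write_clusters,
    write_connectome,
    write_timeseries,
)
from .regional import regional_pipeline
from .similarity import (
    identifiability,
    row_max_normalize,
    similarity_matrix,
    threshold_sweep,
    zscore_rows,
)
from .simulate import SyntheticCohort, SyntheticParams, simulate_cohort
from .stats import (
    bonferroni,
    glm_self_similarity,
    lme_self_to_other,
    motion_analysis,
    partial_corr,
)

logger = logging.getLogger(__name__)

FC_METRICS = ("pearson", "partial", "both", "none")
LME_FORMS = ("days_only", "days_plus_pma")


@dataclass
class AnalysisConfig:
    """Configuration of one end-to-end run (exactly one cohort source)."""

    out_dir: str
    simulate: Optional[dict] = None
    inputs: Optional[dict] = None
    density: float = 0.25
    mask_convention: str = "row"
    fc_metric: str = "pearson"
    clusters: Optional[str] = None   # path; default: built-in study clusters
    edge_scope: str = "within"
    lme_form: str = "days_plus_pma"
    bonferroni_m: int = 7
    fd_threshold: float = 0.3
    sweep_densities: Optional[list[float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ConfigError(
                "exactly one of 'simulate' and 'inputs' must be configured"
            )
        if not 0 < self.density <= 1:
            raise ConfigError(f"density must be in (0, 1], got {self.density}")
        if self.fc_metric not in FC_METRICS:
            raise ConfigError(f"fc_metric must be one of {FC_METRICS}")
        if self.lme_form not in LME_FORMS:
            raise ConfigError(f"lme_form must be one of {LME_FORMS}")
        if self.inputs is not None:
            missing = [
                k for k in ("cohort_table", "connectome_dir") if k not in self.inputs
            ]
            if missing:
                raise ConfigError(f"inputs block missing keys: {missing}")
            for key in ("cohort_table", "connectome_dir", "timeseries_dir"):
                if key in self.inputs and not Path(self.inputs[key]).exists():
                    raise ConfigError(f"input path does not exist: {self.inputs[key]}")
        if self.clusters is not None and not Path(self.clusters).exists():
            raise ConfigError(f"clusters file does not exist: {self.clusters}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


# ---------------------------------------------------------------------------
# Cohort acquisition
# ---------------------------------------------------------------------------


def write_cohort_dir(cohort: SyntheticCohort, out_dir: str | Path) -> None:
    """Write a simulated cohort in the on-disk layout the pipeline reads.

    ``cohort.csv``, ``clusters.json`` (study partition when the atlas has
    90 nodes), ``connectomes/<sid>_tp<k>_sc.csv`` and, when present,
    ``timeseries/<sid>_tp<k>_ts.csv``.
    """
    out = Path(out_dir)
    (out / "connectomes").mkdir(parents=True, exist_ok=True)
    write_cohort_table(cohort.panel, out / "cohort.csv")
    if cohort.params.n_nodes == STUDY_ATLAS_SIZE:
        write_clusters(study_clusters(), out / "clusters.json", STUDY_ATLAS_SIZE, 0)
    for (sid, tp), cm in cohort.sc.items():
        write_connectome(cm, out / "connectomes" / f"{sid}_tp{tp}_sc.csv")
    if any(t is not None for t in cohort.ts.values()):
        (out / "timeseries").mkdir(exist_ok=True)
        for (sid, tp), ts in cohort.ts.items():
            if ts is not None:
                write_timeseries(ts, out / "timeseries" / f"{sid}_tp{tp}_ts.csv")


def _load_inputs(
    inputs: dict,
) -> tuple[CohortPanel, dict[tuple[str, int], ConnectomeMatrix], dict]:
    panel = read_cohort_table(inputs["cohort_table"])
    conn_dir = Path(inputs["connectome_dir"])
    sc = {}
    for sid in panel.subject_ids:
        for tp in (1, 2):
            path = conn_dir / f"{sid}_tp{tp}_sc.csv"
            if not path.exists():
                raise ConfigError(f"missing connectome file {path}")
            sc[sid, tp] = read_connectome(path, sid, tp, STRUCTURAL)
    ts = {}
    ts_dir = inputs.get("timeseries_dir")
    if ts_dir:
        for sid in panel.subject_ids:
            for tp in (1, 2):
                path = Path(ts_dir) / f"{sid}_tp{tp}_ts.csv"
                if not path.exists():
                    raise ConfigError(f"missing timeseries file {path}")
                ts[sid, tp] = read_timeseries(path)
    return panel, sc, ts


# ---------------------------------------------------------------------------
# Reporting helpers
# ---------------------------------------------------------------------------


def _write_matrix_csv(sim, path: Path) -> None:
    sim.to_frame().to_csv(path, float_format="%.10g")


def _ident_summary(res) -> dict:
    return {
        "n_matched": res.n_matched,
        "n_total": res.n_total,
        "rate": res.rate,
        "mean_self_similarity": float(np.mean(res.self_similarities)),
        "mean_other_similarity": float(np.mean(res.other_similarities)),
    }


def _json_dump(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def run_analysis(config: AnalysisConfig) -> dict:
    """Execute the full analysis; returns the summary also written to disk."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.simulate is not None:
        block = dict(config.simulate)
        block.setdefault("seed", config.seed)
        params = SyntheticParams(**block)
        logger.info("simulating cohort: %s", params)
        want_ts = config.fc_metric != "none"
        cohort = simulate_cohort(params, timeseries=want_ts)
        panel, sc, ts = cohort.panel, cohort.sc, cohort.ts
        if not want_ts:
            ts = {}
    else:
        panel, sc, ts = _load_inputs(config.inputs)
    logger.info("cohort: %d subjects", panel.n_subjects)

    ids = panel.subject_ids
    n_nodes = sc[ids[0], 1].n_nodes

    if config.clusters is not None:
        clusters = read_clusters(config.clusters)
    elif n_nodes == STUDY_ATLAS_SIZE:
        clusters = study_clusters()
    else:
        clusters = []

    # assemble per-modality (tp1, tp2) connectome lists
    modalities: dict[str, tuple[list, list]] = {
        STRUCTURAL: (
            [sc[s, 1] for s in ids],
            [sc[s, 2] for s in ids],
        )
    }
    has_ts = bool(ts) and all((s, tp) in ts and ts[s, tp] is not None
                              for s in ids for tp in (1, 2))
    if has_ts and config.fc_metric in ("pearson", "both"):
        modalities[FUNCTIONAL_PEARSON] = (
            [pearson_fc(ts[s, 1], s, 1) for s in ids],
            [pearson_fc(ts[s, 2], s, 2) for s in ids],
        )
    if has_ts and config.fc_metric in ("partial", "both"):
        modalities[FUNCTIONAL_PARTIAL] = (
            [partial_fc(ts[s, 1], s, 1) for s in ids],
            [partial_fc(ts[s, 2], s, 2) for s in ids],
        )

    pma1 = panel.column("pma_scan1")
    days = panel.column("days_between_scans")

    summary: dict = {"n_subjects": panel.n_subjects, "modalities": {}}
    for mod, (tp1, tp2) in modalities.items():
        logger.info("modality %s: similarity at density %.3g", mod, config.density)
        sim = similarity_matrix(
            tp1, tp2, density=config.density, mask_convention=config.mask_convention
        )
        sim_unmasked = similarity_matrix(tp1, tp2, density=None)
        ident = identifiability(sim)
        ident_unmasked = identifiability(sim_unmasked)
        norm = row_max_normalize(sim)
        z = zscore_rows(sim)
        _write_matrix_csv(sim, out / f"similarity_{mod}.csv")
        _write_matrix_csv(norm, out / f"similarity_{mod}_normalized.csv")
        _write_matrix_csv(z, out / f"similarity_{mod}_zscore.csv")

        self_sim = sim.self_similarities
        glm = glm_self_similarity(self_sim, pma1, days)
        pc_pma = partial_corr(pma1, self_sim, days, covariate_names=["days"])
        pc_days = partial_corr(days, self_sim, pma1, covariate_names=["pma_scan1"])
        lme = lme_self_to_other(
            sim, panel, include_pma=(config.lme_form == "days_plus_pma")
        )

        mod_summary: dict = {
            "identifiability": _ident_summary(ident),
            "identifiability_unmasked": _ident_summary(ident_unmasked),
            "glm": {"beta": glm.beta, "p_value": glm.p_value, "n_obs": glm.n_obs},
            "partial_corr_pma1": {"r": pc_pma.r, "p_value": pc_pma.p_value},
            "partial_corr_days": {"r": pc_days.r, "p_value": pc_days.p_value},
            "lme": {"beta": lme.beta, "p_value": lme.p_value, "n_obs": lme.n_obs,
                    "random_intercept_var": lme.extra["random_intercept_var"]},
        }

        if clusters:
            regional = regional_pipeline(
                tp1,
                tp2,
                clusters,
                density=config.density,
                mask_convention=config.mask_convention,
                edge_scope=config.edge_scope,
            )
            rows = []
            cluster_p_pma, cluster_p_days = [], []
            for name, res in regional.items():
                cglm = glm_self_similarity(
                    res.similarity.self_similarities, pma1, days
                )
                cluster_p_pma.append(cglm.p_value["pma_scan1"])
                cluster_p_days.append(cglm.p_value["days_between_scans"])
                rows.append(
                    {
                        "cluster": name,
                        "n_nodes": res.cluster.size,
                        "n_matched": res.identifiability.n_matched,
                        "n_total": res.identifiability.n_total,
                        "rate": res.identifiability.rate,
                        "beta_pma1": cglm.beta["pma_scan1"],
                        "p_pma1": cglm.p_value["pma_scan1"],
                        "beta_days": cglm.beta["days_between_scans"],
                        "p_days": cglm.p_value["days_between_scans"],
                    }
                )
            adj_pma, sig_pma = bonferroni(cluster_p_pma, m=config.bonferroni_m)
            adj_days, sig_days = bonferroni(cluster_p_days, m=config.bonferroni_m)
            for row, ap, sp, ad, sd_ in zip(rows, adj_pma, sig_pma, adj_days, sig_days):
                row["p_pma1_bonferroni"] = float(ap)
                row["sig_pma1_bonferroni"] = bool(sp)
                row["p_days_bonferroni"] = float(ad)
                row["sig_days_bonferroni"] = bool(sd_)
            reg_table = pd.DataFrame(rows)
            reg_table.to_csv(
                out / f"regional_{mod}.csv", index=False, float_format="%.10g"
            )
            mod_summary["regional"] = {
                r["cluster"]: {"rate": r["rate"], "n_matched": r["n_matched"]}
                for r in rows
            }

        if panel.has_fd():
            motion = motion_analysis(self_sim, panel, config.fd_threshold)
            mod_summary["motion"] = {
                "r": motion.correlation.r,
                "p_value": motion.correlation.p_value,
                "subgroup_n": motion.subgroup.n_subjects,
                "fd_threshold": config.fd_threshold,
            }

        if config.sweep_densities:
            sweep = threshold_sweep(
                tp1, tp2, config.sweep_densities, config.mask_convention
            )
            sweep.table.to_csv(
                out / f"sweep_{mod}.csv", index=False, float_format="%.10g"
            )
            mod_summary["sweep_best_densities"] = sweep.best_densities

        summary["modalities"][mod] = mod_summary

    _json_dump(summary, out / "identifiability.json")
    manifest = {
        "package": "connfp",
        "version": __version__,
        "seed": config.seed,
        # out_dir is wherever the bundle sits; recording it would make the
        # bundle depend on its own location
        "config": {
            k: v
            for k, v in dataclasses.asdict(config).items()
            if v is not None and k != "out_dir"
        },
        "n_subjects": panel.n_subjects,
        "n_nodes": n_nodes,
        "modalities": sorted(modalities),
        "clusters": [c.name for c in clusters],
    }
    _json_dump(manifest, out / "manifest.json")
    return summary
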