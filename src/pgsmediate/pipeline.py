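"""End-to-end orchestration: simulate -> connectivity -> metrics -> g ->
polygenic score -> mediation -> reliability, with deterministic seeding and a
manifest of everything written.

Stage order follows the analysis strategy: coherence networks per band and
session, session-mean networks, group-level Holm-Bonferroni pruning, graph
metrics, the second-order g factor, genotype/sample QC and best-fit C+T
polygenic scoring, the 3-IQR participant outlier screen, partial
correlations, global mediation per band, ten exploratory mediation models
per participant group (whole / young / older, split at the age cutoff), and
ICC(3,1) test-retest reliability of all metrics across the two sessions.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .connectivity import all_band_coherence, segment_epochs
from .genetics import (
    PgsThresholdSearch,
    pc_outlier_filter,
    relatedness_filter,
    sample_qc,
    snp_qc,
)
from .gfactor import SecondOrderCFA, residualize_scores
from .mediation import PenaltyConfig, global_mediation, partial_correlation, run_band_models
from .networks import HolmBonferroniPruner, graph_metrics, remove_outliers
from .reliability import reliability_map
from .simulate import CohortConfig, SyntheticCohort, simulate_cohort

__all__ = ["PipelineConfig", "split_cohort", "run_pipeline"]

log = logging.getLogger("pgsmediate")

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """One config for the whole run; every module default is overridable."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    networks_mode: str = "direct"  # 'direct' (edge model) or 'timeseries'
    prune_alpha: float = 0.01
    age_cutoff: float = 40.0
    boundary_in_young: bool = True  # age == cutoff goes to the young group
    outlier_iqr: float = 3.0
    pgs_grid_step: float = 5e-5
    n_permutations: int = 1000
    penalty: PenaltyConfig = field(default_factory=PenaltyConfig)
    t_med: float = 0.001
    t_path: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.networks_mode not in ("direct", "timeseries"):
            raise ValueError("networks_mode must be 'direct' or 'timeseries'")
        # one master seed drives the cohort and every stochastic stage
        self.cohort = (
            self.cohort
            if isinstance(self.cohort, CohortConfig)
            else CohortConfig(**self.cohort)
        )
        self.penalty = (
            self.penalty
            if isinstance(self.penalty, PenaltyConfig)
            else PenaltyConfig(**self.penalty)
        )


def split_cohort(
    covariates: pd.DataFrame, cutoff: float = 40.0, boundary_in_young: bool = True
) -> tuple[pd.Index, pd.Index]:
    """Partition participants into young / older groups at the age cutoff."""
    age = covariates["age"]
    young = age <= cutoff if boundary_in_young else age < cutoff
    young_ids, older_ids = covariates.index[young], covariates.index[~young]
    if len(young_ids) == 0 or len(older_ids) == 0:
        raise ValueError("age split produced an empty group")
    return young_ids, older_ids


# ---------------------------------------------------------------------------
# helpers


def _session_networks(cohort: SyntheticCohort, cfg: PipelineConfig) -> dict[str, np.ndarray]:
    """band -> (n, 2, R, R) weighted networks, from either generator path."""
    if cfg.networks_mode == "direct":
        assert cohort.networks is not None
        return cohort.networks
    bands = cohort.config.band_definitions()
    n, nroi = cohort.config.n_participants, cohort.config.n_rois
    out = {b.name: np.empty((n, 2, nroi, nroi)) for b in bands}
    assert cohort.roi_timeseries is not None
    for i, (pid, ts1, ts2) in enumerate(cohort.roi_timeseries):
        for s_idx, ts in enumerate((ts1, ts2)):
            epochs = segment_epochs(ts, cohort.config.sample_rate)
            nets = all_band_coherence(epochs, bands, session=f"ec{s_idx + 1}")
            for b in bands:
                out[b.name][i, s_idx] = nets[b.name].w
    return out


def _metric_tables(
    nets: dict[str, np.ndarray], ids: list[str], prune_alpha: float
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Tidy metric tables for the session-mean, EC1 and EC2 networks.

    Pruning masks are learned per band on the session-mean networks and
    applied to all three variants, so per-session metrics live on the
    group-pruned graph.
    """
    frames = {"mean": [], "ec1": [], "ec2": []}
    removed = {}
    for band, arr in nets.items():
        mean_nets = arr.mean(axis=1)
        pruner = HolmBonferroniPruner(alpha=prune_alpha).fit(list(mean_nets))
        removed[band] = pruner.result_.n_removed
        mask = pruner.keep_mask_
        for tag, mats in (
            ("mean", mean_nets),
            ("ec1", arr[:, 0]),
            ("ec2", arr[:, 1]),
        ):
            for i, pid in enumerate(ids):
                m = graph_metrics(np.where(mask, mats[i], 0.0))
                rows = [
                    (pid, band, "global_efficiency", -1, m.E),
                    (pid, band, "global_clustering", -1, m.C),
                ]
                rows += [
                    (pid, band, "nodal_efficiency", r, m.E_i[r]) for r in range(len(m.E_i))
                ]
                rows += [
                    (pid, band, "local_clustering", r, m.C_i[r]) for r in range(len(m.C_i))
                ]
                frames[tag].append(
                    pd.DataFrame(
                        rows, columns=["participant", "band", "metric", "roi", "value"]
                    )
                )
    tables = {tag: pd.concat(fr, ignore_index=True) for tag, fr in frames.items()}
    return tables["mean"], tables["ec1"], tables["ec2"], removed


def _global_wide(metrics: pd.DataFrame) -> pd.DataFrame:
    """participant x (band_E / band_C) wide table of global metrics."""
    glob = metrics[metrics["roi"] == -1]
    wide = glob.pivot_table(
        index="participant", columns=["band", "metric"], values="value"
    )
    wide.columns = [f"{b}_{'E' if m == 'global_efficiency' else 'C'}" for b, m in wide.columns]
    return wide


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# the run


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Execute all stages and write tables plus a manifest to ``outdir``.

    Returns the manifest dict.  A rerun with the same config is
    bit-identical.
    """
    t0 = time.time()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage_info: dict[str, dict] = {}

    def stage(name):
        log.info("stage %s", name)
        return stage_info.setdefault(name, {})

    try:
        # -- simulate -----------------------------------------------------
        info = stage("simulate")
        cohort = simulate_cohort(
            cfg.cohort,
            networks="direct" if cfg.networks_mode == "direct" else "timeseries",
        )
        ids = list(cohort.covariates.index)
        info["n_participants"] = len(ids)
        info["n_snps"] = cohort.genotypes.n_snps

        # -- connectivity + metrics ---------------------------------------
        info = stage("metrics")
        nets = _session_networks(cohort, cfg)
        metrics_mean, metrics_ec1, metrics_ec2, pruned = _metric_tables(
            nets, ids, cfg.prune_alpha
        )
        info["edges_removed_by_pruning"] = pruned
        info["rows_mean"] = len(metrics_mean)

        # -- g factor ------------------------------------------------------
        info = stage("gfactor")
        resid = residualize_scores(
            cohort.test_scores, cohort.covariates["age"], cohort.covariates["sex"]
        )
        cfa = SecondOrderCFA(random_state=cfg.seed).fit(resid)
        g = pd.Series(cfa.transform(resid), index=resid.index, name="g")
        info["fit_indices"] = cfa.fit_indices_
        info["n_complete"] = len(g)

        # -- genetics ------------------------------------------------------
        info = stage("genetics")
        geno = snp_qc(cohort.genotypes)
        kept = sample_qc(geno)
        geno = geno.subset(participants=kept)
        kept = relatedness_filter(geno, random_state=cfg.seed)
        geno = geno.subset(participants=kept)
        kept, pcs = pc_outlier_filter(geno)
        geno = geno.subset(participants=kept)
        info["n_snps_post_qc"] = geno.n_snps
        info["n_participants_post_qc"] = geno.n_participants

        covars = cohort.covariates.loc[kept, ["age", "sex"]].join(pcs.loc[kept])
        common = g.index.intersection(kept)
        search = PgsThresholdSearch(
            grid_step=cfg.pgs_grid_step,
            n_permutations=cfg.n_permutations,
            random_state=cfg.seed,
        ).fit(
            geno.subset(participants=common),
            g.loc[common].to_numpy(),
            gwas=cohort.gwas.filter_info(),
            covariates=covars.loc[common],
        )
        pgs = search.best_score_
        info["best_threshold"] = search.best_threshold_
        info["best_r2_increment"] = search.best_r2_increment_
        info["permutation_p"] = search.permutation_p_

        # -- outlier screen + split ---------------------------------------
        info = stage("outliers")
        wide = _global_wide(metrics_mean).loc[common]
        screen = wide.join(g.loc[common])
        kept_final, removed = remove_outliers(screen, n_iqr=cfg.outlier_iqr)
        info["n_removed"] = len(removed)
        info["n_final"] = len(kept_final)
        covars_f = covars.loc[kept_final]
        g_f = g.loc[kept_final]
        pgs_f = pgs.loc[kept_final]
        young, older = split_cohort(
            cohort.covariates.loc[kept_final], cfg.age_cutoff, cfg.boundary_in_young
        )
        info["n_young"], info["n_older"] = len(young), len(older)

        # -- partial correlations and global mediation ---------------------
        info = stage("global_models")
        controls = covars_f[["age", "sex"]].to_numpy()
        med_covars = covars_f[["age", "sex", "PC1", "PC2", "PC3", "PC4"]].to_numpy()
        pgs_z = (pgs_f - pgs_f.mean()) / pgs_f.std(ddof=1)
        pc_rows, gm_rows = [], []
        for col in wide.columns:
            metric = wide.loc[kept_final, col].to_numpy()
            for other_name, other in (("g", g_f.to_numpy()), ("pgs", pgs_z.to_numpy())):
                r, p = partial_correlation(metric, other, controls)
                pc_rows.append({"variable": col, "with": other_name, "r": r, "p": p})
            res = global_mediation(
                pgs_z.to_numpy(), metric, g_f.to_numpy(), med_covars
            )
            gm_rows.append(
                {
                    "variable": col,
                    "a": res.a,
                    "b": res.b,
                    "c_prime": res.c_prime,
                    "ab": res.ab,
                    "se_ab": res.se_ab,
                }
            )
        partial_corrs = pd.DataFrame(pc_rows)
        global_med = pd.DataFrame(gm_rows)
        info["n_models"] = len(gm_rows)

        # -- region-specific mediation -------------------------------------
        info = stage("xmed")
        pen = PenaltyConfig(**{**asdict(cfg.penalty), "seed": cfg.seed})
        nodal = metrics_mean[metrics_mean["roi"] >= 0]
        nodal = nodal[nodal["participant"].isin(kept_final)]
        selections = run_band_models(
            nodal,
            pgs_z,
            g_f,
            covars_f[["age", "sex", "PC1", "PC2", "PC3", "PC4"]],
            age=cohort.covariates["age"],
            age_cutoff=cfg.age_cutoff,
            bands=cohort.config.bands,
            penalty=pen,
            t_med=cfg.t_med,
            t_path=cfg.t_path,
        )
        info["n_models"] = len(selections)
        info["n_selected"] = {
            f"{g_}_{b}_{m}": sel.n_selected for (g_, b, m), sel in selections.items()
        }
        info["penalties"] = {
            f"{g_}_{b}_{m}": {"lambda_a": sel.lambda_a, "lambda_b": sel.lambda_b}
            for (g_, b, m), sel in selections.items()
        }

        # -- reliability ----------------------------------------------------
        info = stage("reliability")
        keep = metrics_ec1["participant"].isin(kept_final)
        rel = reliability_map(metrics_ec1[keep], metrics_ec2[metrics_ec2["participant"].isin(kept_final)])
        info["mean_icc"] = float(rel["icc"].mean())

        # -- write ----------------------------------------------------------
        files = {
            "covariates.tsv": covars_f,
            "g.tsv": g_f.to_frame(),
            "pgs.tsv": pgs_f.to_frame(),
            "metrics_mean.tsv": metrics_mean,
            "metrics_ec1.tsv": metrics_ec1,
            "metrics_ec2.tsv": metrics_ec2,
            "partial_correlations.tsv": partial_corrs,
            "global_mediation.tsv": global_med,
            "reliability.tsv": rel,
        }
        for (group, band, metric), sel in selections.items():
            files[f"mediation_{group}_{band}_{metric}.tsv"] = sel.table
        for name, df in files.items():
            df.to_csv(out / name, sep="\t", float_format=_FLOAT_FMT)
        report = {
            "best_threshold": search.best_threshold_,
            "best_r2_increment": search.best_r2_increment_,
            "permutation_p": search.permutation_p_,
            "n_permutations": cfg.n_permutations,
        }
        (out / "pgs_report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
        (out / "cfa_report.json").write_text(
            json.dumps(
                {
                    "fit_indices": cfa.fit_indices_,
                    "loadings": cfa.loadings_.round(6).to_dict(),
                    "second_order_loadings": cfa.second_order_loadings_.round(6).to_dict(),
                },
                indent=1,
                sort_keys=True,
            )
        )
    except Exception as err:
        failed = list(stage_info)[-1] if stage_info else "setup"
        raise RuntimeError(f"pipeline stage {failed!r} failed: {err}") from err

    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config": _jsonable_config(cfg),
        "stages": stage_info,
        "files": {
            name: _sha256(out / name)
            for name in sorted([*files, "pgs_report.json", "cfa_report.json"])
        },
        "runtime_s": round(time.time() - t0, 1),
    }
    manifest_no_time = {k: v for k, v in manifest.items() if k != "runtime_s"}
    (out / "manifest.json").write_text(json.dumps(manifest_no_time, indent=1, sort_keys=True))
    return manifest


def _jsonable_config(cfg: PipelineConfig) -> dict:
    d = asdict(cfg)
    for key, val in list(d.items()):
        if isinstance(val, tuple):
            d[key] = list(val)
    return json.loads(json.dumps(d, default=list))
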