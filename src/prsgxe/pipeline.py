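"""End-to-end orchestration: simulate/read -> QC -> PCs -> clump -> scan ->
refine -> score test cohort -> adversity -> interaction analysis."""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gxe_stats, phenotypes, prs_core, synthetic_data
from .errors import ValidationError
from .geno_io import PruneConfig, QcThresholds, compute_pcs, qc_filter

logger = logging.getLogger(__name__)

REPORT_SECTIONS = ["data", "qc", "pca", "clump", "scan", "refine", "rprs", "adversity", "gxe"]

REQUIRED_KEYS = ["alpha_refine"]

DEFAULT_CONFIG = {
    "seed": 0,
    "qc_preset": "default",
    "prune": {"window_kb": 50.0, "step_snps": 5, "r2_max": 0.2},
    "clump": {"window_kb": 250.0, "r2_max": 0.2},
    "grid": {"n": 100},
    "alpha_refine": None,  # required: must be set explicitly in the config
    "scan_covariates": "pcs",  # 'pcs' (first n_pcs PCs) or 'none'
    "n_pcs_scan": 10,
    "n_pcs_gxe": 3,
    "probe_points": [-1.0, 1.0],
    "bootstrap": {"enabled": False, "n_boot": 1000},
    "imputation": {"enabled": False, "m": 30},
    "simulation": {},
}


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return merge_config(user)


def merge_config(user: dict) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    for key in REQUIRED_KEYS:
        if cfg.get(key) is None:
            raise ValidationError(f"config missing required key {key!r}")
    return cfg


def _sim_config(cfg: dict) -> synthetic_data.SimConfig:
    sim = dict(cfg.get("simulation") or {})
    gxe = sim.pop("gxe", None)
    kwargs = {k: v for k, v in sim.items() if v is not None}
    kwargs.setdefault("seed", cfg.get("seed", 0))
    sc = synthetic_data.SimConfig(**kwargs)
    if gxe:
        sc.gxe = synthetic_data.GxeParams(**gxe)
    return sc


def run_pipeline(config: dict, out_dir=None, seed: int | None = None) -> dict:
    """Execute the full analysis and return (and optionally write) the
    machine-readable report. ``seed`` overrides the config seed."""
    cfg = merge_config(config)
    if seed is not None:
        cfg["seed"] = seed
        cfg.setdefault("simulation", {})
    report: dict = {"config": cfg}

    sc = _sim_config(cfg)
    logger.info("stage data: simulating cohorts (seed=%d)", sc.seed)
    try:
        disc = synthetic_data.simulate_genotypes(sc, "discovery")
        test = synthetic_data.simulate_genotypes(sc, "test")
        causal = synthetic_data.causal_snp_ids(sc)
        gwas = synthetic_data.simulate_gwas(disc.snp_meta, causal, sc)
        insulin = synthetic_data.simulate_insulin(disc, gwas, causal, sc)
    except Exception as exc:
        raise ValidationError(f"stage data failed: {exc}") from exc
    report["data"] = {
        "n_discovery": disc.n_samples,
        "n_test": test.n_samples,
        "n_snps": disc.n_snps,
        "n_causal": len(causal),
    }

    logger.info("stage qc")
    try:
        thr = QcThresholds.preset(cfg["qc_preset"])
        disc_qc = qc_filter(disc, thr)
        test_qc = qc_filter(test, thr)
    except Exception as exc:
        raise ValidationError(f"stage qc failed: {exc}") from exc
    report["qc"] = {
        "preset": cfg["qc_preset"],
        "discovery_snps": disc_qc.n_snps,
        "test_snps": test_qc.n_snps,
    }

    logger.info("stage pca")
    try:
        prune_cfg = PruneConfig(**cfg["prune"])
        n_scan = cfg["n_pcs_scan"] if cfg["scan_covariates"] == "pcs" else 0
        disc_pcs = compute_pcs(disc_qc, n_scan, prune_cfg) if n_scan else None
        test_pcs = compute_pcs(test_qc, cfg["n_pcs_gxe"], prune_cfg)
    except Exception as exc:
        raise ValidationError(f"stage pca failed: {exc}") from exc
    report["pca"] = {
        "scan_covariates": cfg["scan_covariates"],
        "n_pcs_scan": n_scan,
        "n_pcs_gxe": cfg["n_pcs_gxe"],
    }

    logger.info("stage clump")
    try:
        clump = prs_core.ld_clump(
            gwas, disc_qc,
            r2_max=cfg["clump"]["r2_max"],
            window_kb=cfg["clump"]["window_kb"],
        )
        disc_cl = disc_qc.subset_snps(clump.retained)
        test_cl = test_qc.subset_snps(clump.retained)
    except Exception as exc:
        raise ValidationError(f"stage clump failed: {exc}") from exc
    report["clump"] = {
        "n_retained": len(clump.retained),
        "n_removed": len(clump.removed_by),
    }

    logger.info("stage scan")
    try:
        n_grid = int(cfg["grid"]["n"])
        grid = [round((i + 1) / n_grid, 10) for i in range(n_grid)]
        scan = prs_core.threshold_scan(disc_cl, gwas, insulin, disc_pcs, grid)
    except Exception as exc:
        raise ValidationError(f"stage scan failed: {exc}") from exc
    best_row = scan.table.loc[scan.table["threshold"] == scan.best_threshold].iloc[0]
    report["scan"] = {
        "n_thresholds": len(scan.table),
        "best_threshold": scan.best_threshold,
        "best_n_snps": int(best_row["n_snps"]),
        "best_r2_incremental": float(best_row["r2_incremental"]),
        "best_p": float(best_row["p_prs"]),
    }

    logger.info("stage refine")
    try:
        refined = prs_core.refine_snps(
            disc_cl, gwas, insulin, disc_pcs,
            source_threshold=scan.best_threshold,
            alpha_refine=cfg["alpha_refine"],
        )
    except Exception as exc:
        raise ValidationError(f"stage refine failed: {exc}") from exc
    report["refine"] = {
        "n_snps": len(refined),
        "alpha_refine": refined.alpha_refine,
        "source_threshold": refined.source_threshold,
        "sha256": refined.content_hash(),
    }

    logger.info("stage rprs")
    try:
        rprs = prs_core.compute_rprs(test_cl, refined)
    except Exception as exc:
        raise ValidationError(f"stage rprs failed: {exc}") from exc
    report["rprs"] = {
        "n_snps_used": rprs.n_snps_used,
        "mean": float(rprs.standardized.mean()),
        "sd": float(rprs.standardized.std()),
    }

    logger.info("stage adversity")
    try:
        components = synthetic_data.simulate_adversity(sc, test.n_samples)
        adv = phenotypes.adversity_score(components)
    except Exception as exc:
        raise ValidationError(f"stage adversity failed: {exc}") from exc
    report["adversity"] = {
        "n_components": adv.n_components,
        "n_complete": int(adv.complete_case.sum()),
        "mean_score": float(np.nanmean(adv.score)),
    }

    logger.info("stage gxe")
    try:
        rng = np.random.default_rng(np.random.SeedSequence((sc.seed, 97)))
        sex = rng.integers(0, 2, test.n_samples).astype(float)
        m_true = synthetic_data.genetic_value(test, sc)
        sd = m_true.std()
        m_std = (m_true - m_true.mean()) / sd if sd > 0 else m_true
        x_for_outcome = np.where(np.isnan(adv.score), np.nanmean(adv.score), adv.score)
        outcome = synthetic_data.simulate_outcome(x_for_outcome, m_std, None, sc)
        data = pd.DataFrame(
            {
                "outcome": outcome,
                "adversity": adv.score,
                "rprs": rprs.standardized,
                "sex": sex,
                "pc1": test_pcs[:, 0],
                "pc2": test_pcs[:, 1],
                "pc3": test_pcs[:, 2],
            }
        )
        fits = gxe_stats.fit_gxe_models(data)
        m3 = fits["model3"]
        slopes = gxe_stats.simple_slopes(m3, tuple(cfg["probe_points"]))
        x_obs = data.dropna()["adversity"].to_numpy()
        ros = gxe_stats.jn_regions(m3, (float(x_obs.min()), float(x_obs.max())))
        indices = gxe_stats.poi_pa(m3, x_obs)
        gxe_report = {
            "n": int(len(data.dropna())),
            "models": {
                label: {
                    "names": f.names,
                    "estimates": [float(v) for v in f.params],
                    "se": [float(v) for v in f.bse],
                    "p": [float(v) for v in f.pvalues],
                    "r_squared": f.r_squared,
                }
                for label, f in fits.items()
            },
            "interaction": {
                "estimate": m3[gxe_stats.XM_NAME],
                "se": m3.se(gxe_stats.XM_NAME),
                "p": m3.p(gxe_stats.XM_NAME),
            },
            "simple_slopes": dataclasses.asdict(slopes),
            "regions_of_significance": dataclasses.asdict(ros),
            "susceptibility": dataclasses.asdict(indices),
        }
        if cfg["bootstrap"]["enabled"]:
            boot = gxe_stats.bootstrap_interaction(
                data, n_boot=int(cfg["bootstrap"]["n_boot"]), seed=sc.seed
            )
            gxe_report["bootstrap"] = dataclasses.asdict(boot)
        if cfg["imputation"]["enabled"]:
            m = int(cfg["imputation"]["m"])
            imputed_fits = []
            for comp_set in phenotypes.hot_deck_impute(components, m=m, seed=sc.seed):
                adv_i = phenotypes.adversity_score(comp_set)
                data_i = data.copy()
                data_i["adversity"] = adv_i.score
                imputed_fits.append(gxe_stats.fit_gxe_models(data_i)["model3"])
            pooled = gxe_stats.pool_estimates(imputed_fits)
            j = pooled.names.index(gxe_stats.XM_NAME)
            gxe_report["imputation"] = {
                "m": pooled.m,
                "interaction_pooled": float(pooled.estimates[j]),
                "interaction_se": float(pooled.total_se[j]),
                "interaction_p": float(pooled.pvalues[j]),
            }
        report["gxe"] = gxe_report
    except ValidationError:
        raise
    except Exception as exc:
        raise ValidationError(f"stage gxe failed: {exc}") from exc

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        scan.to_tsv(out / "threshold_scan.tsv")
        refined.to_tsv(out / "refined_set.tsv")
        try:
            gxe_stats.plot_interaction(
                m3, (float(x_obs.min()), float(x_obs.max())),
                tuple(cfg["probe_points"]), out / "crossover.png",
            )
        except ImportError:
            logger.info("matplotlib unavailable; skipping crossover plot")
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=_jsonable)
    return report


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
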