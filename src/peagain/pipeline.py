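"""Config-driven orchestration of the full analysis on synthetic or user data.

``run_study`` executes simulate/load -> marker QC -> variance components ->
AMMI -> model-grid cross-validation -> RMSD configuration ranking ->
prediction scenarios -> gains -> GWAS, writing tidy CSV tables, a JSON
manifest (seeds, config hash, stage log) and returning the bundle in memory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from peagain import __version__
from peagain.ammi import ammi_fit, nominal_yields
from peagain.evaluation import (
    inter_environment_cv,
    inter_population_prediction,
    rmsd_model_selection,
    run_cv,
)
from peagain.gains import GainScenario, efficiency_ratio, gain_per_year_gs, gain_per_year_ps
from peagain.genotypes import (
    compute_kinship,
    filter_maf,
    filter_missing_rate,
    impute_missing,
    read_genotypes,
)
from peagain.gwas import score_test_stratified
from peagain.quantgen import (
    PhenotypeTable,
    blup_line_means,
    cv_g,
    estimate_vc_multi_env,
    estimate_vc_single_env,
    h2_multi_env,
    h2_single_env,
)
from peagain.simdata import SimConfig, simulate_study

logger = logging.getLogger("peagain")

MODEL_KINDS = ("rrblup", "gblup", "bayeslasso")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Validated study configuration (see ``from_yaml``)."""

    sim: dict = field(default_factory=dict)
    genotype_path: str | None = None
    genotype_format: str = "csv"
    phenotype_path: str | None = None
    missing_thresholds: list[float] = field(default_factory=lambda: [0.01, 0.05, 0.10, 0.20, 0.30])
    min_maf: float = 0.05
    impute_method: str = "mode"
    models: list[str] = field(default_factory=lambda: list(MODEL_KINDS))
    cv_k: int = 10
    cv_repetitions: int = 50
    scenarios: list[str] = field(default_factory=lambda: ["intra_env_intra_pop"])
    t_G: float = 0.5
    t_P_values: list[float] = field(default_factory=lambda: [1.0, 2.0])
    intensity_ratio: float = 1.46
    gwas_threshold: float = 3.0
    gwas_n_pcs: int = 2
    bayeslasso_chain: int = 1500
    bayeslasso_burn_in: int = 500
    seed: int = 1

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("model grid must be non-empty")
        for m in self.models:
            if m not in MODEL_KINDS:
                raise ValueError(f"unknown model {m!r}")
        if sorted(self.missing_thresholds) != list(self.missing_thresholds):
            raise ValueError("missing thresholds must be sorted ascending")
        if self.genotype_path is None and not self.sim:
            self.sim = {}  # defaults are fine; synthetic run
        if self.genotype_path is not None and self.phenotype_path is None:
            raise ValueError("genotype_path given without phenotype_path")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage_seed(master: int, stage: str) -> int:
    """Per-stage seed from a documented hash of the master seed + stage name."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big")


def run_study(config: PipelineConfig, out_dir=None) -> dict:
    """Execute the configured pipeline; returns (and optionally writes) a bundle."""
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": [],
    }
    bundle: dict = {"manifest": manifest}

    def stage(name):
        def wrap(fn):
            t0 = time.time()
            try:
                result = fn()
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
            manifest["stages"].append({"stage": name, "seconds": round(time.time() - t0, 3)})
            logger.info("stage %s done in %.2fs", name, time.time() - t0)
            return result

        return wrap

    # --- data -------------------------------------------------------------
    def load_data():
        if config.genotype_path is not None:
            g = read_genotypes(config.genotype_path, format=config.genotype_format)
            ph = PhenotypeTable.from_csv(config.phenotype_path)
            pops = ph.data.drop_duplicates("line").set_index("line")["population"]
            g.populations = {l: pops.get(l, "pop1") for l in g.line_ids}
            return g, ph
        sim_cfg = SimConfig(seed=_stage_seed(config.seed, "simdata") % 10_000, **config.sim)
        g, ph, _ = simulate_study(sim_cfg)
        return g, ph

    genotypes_raw, phenotypes = stage("data")(load_data)
    trait = phenotypes.traits[0]
    envs = phenotypes.environments

    # --- QC ---------------------------------------------------------------
    def qc():
        by_threshold = {}
        for thr in config.missing_thresholds:
            g = filter_missing_rate(genotypes_raw, thr)
            g = filter_maf(g, config.min_maf)
            g = impute_missing(g, method=config.impute_method,
                               seed=_stage_seed(config.seed, f"impute{thr}"))
            by_threshold[thr] = g
        return by_threshold

    genotypes_by_thr = stage("qc")(qc)
    bundle["marker_counts"] = pd.DataFrame(
        [(t, g.n_markers) for t, g in genotypes_by_thr.items()],
        columns=["threshold", "n_markers"],
    )
    genotypes = genotypes_by_thr[config.missing_thresholds[0]]

    # --- quantitative genetics -------------------------------------------
    def quant():
        rows = []
        blups = {}
        for env in envs:
            vc = estimate_vc_single_env(phenotypes, env, trait)
            h2 = h2_single_env(vc.S_G2, vc.S_e2, vc.n_reps)
            rows.append((env, vc.S_G2, vc.S_e2, h2, cv_g(vc.S_G2, vc.mean)))
            blups[env] = blup_line_means(phenotypes, env, trait)
        vc_multi = estimate_vc_multi_env(phenotypes, trait)
        h2_overall = h2_multi_env(
            vc_multi.S_G2, vc_multi.S_GE2, vc_multi.S_e2, vc_multi.n_envs, vc_multi.n_reps
        )
        table = pd.DataFrame(rows, columns=["environment", "S_G2", "S_e2", "H2", "CV_g"])
        return table, vc_multi, h2_overall, blups

    vc_table, vc_multi, h2_overall, blups = stage("quantgen")(quant)
    bundle["variance_components"] = vc_table
    bundle["vc_multi"] = {
        "S_G2": vc_multi.S_G2, "S_GE2": vc_multi.S_GE2, "S_e2": vc_multi.S_e2,
        "H2_multi": h2_overall,
    }

    # --- AMMI -------------------------------------------------------------
    def ammi_stage():
        cell = phenotypes.data.pivot_table(index="line", columns="environment",
                                           values=trait, aggfunc="mean")
        pooled_ms, pooled_df = [], 0
        for env in envs:
            vc = estimate_vc_single_env(phenotypes, env, trait)
            n_g = phenotypes.data["line"].nunique()
            d = (n_g - 1) * (vc.n_reps - 1)
            pooled_ms.append(vc.S_e2 * d)
            pooled_df += d
        ms_error = sum(pooled_ms) / pooled_df
        fit = ammi_fit(cell, ms_error=ms_error, df_error=pooled_df,
                       n_reps=vc_multi.n_reps)
        nom = nominal_yields(fit, 0) if fit.retained_axes >= 1 else None
        return fit, nom

    ammi_result, nominal = stage("ammi")(ammi_stage)
    bundle["ammi"] = {
        "retained_axes": ammi_result.retained_axes,
        "pct_gei_explained": list(ammi_result.pct_gei_explained),
    }
    bundle["nominal_yields"] = nominal

    # --- model grid CV ----------------------------------------------------
    overall_blup = pd.concat(blups.values(), axis=1).mean(axis=1)

    def model_spec(kind):
        spec = {"kind": kind}
        if kind == "bayeslasso":
            spec.update(chain_length=config.bayeslasso_chain,
                        burn_in=config.bayeslasso_burn_in)
        return spec

    def grid_cv():
        rows = []
        for kind in config.models:
            for thr, g in genotypes_by_thr.items():
                res = run_cv(model_spec(kind), g, overall_blup,
                             k=config.cv_k, repetitions=config.cv_repetitions,
                             seed=_stage_seed(config.seed, f"cv:{kind}:{thr}"))
                rows.append((kind, thr, trait, res.predictive_ability))
        return pd.DataFrame(rows, columns=["model", "threshold", "trait", "pa"])

    pa_table = stage("model_grid")(grid_cv)
    bundle["predictive_abilities"] = pa_table
    ranking = rmsd_model_selection(pa_table)
    bundle["rmsd_ranking"] = ranking
    best_model = ranking.iloc[0]["model"]
    best_thr = ranking.iloc[0]["threshold"]
    g_best = genotypes_by_thr[best_thr]

    # --- scenarios --------------------------------------------------------
    def scenarios():
        rows = []
        spec = model_spec(best_model)
        if "inter_env_intra_pop" in config.scenarios:
            for env in envs:
                res = inter_environment_cv(
                    spec, g_best, blups, env, k=config.cv_k,
                    repetitions=max(1, config.cv_repetitions // 10),
                    seed=_stage_seed(config.seed, f"interenv:{env}"),
                )
                for venv, cv in res.items():
                    rows.append(("inter_env_intra_pop", env, venv, cv.predictive_ability))
        if "intra_env_inter_pop" in config.scenarios or "inter_env_inter_pop" in config.scenarios:
            pops = sorted(set(g_best.populations.values()))
            for pop in pops:
                for env in envs:
                    for scope, name in (("same_env", "intra_env_inter_pop"),
                                        ("other_envs", "inter_env_inter_pop")):
                        if name not in config.scenarios:
                            continue
                        res = inter_population_prediction(
                            spec, g_best, blups, pop, env, validation_scope=scope,
                            seed=_stage_seed(config.seed, f"interpop:{pop}:{env}:{scope}"),
                        )
                        rows.append((name, f"{pop}@{env}", "-", res.predictive_ability))
        return pd.DataFrame(rows, columns=["scenario", "training", "validation", "r_Ab"])

    bundle["scenarios"] = stage("scenarios")(scenarios) if config.scenarios else pd.DataFrame()

    # --- gains ------------------------------------------------------------
    def gains_stage():
        r_ab = float(pa_table.loc[
            (pa_table["model"] == best_model) & (pa_table["threshold"] == best_thr), "pa"
        ].iloc[0])
        H = float(np.sqrt(max(h2_overall, 1e-12)))
        rows = []
        for t_p in config.t_P_values:
            sc = GainScenario(r_Ab=r_ab, H=H, t_G=config.t_G, t_P=t_p,
                              intensity_ratio=config.intensity_ratio)
            rows.append({
                "t_P": t_p, "r_Ab": r_ab, "H": H, "r_Ac": sc.r_Ac,
                "gain_per_year_gs": gain_per_year_gs(sc),
                "gain_per_year_ps": gain_per_year_ps(sc),
                "efficiency_ratio": efficiency_ratio(
                    sc.r_Ac, H, config.t_G, t_p, config.intensity_ratio),
            })
        return pd.DataFrame(rows)

    bundle["gains"] = stage("gains")(gains_stage)

    # --- GWAS -------------------------------------------------------------
    def gwas_stage():
        res = score_test_stratified(
            g_best, overall_blup, n_components=config.gwas_n_pcs,
            threshold=config.gwas_threshold,
        )
        return res

    gwas_result = stage("gwas")(gwas_stage)
    bundle["gwas_top"] = gwas_result.top(100)
    bundle["gwas_n_significant"] = len(gwas_result.significant)

    if out is not None:
        _write_bundle(bundle, out)
    return bundle


def _write_bundle(bundle: dict, out: Path) -> None:
    for key in ("marker_counts", "variance_components", "predictive_abilities",
                "rmsd_ranking", "scenarios", "gains", "gwas_top", "nominal_yields"):
        value = bundle.get(key)
        if isinstance(value, pd.DataFrame) and not value.empty:
            value.to_csv(out / f"{key}.csv", index=False)
    scalars = {
        "vc_multi": bundle["vc_multi"],
        "ammi": bundle["ammi"],
        "gwas_n_significant": bundle["gwas_n_significant"],
    }
    (out / "summary.json").write_text(json.dumps(scalars, indent=2, default=float))
    (out / "manifest.json").write_text(json.dumps(bundle["manifest"], indent=2))


def make_report(bundle: dict) -> str:
    """Human-readable markdown summary of a ``run_study`` bundle."""
    lines = ["# Study report (synthetic unless user data supplied)", ""]
    man = bundle.get("manifest", {})
    lines.append(f"Seed {man.get('seed')} | config {man.get('config_hash')} | "
                 f"version {man.get('version')}")
    lines.append("")
    for key, title in (
        ("marker_counts", "Marker counts per missing-rate threshold"),
        ("variance_components", "Per-environment variance components and H2"),
        ("predictive_abilities", "Model-grid predictive abilities"),
        ("rmsd_ranking", "RMSD configuration ranking"),
        ("scenarios", "Prediction scenarios"),
        ("gains", "GS vs PS efficiency (inputs -> ratio audit trail)"),
    ):
        value = bundle.get(key)
        if isinstance(value, pd.DataFrame) and not value.empty:
            lines.append(f"## {title}")
            lines.append(value.to_string(index=False))
            lines.append("")
        else:
            lines.append(f"## {title}\n(section unavailable)\n")
    if "vc_multi" in bundle:
        lines.append("## Multi-environment components")
        lines.append(json.dumps(bundle["vc_multi"], indent=2, default=float))
        lines.append("")
    if "ammi" in bundle:
        lines.append("## AMMI")
        lines.append(json.dumps(bundle["ammi"], indent=2, default=float))
        lines.append("")
    if "gwas_n_significant" in bundle:
        lines.append(f"## GWAS\nsignificant markers at threshold: {bundle['gwas_n_significant']}")
    return "\n".join(lines)
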