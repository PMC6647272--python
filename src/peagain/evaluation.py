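"""Cross-validation machinery and the four prediction scenarios.

Stratified (by population) 10-fold cross-validation with repetitions,
intra/inter-environment and intra/inter-population predictive abilities,
and RMSD-based model/configuration ranking. Predictive ability is always
the Pearson correlation computed within each population and then averaged
unweighted across populations (population means differ; pooling would bias
the correlation upward).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from peagain.genotypes import GenotypeMatrix, compute_kinship, KinshipMatrix
from peagain.gsmodels import (
    StructureDesign,
    fit_bayeslasso,
    fit_gblup,
    fit_rrblup,
    predict,
)

__all__ = [
    "CVResult",
    "stratified_kfold",
    "predictive_ability",
    "run_cv",
    "inter_environment_cv",
    "inter_population_prediction",
    "rmsd_model_selection",
]

SCENARIOS = (
    "intra_env_intra_pop",
    "inter_env_intra_pop",
    "intra_env_inter_pop",
    "inter_env_inter_pop",
)


@dataclass
class CVResult:
    scenario: str
    predictive_ability: float
    records: pd.DataFrame  # columns: repetition, population, r
    train_env: object = None
    validation_env: object = None
    train_pops: list = field(default_factory=list)
    validation_pops: list = field(default_factory=list)
    n_repetitions: int = 1
    k_folds: int = 10
    seed: int = 0


def stratified_kfold(line_ids: list[str], populations: dict, k: int, seed: int = 0) -> np.ndarray:
    """Fold assignment (0..k-1) per line, stratified by population.

    Within each population, shuffled lines are dealt round-robin, so per-fold
    population counts differ by at most 1 from proportionality. Deterministic
    given ``seed``.
    """
    rng = np.random.default_rng(seed)
    folds = np.empty(len(line_ids), dtype=int)
    pops = sorted({populations[l] for l in line_ids})
    labels = np.array([populations[l] for l in line_ids])
    for pi, pop in enumerate(pops):
        idx = np.flatnonzero(labels == pop)
        if len(idx) < k:
            raise ValueError(f"population {pop!r} has {len(idx)} lines < k={k}")
        perm = rng.permutation(idx)
        # offset by population index so the larger folds rotate
        folds[perm] = (np.arange(len(perm)) + pi) % k
    return folds


def predictive_ability(
    observed: pd.Series, predicted: pd.Series, populations: dict
) -> float:
    """Pearson r within each population, unweighted mean across populations."""
    common = observed.index.intersection(predicted.index)
    obs, pred = observed.loc[common], predicted.loc[common]
    labels = pd.Series({l: populations[l] for l in common})
    rs = []
    for pop, lines in labels.groupby(labels).groups.items():
        o, p = obs.loc[lines], pred.loc[lines]
        if len(o) < 3:
            raise ValueError(f"population {pop!r} has < 3 lines for correlation")
        if o.std() == 0 or p.std() == 0:
            warnings.warn(f"constant values in population {pop!r}; excluded from r_Ab")
            continue
        rs.append(stats.pearsonr(o, p).statistic)
    if not rs:
        raise ValueError("no population yielded a defined correlation")
    return float(np.mean(rs))


def _pop_correlations(observed: pd.Series, predicted: pd.Series,
                      labels: pd.Series, rep: int) -> list:
    """Per-population correlation rows; constant vectors are skipped with a warning."""
    rows = []
    for pop in sorted(set(labels)):
        lines = labels[labels == pop].index
        o, p = observed.loc[lines], predicted.loc[lines]
        if o.std() == 0 or p.std() == 0:
            warnings.warn(f"constant values in population {pop!r}; excluded from r_Ab")
            continue
        rows.append((rep, pop, float(stats.pearsonr(o, p).statistic)))
    return rows


def _fit_and_predict(
    model_spec: dict,
    genotypes: GenotypeMatrix,
    y_train: pd.Series,
    train_ids: list[str],
    valid_ids: list[str],
    use_structure: bool,
    seed: int,
    kinship: KinshipMatrix | None = None,
) -> pd.Series:
    """Train one model on ``train_ids`` and predict ``valid_ids``."""
    kind = model_spec["kind"]
    opts = {k: v for k, v in model_spec.items() if k != "kind"}
    struct_tr = struct_va = None
    if use_structure:
        struct_tr = StructureDesign.from_populations(genotypes.populations, train_ids)
        struct_va = StructureDesign.from_populations(
            genotypes.populations, valid_ids, pop_order=struct_tr.pop_labels
        )
    if kind == "rrblup":
        g_train = genotypes.subset_lines(train_ids)
        fit = fit_rrblup(g_train, y_train, structure=struct_tr, **opts)
        return predict(fit, genotypes.subset_lines(valid_ids), structure_new=struct_va)
    if kind == "bayeslasso":
        g_train = genotypes.subset_lines(train_ids)
        fit = fit_bayeslasso(g_train, y_train, structure=struct_tr, seed=seed, **opts)
        return predict(fit, genotypes.subset_lines(valid_ids), structure_new=struct_va)
    if kind == "gblup":
        if kinship is None:
            kinship = compute_kinship(genotypes.subset_lines(list(train_ids) + list(valid_ids)))
        pos = {l: i for i, l in enumerate(kinship.line_ids)}
        tr = [pos[l] for l in train_ids]
        va = [pos[l] for l in valid_ids]
        k_train = KinshipMatrix(list(train_ids), kinship.values[np.ix_(tr, tr)])
        fit = fit_gblup(k_train, y_train, structure=struct_tr, **opts)
        preds = predict(fit, kinship_cross=kinship.values[np.ix_(va, tr)],
                        structure_new=struct_va)
        preds.index = valid_ids
        return preds
    raise ValueError(f"unknown model kind {kind!r}")


def run_cv(
    model_spec: dict,
    genotypes: GenotypeMatrix,
    phenotypes: pd.Series,
    k: int = 10,
    repetitions: int = 50,
    seed: int = 0,
    use_structure: bool = False,
) -> CVResult:
    """Repeated stratified k-fold CV on one phenotype vector (line BLUPs).

    Per-repetition fold seeds derive deterministically from the master seed.
    """
    line_ids = genotypes.line_ids
    pops = genotypes.populations
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=repetitions)
    rows = []
    kin = compute_kinship(genotypes) if model_spec["kind"] == "gblup" else None
    for rep in range(repetitions):
        folds = stratified_kfold(line_ids, pops, k, seed=int(rep_seeds[rep]))
        preds = pd.Series(index=line_ids, dtype=float)
        for f in range(k):
            valid = [l for l, fl in zip(line_ids, folds) if fl == f]
            train = [l for l, fl in zip(line_ids, folds) if fl != f]
            preds.loc[valid] = _fit_and_predict(
                model_spec, genotypes, phenotypes.loc[train], train, valid,
                use_structure, seed=int(rep_seeds[rep]) + f, kinship=kin,
            )
        labels = pd.Series({l: pops[l] for l in line_ids})
        rows.extend(_pop_correlations(phenotypes, preds, labels, rep))
    records = pd.DataFrame(rows, columns=["repetition", "population", "r"])
    r_ab = float(records.groupby("repetition")["r"].mean().mean())
    return CVResult(
        scenario="intra_env_intra_pop",
        predictive_ability=r_ab,
        records=records,
        n_repetitions=repetitions,
        k_folds=k,
        seed=seed,
    )


def inter_environment_cv(
    model_spec: dict,
    genotypes: GenotypeMatrix,
    phenotypes_by_env: dict,
    train_env,
    k: int = 10,
    repetitions: int = 50,
    seed: int = 0,
) -> dict:
    """Train in one environment, validate held-out lines in the others.

    Per fold, the model is trained on the 90% lines' ``train_env``
    phenotypes; predictions for the held-out 10% are correlated with their
    phenotypes in each other environment. Returns validation_env -> CVResult.
    """
    if len(phenotypes_by_env) < 2:
        raise ValueError("need >= 2 environments")
    line_ids = genotypes.line_ids
    pops = genotypes.populations
    valid_envs = [e for e in phenotypes_by_env if e != train_env]
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=repetitions)
    kin = compute_kinship(genotypes) if model_spec["kind"] == "gblup" else None
    rows = {env: [] for env in valid_envs}
    y_train_all = phenotypes_by_env[train_env]
    for rep in range(repetitions):
        folds = stratified_kfold(line_ids, pops, k, seed=int(rep_seeds[rep]))
        preds = pd.Series(index=line_ids, dtype=float)
        for f in range(k):
            valid = [l for l, fl in zip(line_ids, folds) if fl == f]
            train = [l for l, fl in zip(line_ids, folds) if fl != f]
            preds.loc[valid] = _fit_and_predict(
                model_spec, genotypes, y_train_all.loc[train], train, valid,
                False, seed=int(rep_seeds[rep]) + f, kinship=kin,
            )
        labels = pd.Series({l: pops[l] for l in line_ids})
        for env in valid_envs:
            rows[env].extend(_pop_correlations(phenotypes_by_env[env], preds, labels, rep))
    out = {}
    for env in valid_envs:
        records = pd.DataFrame(rows[env], columns=["repetition", "population", "r"])
        out[env] = CVResult(
            scenario="inter_env_intra_pop",
            predictive_ability=float(records.groupby("repetition")["r"].mean().mean()),
            records=records,
            train_env=train_env,
            validation_env=env,
            n_repetitions=repetitions,
            k_folds=k,
            seed=seed,
        )
    return out


def inter_population_prediction(
    model_spec: dict,
    genotypes: GenotypeMatrix,
    phenotypes_by_env: dict,
    train_pop: str,
    train_env,
    validation_scope: str = "same_env",
    seed: int = 0,
) -> CVResult:
    """Train on one full population, predict the other populations.

    No cross-validation inside training (the full training population is
    used). ``validation_scope``: ``same_env`` correlates predictions with
    the training environment's phenotypes of the other populations;
    ``other_envs`` averages the per-population correlations over each other
    environment.
    """
    pops = genotypes.populations
    all_pops = sorted(set(pops.values()))
    if train_pop not in all_pops:
        raise ValueError(f"unknown population {train_pop!r}")
    if len(all_pops) < 2:
        raise ValueError("need >= 2 populations")
    if validation_scope not in ("same_env", "other_envs"):
        raise ValueError("validation_scope must be 'same_env' or 'other_envs'")
    train_ids = [l for l in genotypes.line_ids if pops[l] == train_pop]
    valid_pops = [p for p in all_pops if p != train_pop]
    valid_ids = [l for l in genotypes.line_ids if pops[l] != train_pop]
    y_train = phenotypes_by_env[train_env].loc[train_ids]
    preds = _fit_and_predict(
        model_spec, genotypes, y_train, train_ids, valid_ids, False, seed=seed
    )
    envs = [train_env] if validation_scope == "same_env" else [
        e for e in phenotypes_by_env if e != train_env
    ]
    rows = []
    for env in envs:
        obs = phenotypes_by_env[env]
        for pop in valid_pops:
            lines = [l for l in valid_ids if pops[l] == pop]
            rows.append((env, pop, float(stats.pearsonr(
                obs.loc[lines], preds.loc[lines]).statistic)))
    records = pd.DataFrame(rows, columns=["environment", "population", "r"])
    # populations averaged within each validation environment, then environments
    r_ab = float(records.groupby("environment")["r"].mean().mean())
    return CVResult(
        scenario="intra_env_inter_pop" if validation_scope == "same_env" else "inter_env_inter_pop",
        predictive_ability=r_ab,
        records=records.rename(columns={"environment": "repetition"}),
        train_env=train_env,
        train_pops=[train_pop],
        validation_pops=valid_pops,
        n_repetitions=1,
        k_folds=0,
        seed=seed,
    )


def rmsd_model_selection(pa_table: pd.DataFrame) -> pd.DataFrame:
    """Rank (model, missing-threshold) configurations by RMSD to the best.

    ``pa_table`` needs columns model, threshold, trait, pa, complete over the
    grid. Per configuration, RMSD over traits of (best-for-trait PA minus
    this configuration's PA); ascending sort, ties broken by higher mean PA
    then by lower missing threshold.
    """
    required = {"model", "threshold", "trait", "pa"}
    if not required.issubset(pa_table.columns):
        raise ValueError(f"pa_table needs columns {sorted(required)}")
    traits = sorted(pa_table["trait"].unique())
    grid = pa_table.groupby(["model", "threshold"], observed=True)
    for (mdl, thr), sub in grid:
        if sorted(sub["trait"]) != traits:
            raise ValueError(f"incomplete grid for ({mdl}, {thr})")
    best = pa_table.groupby("trait", observed=True)["pa"].max()
    rows = []
    for (mdl, thr), sub in grid:
        penalty = best.loc[sub["trait"]].to_numpy() - sub["pa"].to_numpy()
        rmsd = float(np.sqrt(np.mean(penalty**2)))
        rows.append((mdl, thr, rmsd, float(sub["pa"].mean())))
    out = pd.DataFrame(rows, columns=["model", "threshold", "rmsd", "mean_pa"])
    out = out.sort_values(
        by=["rmsd", "mean_pa", "threshold"], ascending=[True, False, True]
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
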