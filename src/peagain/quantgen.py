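"""Quantitative genetics for balanced RCB multi-environment trials.

Variance components come from expected-mean-square (method-of-moments)
algebra on the balanced ANOVA, which coincides with REML for balanced data.
Negative estimates are clamped to zero and flagged. Downstream utilities:
broad-sense heritability (single- and multi-environment forms), genetic
coefficient of variation, genetic correlation across environment pairs,
BLUP shrinkage of line means, and Pearson trait correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PhenotypeTable",
    "VarianceComponents",
    "estimate_vc_single_env",
    "estimate_vc_multi_env",
    "cv_g",
    "h2_single_env",
    "h2_multi_env",
    "genetic_correlation",
    "blup_line_means",
    "trait_correlations",
]

DESIGN_COLUMNS = ("line", "population", "environment", "block")


class BalanceError(ValueError):
    """Raised when a design is not a complete balanced RCB."""


@dataclass
class PhenotypeTable:
    """Long-format plot records: line, population, environment, block, traits."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in DESIGN_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"phenotype table lacks columns {missing}")
        self.data = self.data.reset_index(drop=True)
        for t in self.traits:
            if not pd.api.types.is_numeric_dtype(self.data[t]):
                raise ValueError(f"trait column {t!r} is not numeric")

    @property
    def traits(self) -> list[str]:
        return [c for c in self.data.columns if c not in DESIGN_COLUMNS]

    @property
    def environments(self) -> list[str]:
        return sorted(self.data["environment"].unique())

    @property
    def populations(self) -> list[str]:
        return sorted(self.data["population"].unique())

    def subset(self, environment=None, population=None) -> "PhenotypeTable":
        df = self.data
        if environment is not None:
            df = df[df["environment"] == environment]
        if population is not None:
            df = df[df["population"] == population]
        return PhenotypeTable(df.copy())

    def check_balanced(self) -> None:
        """Every line x environment x block cell present exactly once."""
        counts = self.data.groupby(["line", "environment", "block"], observed=True).size()
        if (counts != 1).any():
            raise BalanceError("duplicated plot records")
        per_env = self.data.groupby("environment", observed=True).apply(
            lambda d: d.groupby(["line", "block"], observed=True).size().shape[0],
            include_groups=False,
        )
        n_lines = self.data["line"].nunique()
        blocks_per_env = self.data.groupby("environment", observed=True)["block"].nunique()
        if not (per_env == n_lines * blocks_per_env).all():
            raise BalanceError("incomplete RCB: some line x block cells absent")

    def line_means(self, trait: str, environment=None) -> pd.Series:
        df = self.data if environment is None else self.data[self.data["environment"] == environment]
        return df.groupby("line", observed=True)[trait].mean()

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PhenotypeTable":
        return cls(pd.read_csv(path))


@dataclass
class VarianceComponents:
    """Variance components from a balanced ANOVA, clamped at zero.

    For pooled-genotype analyses ``S_G2``/``S_GE2``/``S_e2`` are set; for the
    population-factor analysis the ``S_R2``/``S_GR2``/``S_RE2``/``S_GRE2``
    quartet replaces the first two. ``p_values`` hold the ANOVA F-test
    significance of each estimated component; ``clamped`` lists components
    whose raw estimate was negative.
    """

    S_G2: float | None = None
    S_GE2: float | None = None
    S_e2: float = 0.0
    S_R2: float | None = None
    S_GR2: float | None = None
    S_RE2: float | None = None
    S_GRE2: float | None = None
    n_reps: int = 1
    n_envs: int = 1
    mean: float = 0.0
    p_values: dict = field(default_factory=dict)
    clamped: list = field(default_factory=list)


def _clamp(name: str, value: float, clamped: list) -> float:
    if value < 0:
        clamped.append(name)
        return 0.0
    return float(value)


def _anova_cells(df: pd.DataFrame, trait: str):
    y = df[trait].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise BalanceError("missing trait values; balanced analysis impossible")
    return y


def estimate_vc_single_env(
    ph: PhenotypeTable, environment, trait: str, population=None
) -> VarianceComponents:
    """Genotype + block ANOVA in one environment; S_G2 = (MS_G - MS_e)/n."""
    sub = ph.subset(environment=environment, population=population)
    sub.check_balanced()
    df = sub.data
    y = _anova_cells(df, trait)
    m = y.mean()
    g_means = df.groupby("line", observed=True)[trait].mean()
    b_means = df.groupby("block", observed=True)[trait].mean()
    n_g, n_b = len(g_means), len(b_means)
    if n_g < 2 or n_b < 1:
        raise BalanceError("need >= 2 genotypes")
    ss_tot = float(((y - m) ** 2).sum())
    ss_g = n_b * float(((g_means - m) ** 2).sum())
    ss_b = n_g * float(((b_means - m) ** 2).sum())
    ss_e = ss_tot - ss_g - ss_b
    df_g, df_b = n_g - 1, n_b - 1
    df_e = (n_g - 1) * (n_b - 1)
    ms_g = ss_g / df_g
    ms_e = ss_e / df_e if df_e > 0 else float("nan")
    clamped: list = []
    s_e2 = max(ms_e, 0.0)
    s_g2 = _clamp("S_G2", (ms_g - ms_e) / n_b, clamped)
    p_g = float(stats.f.sf(ms_g / ms_e, df_g, df_e)) if df_e > 0 and ms_e > 0 else float("nan")
    return VarianceComponents(
        S_G2=s_g2, S_e2=s_e2, n_reps=n_b, n_envs=1, mean=float(m),
        p_values={"S_G2": p_g}, clamped=clamped,
    )


def _pooled_multi_env_ss(df: pd.DataFrame, trait: str):
    """Sums of squares for Y = m + G + E + B(E) + GE + e on a balanced design."""
    y = _anova_cells(df, trait)
    m = y.mean()
    g = df["line"].nunique()
    e = df["environment"].nunique()
    n = df.groupby("environment", observed=True)["block"].nunique().iloc[0]

    g_means = df.groupby("line", observed=True)[trait].mean()
    e_means = df.groupby("environment", observed=True)[trait].mean()
    ge_means = df.groupby(["line", "environment"], observed=True)[trait].mean()
    be_means = df.groupby(["environment", "block"], observed=True)[trait].mean()

    ss_tot = float(((y - m) ** 2).sum())
    ss_g = e * n * float(((g_means - m) ** 2).sum())
    ss_e_env = g * n * float(((e_means - m) ** 2).sum())
    ss_be = g * float(
        sum(
            (be_means[env] - e_means[env]).pow(2).sum()
            for env in e_means.index
        )
    )
    ge = ge_means.reset_index()
    ge["fit"] = (
        ge["line"].map(g_means) + ge["environment"].map(e_means) - m
    )
    ss_ge = n * float(((ge[trait] - ge["fit"]) ** 2).sum())
    ss_err = ss_tot - ss_g - ss_e_env - ss_be - ss_ge
    df_err = g * e * n - 1 - (g - 1) - (e - 1) - e * (n - 1) - (g - 1) * (e - 1)
    return {
        "m": m, "g": g, "e": e, "n": n,
        "ss": {"G": ss_g, "E": ss_e_env, "B(E)": ss_be, "GE": ss_ge, "err": ss_err},
        "df": {"G": g - 1, "E": e - 1, "B(E)": e * (n - 1), "GE": (g - 1) * (e - 1), "err": df_err},
    }


def estimate_vc_multi_env(
    ph: PhenotypeTable, trait: str, with_population_factor: bool = False
) -> VarianceComponents:
    """Multi-environment variance decomposition from balanced-ANOVA EMS.

    Without the population factor: Y = m + G + E + B(E) + GE + e, yielding
    S_G2, S_GE2, S_e2. With it: genotypes nested in populations, crossed
    with environments, yielding S_R2, S_GR2, S_RE2, S_GRE2 (equal population
    sizes required). F tests use the EMS-implied denominators.
    """
    ph.check_balanced()
    if ph.data["environment"].nunique() < 2:
        raise BalanceError("multi-environment analysis needs >= 2 environments")
    if not with_population_factor:
        a = _pooled_multi_env_ss(ph.data, trait)
        ss, dof, n, e = a["ss"], a["df"], a["n"], a["e"]
        ms = {k: ss[k] / dof[k] for k in ss if dof[k] > 0}
        clamped: list = []
        s_e2 = max(ms["err"], 0.0)
        s_ge2 = _clamp("S_GE2", (ms["GE"] - ms["err"]) / n, clamped)
        s_g2 = _clamp("S_G2", (ms["G"] - ms["GE"]) / (n * e), clamped)
        p = {
            "S_G2": float(stats.f.sf(ms["G"] / ms["GE"], dof["G"], dof["GE"])),
            "S_GE2": float(stats.f.sf(ms["GE"] / ms["err"], dof["GE"], dof["err"])),
        }
        return VarianceComponents(
            S_G2=s_g2, S_GE2=s_ge2, S_e2=s_e2, n_reps=n, n_envs=e,
            mean=float(a["m"]), p_values=p, clamped=clamped,
        )
    return _vc_with_population_factor(ph, trait)


def _vc_with_population_factor(ph: PhenotypeTable, trait: str) -> VarianceComponents:
    df = ph.data
    pop_sizes = df.groupby("population", observed=True)["line"].nunique()
    if pop_sizes.nunique() != 1:
        raise BalanceError(
            "population-factor EMS algebra requires equal lines per population"
        )
    y = _anova_cells(df, trait)
    m = y.mean()
    p_n = len(pop_sizes)
    g = int(pop_sizes.iloc[0])  # lines per population
    e = df["environment"].nunique()
    n = df.groupby("environment", observed=True)["block"].nunique().iloc[0]

    r_means = df.groupby("population", observed=True)[trait].mean()
    gr_means = df.groupby("line", observed=True)[trait].mean()
    e_means = df.groupby("environment", observed=True)[trait].mean()
    be_means = df.groupby(["environment", "block"], observed=True)[trait].mean()
    re_means = df.groupby(["population", "environment"], observed=True)[trait].mean()
    ge_means = df.groupby(["line", "population", "environment"], observed=True)[trait].mean()

    ss_r = g * e * n * float(((r_means - m) ** 2).sum())
    line_pop = df.drop_duplicates("line").set_index("line")["population"]
    ss_gr = e * n * float(
        ((gr_means - line_pop.map(r_means)) ** 2).sum()
    )
    ss_e_env = p_n * g * n * float(((e_means - m) ** 2).sum())
    ss_be = p_n * g * float(
        sum((be_means[env] - e_means[env]).pow(2).sum() for env in e_means.index)
    )
    re = re_means.reset_index()
    re["fit"] = re["population"].map(r_means) + re["environment"].map(e_means) - m
    ss_re = g * n * float(((re[trait] - re["fit"]) ** 2).sum())
    ge = ge_means.reset_index()
    re_lookup = re_means
    ge["fit"] = (
        ge["line"].map(gr_means)
        + [re_lookup[(r, env)] for r, env in zip(ge["population"], ge["environment"])]
        - ge["population"].map(r_means)
    )
    ss_ge = n * float(((ge[trait] - ge["fit"]) ** 2).sum())
    ss_tot = float(((y - m) ** 2).sum())
    ss_err = ss_tot - ss_r - ss_gr - ss_e_env - ss_be - ss_re - ss_ge

    dof = {
        "R": p_n - 1,
        "G(R)": p_n * (g - 1),
        "E": e - 1,
        "B(E)": e * (n - 1),
        "RE": (p_n - 1) * (e - 1),
        "G(R)E": p_n * (g - 1) * (e - 1),
    }
    dof["err"] = p_n * g * e * n - 1 - sum(dof.values())
    ss = {"R": ss_r, "G(R)": ss_gr, "E": ss_e_env, "B(E)": ss_be,
          "RE": ss_re, "G(R)E": ss_ge, "err": ss_err}
    ms = {k: ss[k] / dof[k] for k in ss if dof[k] > 0}

    clamped: list = []
    s_e2 = max(ms["err"], 0.0)
    s_gre2 = _clamp("S_GRE2", (ms["G(R)E"] - ms["err"]) / n, clamped)
    s_re2 = _clamp("S_RE2", (ms["RE"] - ms["G(R)E"]) / (n * g), clamped)
    s_gr2 = _clamp("S_GR2", (ms["G(R)"] - ms["G(R)E"]) / (n * e), clamped)
    s_r2 = _clamp(
        "S_R2",
        (ms["R"] - ms["G(R)"] - ms["RE"] + ms["G(R)E"]) / (n * g * e),
        clamped,
    )
    # Satterthwaite synthetic denominator for the population main effect
    ms_den_r = ms["G(R)"] + ms["RE"] - ms["G(R)E"]
    if ms_den_r > 0:
        df_den_r = ms_den_r**2 / (
            ms["G(R)"] ** 2 / dof["G(R)"]
            + ms["RE"] ** 2 / dof["RE"]
            + ms["G(R)E"] ** 2 / dof["G(R)E"]
        )
        p_r = float(stats.f.sf(ms["R"] / ms_den_r, dof["R"], df_den_r))
    else:
        p_r = float("nan")
    p = {
        "S_R2": p_r,
        "S_GR2": float(stats.f.sf(ms["G(R)"] / ms["G(R)E"], dof["G(R)"], dof["G(R)E"])),
        "S_RE2": float(stats.f.sf(ms["RE"] / ms["G(R)E"], dof["RE"], dof["G(R)E"])),
        "S_GRE2": float(stats.f.sf(ms["G(R)E"] / ms["err"], dof["G(R)E"], dof["err"])),
    }
    return VarianceComponents(
        S_R2=s_r2, S_GR2=s_gr2, S_RE2=s_re2, S_GRE2=s_gre2, S_e2=s_e2,
        n_reps=n, n_envs=e, mean=float(m), p_values=p, clamped=clamped,
    )


def cv_g(S_G2: float, mean: float) -> float:
    """Genetic coefficient of variation, 100 * sqrt(S_G2) / mean (percent)."""
    if S_G2 < 0:
        raise ValueError("S_G2 must be >= 0")
    if mean == 0:
        raise ValueError("mean must be nonzero")
    return 100.0 * np.sqrt(S_G2) / mean


def h2_single_env(S_G2: float, S_e2: float, n_reps: int) -> float:
    """Broad-sense heritability on a genotype-mean basis, one environment."""
    if S_G2 < 0 or S_e2 < 0 or n_reps < 1:
        raise ValueError("components must be >= 0 and n_reps >= 1")
    denom = S_G2 + S_e2 / n_reps
    if denom == 0:
        raise ValueError("H2 undefined: all components zero")
    return S_G2 / denom


def h2_multi_env(S_G2: float, S_GE2: float, S_e2: float, n_envs: int, n_reps: int) -> float:
    """Broad-sense heritability across environments on a genotype-mean basis."""
    if min(S_G2, S_GE2, S_e2) < 0 or n_envs < 1 or n_reps < 1:
        raise ValueError("components must be >= 0 and counts >= 1")
    denom = S_G2 + S_GE2 / n_envs + S_e2 / (n_envs * n_reps)
    if denom == 0:
        raise ValueError("H2 undefined: all components zero")
    return S_G2 / denom


def genetic_correlation(r_pheno: float, H_env1: float, H_env2: float):
    """Genetic correlation r_g = r / (H1 * H2); returns ``(r_g, out_of_range)``.

    H values are square roots of broad-sense heritability. Estimation noise
    can push |r_g| past 1; the value is returned as-is with a flag.
    """
    if not (0 < H_env1 <= 1 and 0 < H_env2 <= 1):
        raise ValueError("H values must lie in (0, 1]")
    r_g = r_pheno / (H_env1 * H_env2)
    return r_g, abs(r_g) > 1.0


def blup_line_means(ph: PhenotypeTable, environment, trait: str) -> pd.Series:
    """Shrink line means toward the environment grand mean by H2.

    BLUP_i = m + H2 * (mean_i - m), with H2 from the pooled-genotype
    single-environment components. These values are the phenotypic inputs
    to the genomic prediction models.
    """
    vc = estimate_vc_single_env(ph, environment, trait)
    h2 = h2_single_env(vc.S_G2, vc.S_e2, vc.n_reps)
    means = ph.line_means(trait, environment=environment)
    return vc.mean + h2 * (means - vc.mean)


def trait_correlations(line_values: pd.DataFrame, grouping: pd.Series | None = None):
    """Pairwise Pearson correlations with two-sided p-values.

    ``line_values`` is a line x trait table; ``grouping`` (optional) maps
    line -> population for per-group results. Returns a dict
    group -> (r DataFrame, p DataFrame); the pooled analysis uses the key
    ``'pooled'``. Constant columns give NaN and are flagged via NaN.
    """
    if len(line_values) < 3:
        raise ValueError("need at least 3 lines")
    groups = {"pooled": line_values} if grouping is None else {
        g: line_values.loc[grouping[grouping == g].index] for g in grouping.unique()
    }
    out = {}
    for name, df in groups.items():
        cols = df.columns
        k = len(cols)
        r = pd.DataFrame(np.eye(k), index=cols, columns=cols)
        p = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
        for i in range(k):
            for j in range(i + 1, k):
                x, y = df[cols[i]], df[cols[j]]
                if x.std() == 0 or y.std() == 0:
                    r.iloc[i, j] = r.iloc[j, i] = np.nan
                    p.iloc[i, j] = p.iloc[j, i] = np.nan
                else:
                    res = stats.pearsonr(x, y)
                    r.iloc[i, j] = r.iloc[j, i] = res.statistic
                    p.iloc[i, j] = p.iloc[j, i] = res.pvalue
        out[name] = (r, p)
    return out
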