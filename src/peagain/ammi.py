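"""AMMI: additive main effects plus multiplicative interaction via SVD.

The genotype x environment cell-mean matrix is double-centered; its SVD
gives interaction axes. Axis retention iterates the Cornelius-style F_R
test on the residual from n = 0 upward. Nominal values (entry mean plus the
PC1 interaction term, excluding the environment main effect) support the
classic one-axis adaptation plot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["AMMIFit", "ammi_fit", "f_r_test", "nominal_yields", "select_top_entries"]


@dataclass
class AMMIFit:
    grand_mean: float
    genotype_effects: pd.Series  # sum to 0
    environment_effects: pd.Series  # sum to 0
    singular_values: np.ndarray  # nonincreasing SVD singular values
    axis_ss: np.ndarray  # squared singular values; sum equals the GEI SS
    genotype_scores: np.ndarray  # (n_genotypes, n_axes), unit columns
    environment_scores: np.ndarray  # (n_environments, n_axes), unit columns
    retained_axes: int
    pct_gei_explained: np.ndarray
    residual: pd.DataFrame  # deviation d_ij for the retained model
    n_reps: int
    ms_error: float
    axis_p_values: np.ndarray  # p-value of the residual after 0,1,... axes

    @property
    def gei_ss(self) -> float:
        return float(self.axis_ss.sum())

    def reconstruct(self, n_axes: int | None = None) -> pd.DataFrame:
        """Modelled cell means with the first ``n_axes`` interaction axes."""
        k = self.retained_axes if n_axes is None else n_axes
        base = (
            self.grand_mean
            + self.genotype_effects.to_numpy()[:, None]
            + self.environment_effects.to_numpy()[None, :]
        )
        for n in range(k):
            s = self.singular_values[n]
            base = base + s * np.outer(
                self.genotype_scores[:, n], self.environment_scores[:, n]
            )
        return pd.DataFrame(
            base, index=self.genotype_effects.index, columns=self.environment_effects.index
        )


def f_r_test(
    gei_ss: float,
    axis_ss: np.ndarray,
    n_genotypes: int,
    n_environments: int,
    ms_error: float,
    df_error: int,
    n_reps: int,
) -> np.ndarray:
    """F_R p-values for the AMMI residual after retaining 0, 1, ... axes.

    With cell means as the analysis unit, the residual SS on the plot scale
    is n_reps * (GEI SS - sum of the first n axis SS); its df is
    (g - 1 - n)(e - 1 - n). F = residual MS / MS_error against the plot-level
    error. Returns one p-value per candidate residual (stops when df <= 0).
    """
    if df_error <= 0:
        raise ValueError("df_error must be positive")
    axis_ss = np.asarray(axis_ss, dtype=float)
    g, e = n_genotypes, n_environments
    p_values = []
    for n in range(len(axis_ss) + 1):
        df_r = (g - 1 - n) * (e - 1 - n)
        if df_r <= 0:
            break
        resid_ss = max(gei_ss - axis_ss[:n].sum(), 0.0) * n_reps
        if resid_ss == 0.0:
            p_values.append(1.0)
            continue
        f_stat = (resid_ss / df_r) / ms_error
        p_values.append(float(stats.f.sf(f_stat, df_r, df_error)))
    return np.array(p_values)


def ammi_fit(
    cell_means: pd.DataFrame,
    ms_error: float,
    df_error: int,
    n_reps: int,
    alpha: float = 0.05,
) -> AMMIFit:
    """Fit the AMMI model to a complete genotype x environment mean matrix.

    Axes are retained by adding one while the F_R residual stays significant
    at ``alpha``. Sign convention: the first environment's score on each axis
    is nonnegative.
    """
    if cell_means.isna().any().any():
        raise ValueError("cell-mean matrix must be complete (no imputation)")
    g, e = cell_means.shape
    if g < 2 or e < 2:
        raise ValueError("need at least 2 genotypes and 2 environments")
    y = cell_means.to_numpy(dtype=float)
    m = y.mean()
    g_eff = y.mean(axis=1) - m
    e_eff = y.mean(axis=0) - m
    z = y - m - g_eff[:, None] - e_eff[None, :]

    u, s, vt = np.linalg.svd(z, full_matrices=False)
    max_axes = min(g - 1, e - 1)
    u, s, v = u[:, :max_axes], s[:max_axes], vt[:max_axes].T
    # deterministic signs: first environment's score nonnegative per axis
    for n in range(max_axes):
        if v[0, n] < 0:
            u[:, n] *= -1
            v[:, n] *= -1
    axis_ss = s**2  # axis sums of squares on the cell-mean scale
    gei_ss = float(axis_ss.sum())

    p_values = f_r_test(gei_ss, axis_ss, g, e, ms_error, df_error, n_reps)
    retained = 0
    while retained < len(p_values) and p_values[retained] < alpha:
        retained += 1
    retained = min(retained, max_axes)

    pct = 100.0 * axis_ss / gei_ss if gei_ss > 0 else np.zeros_like(axis_ss)
    fit = AMMIFit(
        grand_mean=float(m),
        genotype_effects=pd.Series(g_eff, index=cell_means.index),
        environment_effects=pd.Series(e_eff, index=cell_means.columns),
        singular_values=s,
        axis_ss=axis_ss,
        genotype_scores=u,
        environment_scores=v,
        retained_axes=retained,
        pct_gei_explained=pct,
        residual=pd.DataFrame(z, index=cell_means.index, columns=cell_means.columns),
        n_reps=n_reps,
        ms_error=ms_error,
        axis_p_values=p_values,
    )
    fit.residual = cell_means - fit.reconstruct(retained)
    return fit


def nominal_yields(fit: AMMIFit, axis: int = 0) -> pd.DataFrame:
    """Entry mean plus the modelled interaction on one axis, per environment.

    nominal_ij = m + G_i + (u_in sqrt(l_n)) * (v_jn sqrt(l_n)); the
    environment main effect is excluded as irrelevant for entry ranking.
    Returns a tidy frame (genotype, environment, env_score, nominal).
    """
    if axis >= fit.retained_axes:
        raise ValueError(
            f"axis {axis} not retained (retained_axes={fit.retained_axes})"
        )
    root_l = np.sqrt(fit.singular_values[axis])
    g_scores = fit.genotype_scores[:, axis] * root_l
    e_scores = fit.environment_scores[:, axis] * root_l
    rows = []
    for i, gid in enumerate(fit.genotype_effects.index):
        for j, env in enumerate(fit.environment_effects.index):
            rows.append(
                (
                    gid,
                    env,
                    e_scores[j],
                    fit.grand_mean + fit.genotype_effects.iloc[i] + g_scores[i] * e_scores[j],
                )
            )
    return pd.DataFrame(rows, columns=["genotype", "environment", "env_score", "nominal"])


def select_top_entries(
    fit: AMMIFit,
    per_environment: int = 2,
    overall: int = 2,
    references: list | None = None,
) -> list:
    """Top entries by AMMI-modelled value per environment and by mean.

    Set semantics; reference entries are always included. Mirrors the usual
    "two top entries in each environment or across environments" plot subset.
    """
    if per_environment < 0 or overall < 0:
        raise ValueError("counts must be >= 0")
    modelled = fit.reconstruct()
    chosen: set = set(references or [])
    for env in modelled.columns:
        chosen.update(modelled[env].nlargest(per_environment).index)
    chosen.update(modelled.mean(axis=1).nlargest(overall).index)
    return sorted(chosen, key=lambda x: str(x))
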