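"""Stratified association scan with PCA structure correction.

Per stratum (RIL population), phenotype and marker dosages are residualized
on the leading principal components of the genotype matrix; the 1-df score
statistic is computed per marker, corrected for genomic inflation (median
chi-square over 0.4549, floored at 1), and strata are combined by summing
chi-squares with summed degrees of freedom. Association score = -log10 p.
Benjamini-Yekutieli FDR and pairwise LD r2 round out the module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from peagain.genotypes import GenotypeMatrix

__all__ = [
    "GWASResult",
    "pca_structure",
    "score_test_stratified",
    "inflation_correction",
    "by_fdr",
    "ld_r2",
]

CHI2_1DF_MEDIAN = float(stats.chi2.median(1))  # 0.4549...


@dataclass
class GWASResult:
    marker_ids: list[str]
    statistics: np.ndarray  # combined chi-square per marker
    df: np.ndarray  # contributing strata per marker
    p_values: np.ndarray
    scores: np.ndarray  # -log10 p
    adjusted_p: np.ndarray  # BY-FDR
    inflation_factors: dict  # stratum -> lambda_GC
    per_stratum_statistics: pd.DataFrame  # marker x stratum (corrected)
    monomorphic_flags: pd.DataFrame  # marker x stratum booleans
    threshold: float = 3.0
    significant: list = field(default_factory=list)

    def top(self, n: int = 100) -> pd.DataFrame:
        order = np.argsort(self.scores)[::-1][:n]
        return pd.DataFrame(
            {
                "marker": [self.marker_ids[i] for i in order],
                "score": self.scores[order],
                "p": self.p_values[order],
                "adjusted_p": self.adjusted_p[order],
            }
        )


def pca_structure(genotypes: GenotypeMatrix, n_components: int = 2) -> pd.DataFrame:
    """Principal component scores of the centered dosage matrix.

    Deterministic sign convention: the loading of largest magnitude on each
    component is positive. Raises if more components than the matrix rank
    are requested.
    """
    if genotypes.has_missing():
        raise ValueError("PCA requires complete genotype data")
    z = genotypes.dosage - genotypes.dosage.mean(axis=0)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum()) if s.size else 0
    if n_components > rank:
        raise ValueError(f"requested {n_components} components but rank is {rank}")
    scores = u[:, :n_components] * s[:n_components]
    for c in range(n_components):
        j = np.argmax(np.abs(vt[c]))
        if vt[c, j] < 0:
            scores[:, c] *= -1
    return pd.DataFrame(
        scores,
        index=genotypes.line_ids,
        columns=[f"PC{c + 1}" for c in range(n_components)],
    )


def _residualize(v: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(covariates, v, rcond=None)
    return v - covariates @ beta


def _score_stats_one_stratum(
    dosage: np.ndarray, y: np.ndarray, covariates: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """1-df score statistics per marker after residualizing on covariates.

    T_j = (x_j' y)^2 / (x_j' x_j * sigma0^2) with residualized x, y and the
    null variance sigma0^2 = y'y / n. Monomorphic markers get statistic 0
    and a flag.
    """
    n, q = covariates.shape
    y_res = _residualize(y, covariates)
    syy = y_res @ y_res
    x_res = dosage - covariates @ np.linalg.lstsq(covariates, dosage, rcond=None)[0]
    sxx = (x_res**2).sum(axis=0)
    mono = dosage.std(axis=0) == 0
    stat = np.zeros(dosage.shape[1])
    ok = (sxx > 1e-12) & ~mono & (syy > 0)
    u = x_res[:, ok].T @ y_res
    # partial r^2 after the covariates; exact Beta(1/2, (n-q-1)/2) null under
    # Gaussian phenotypes, mapped onto the 1-df chi-square scale so that the
    # statistic keeps its nominal calibration at any stratum size
    r2 = np.clip(u**2 / (sxx[ok] * syy), 0.0, 1.0)
    p_exact = stats.beta.sf(r2, 0.5, (n - q - 1) / 2.0)
    stat[ok] = stats.chi2.isf(np.clip(p_exact, np.finfo(float).tiny, 1.0), 1)
    return stat, mono | ~ok


def inflation_correction(statistics: np.ndarray) -> tuple[np.ndarray, float]:
    """Genomic-control correction of 1-df chi-square statistics.

    lambda_GC = median(statistic) / median(chi2_1); statistics are divided by
    max(lambda_GC, 1) — deflation is never applied.
    """
    statistics = np.asarray(statistics, dtype=float)
    lam = float(np.median(statistics) / CHI2_1DF_MEDIAN)
    return statistics / max(lam, 1.0), lam


def by_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjusted p-values (harmonic penalty)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_by")[1]


def score_test_stratified(
    genotypes: GenotypeMatrix,
    phenotype: pd.Series,
    pcs: pd.DataFrame | None = None,
    n_components: int = 2,
    threshold: float = 3.0,
    correct_inflation: bool = True,
) -> GWASResult:
    """Stratified, PC-adjusted single-marker score test.

    Strata are the populations of ``genotypes``. Per-stratum statistics are
    inflation-corrected then summed across strata (summed df) — a
    Fisher-style combination on the statistics. ``pcs`` defaults to
    ``pca_structure`` on the full matrix.
    """
    if genotypes.has_missing():
        raise ValueError("score test requires complete genotype data")
    if pcs is None:
        pcs = pca_structure(genotypes, n_components=n_components)
    labels = genotypes.population_labels
    strata = sorted(set(labels))
    y = np.asarray(phenotype.reindex(genotypes.line_ids), dtype=float)
    if np.isnan(y).any():
        raise ValueError("phenotype must cover all lines")

    per_stratum = {}
    flags = {}
    inflation = {}
    for pop in strata:
        rows = labels == pop
        if rows.sum() < 10:
            raise ValueError(f"stratum {pop!r} has fewer than 10 lines")
        cov = np.column_stack(
            [np.ones(rows.sum()), pcs.loc[np.array(genotypes.line_ids)[rows]].to_numpy()]
        )
        stat, mono = _score_stats_one_stratum(genotypes.dosage[rows], y[rows], cov)
        if correct_inflation and (~mono).sum() >= 100:
            # lambda over markers that actually segregate in this stratum
            corrected, lam = inflation_correction(stat[~mono])
            stat = stat.copy()
            stat[~mono] = corrected
        else:
            lam = 1.0
        per_stratum[pop] = stat
        flags[pop] = mono
        inflation[pop] = lam

    combined = np.sum([per_stratum[p] for p in strata], axis=0)
    # per-marker df: only strata where the marker segregates contribute
    df = np.sum([~flags[p] for p in strata], axis=0)
    p_values = np.ones(len(combined))
    ok = df > 0
    p_values[ok] = stats.chi2.sf(combined[ok], df[ok])
    p_values = np.clip(p_values, np.finfo(float).tiny, 1.0)
    scores = -np.log10(p_values)
    adjusted = by_fdr(p_values)
    significant = [m for m, s in zip(genotypes.marker_ids, scores) if s >= threshold]
    return GWASResult(
        marker_ids=list(genotypes.marker_ids),
        statistics=combined,
        df=df,
        p_values=p_values,
        scores=scores,
        adjusted_p=adjusted,
        inflation_factors=inflation,
        per_stratum_statistics=pd.DataFrame(per_stratum, index=genotypes.marker_ids),
        monomorphic_flags=pd.DataFrame(flags, index=genotypes.marker_ids),
        threshold=threshold,
        significant=significant,
    )


def ld_r2(marker_a: np.ndarray, marker_b: np.ndarray) -> float:
    """Squared Pearson correlation between two dosage vectors.

    Computed over lines with both calls present; monomorphic input gives NaN.
    """
    a = np.asarray(marker_a, dtype=float)
    b = np.asarray(marker_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors must have equal length")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if len(a) < 2 or a.std() == 0 or b.std() == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)
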