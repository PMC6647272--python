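"""Three genomic prediction models: rrBLUP, G-BLUP and the Bayesian Lasso.

rrBLUP solves the printed ridge closed form u = G'(GG' + lambda I)^-1 (y - mu)
with lambda = sigma_e^2 / sigma_u^2 estimated by spectral REML (the
variance-ratio restricted likelihood on the eigenvalues of GG'). G-BLUP is
the equivalent animal model on a kinship matrix. The Bayesian Lasso uses the
Park & Casella scale-mixture Gibbs sampler (single-site updates, numba-
accelerated). All models accept an optional population incidence matrix as
jointly estimated fixed effects; dosages are centered by training-set marker
means and never scaled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from peagain.genotypes import GenotypeMatrix, KinshipMatrix

__all__ = [
    "StructureDesign",
    "GSFit",
    "fit_rrblup",
    "fit_gblup",
    "fit_bayeslasso",
    "predict",
    "spectral_reml",
]


@dataclass
class StructureDesign:
    """Populations x lines 0/1 incidence matrix (each line in one population)."""

    pop_labels: list[str]
    line_ids: list[str]
    incidence: np.ndarray  # (n_pops, n_lines)

    def __post_init__(self) -> None:
        self.incidence = np.asarray(self.incidence, dtype=float)
        if self.incidence.shape != (len(self.pop_labels), len(self.line_ids)):
            raise ValueError("incidence shape must be (n_pops, n_lines)")
        if not np.allclose(self.incidence.sum(axis=0), 1.0):
            raise ValueError("each line must belong to exactly one population")

    @classmethod
    def from_populations(cls, populations: dict, line_ids: list[str],
                         pop_order: list[str] | None = None) -> "StructureDesign":
        pops = pop_order or sorted({populations[l] for l in line_ids})
        inc = np.zeros((len(pops), len(line_ids)))
        idx = {p: i for i, p in enumerate(pops)}
        for j, l in enumerate(line_ids):
            inc[idx[populations[l]], j] = 1.0
        return cls(pops, list(line_ids), inc)

    @property
    def design(self) -> np.ndarray:
        """Lines x populations design matrix (transpose of ``incidence``)."""
        return self.incidence.T


@dataclass
class GSFit:
    """A fitted genomic prediction model.

    Exactly one of ``marker_effects`` (rrblup / bayeslasso) or
    ``breeding_values`` (gblup) is the primary predictor.
    """

    model_kind: str
    mu: float
    fixed_effects: np.ndarray  # coefficients of the fixed-effect design
    structure_pops: list[str] | None
    marker_effects: np.ndarray | None = None
    breeding_values: pd.Series | None = None
    lam: float | None = None  # ridge parameter sigma_e^2 / sigma_u^2
    marker_means: np.ndarray | None = None
    marker_ids: list[str] | None = None
    line_ids: list[str] | None = None
    _alpha: np.ndarray | None = None  # (K + delta I)^-1 residual, gblup only
    mcmc_summary: dict = field(default_factory=dict)

    @property
    def structure_coefficients(self) -> dict | None:
        if self.structure_pops is None:
            return None
        return dict(zip(self.structure_pops, self.fixed_effects))


def _fixed_design(n: int, structure: StructureDesign | None) -> np.ndarray:
    if structure is None:
        return np.ones((n, 1))
    if len(structure.line_ids) != n:
        raise ValueError("structure design does not match sample count")
    return structure.design


def spectral_reml(y: np.ndarray, x: np.ndarray, k: np.ndarray,
                  bounds: tuple[float, float] = (-8.0, 8.0)) -> float:
    """REML estimate of delta = sigma_e^2 / sigma_g^2 for y = Xb + g + e.

    g ~ N(0, sigma_g^2 K). Profiles the restricted likelihood on the
    spectrum of K projected onto the orthogonal complement of X, then
    optimizes over log10(delta). Returns delta.
    """
    n, q = x.shape
    # orthonormal basis of the complement of col(X); the +I shift keeps the
    # complement's eigenvectors separated from col(X) even when K is rank
    # deficient (heavy LD duplicates marker columns), as in EMMA
    u_x, _ = np.linalg.qr(x)
    proj = np.eye(n) - u_x @ u_x.T
    eigval, eigvec = np.linalg.eigh(proj @ (k + np.eye(n)) @ proj)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order][: n - q], eigvec[:, order][:, : n - q]
    eigval = np.clip(eigval - 1.0, 0.0, None)
    eta = eigvec.T @ y
    m = n - q

    def neg_restricted_ll(log_delta: float) -> float:
        d = 10.0**log_delta
        w = eigval + d
        return 0.5 * (m * np.log(np.sum(eta**2 / w)) + np.sum(np.log(w)))

    res = minimize_scalar(neg_restricted_ll, bounds=bounds, method="bounded")
    return float(10.0 ** res.x)


def _gls_fixed(y: np.ndarray, x: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """GLS fixed effects under covariance proportional to ``v``; returns (b, V^-1 r)."""
    vinv = np.linalg.inv(v)
    xtvx = x.T @ vinv @ x
    b = np.linalg.solve(xtvx, x.T @ vinv @ y)
    return b, vinv @ (y - x @ b)


def fit_rrblup(
    genotypes: GenotypeMatrix,
    y: pd.Series,
    structure: StructureDesign | None = None,
    fixed_lambda: float | None = None,
) -> GSFit:
    """Ridge-regression BLUP of marker effects.

    ``y`` is a line -> phenotype series covering all lines of ``genotypes``.
    ``fixed_lambda`` bypasses REML (used by the ridge-oracle tests).
    """
    if genotypes.has_missing():
        raise ValueError("rrBLUP requires complete (imputed) genotype data")
    yv = np.asarray(y.reindex(genotypes.line_ids), dtype=float)
    if np.isnan(yv).any():
        raise ValueError("phenotype must cover all genotyped lines")
    x = _fixed_design(len(yv), structure)
    marker_means = genotypes.dosage.mean(axis=0)
    z = genotypes.dosage - marker_means

    if yv.std() == 0:
        warnings.warn("constant phenotype: all marker effects are zero")
        u_hat = np.zeros(genotypes.n_markers)
        b = np.linalg.lstsq(x, yv, rcond=None)[0]
        lam = float("inf")
    else:
        k = z @ z.T
        lam = fixed_lambda if fixed_lambda is not None else spectral_reml(yv, x, k)
        v = k + lam * np.eye(len(yv))
        b, vinv_r = _gls_fixed(yv, x, v)
        u_hat = z.T @ vinv_r  # G'(GG' + lambda I)^-1 (Y - Xb)
    return GSFit(
        model_kind="rrblup",
        mu=float(b[0]) if structure is None else float(np.mean(b)),
        fixed_effects=b,
        structure_pops=None if structure is None else list(structure.pop_labels),
        marker_effects=u_hat,
        lam=float(lam),
        marker_means=marker_means,
        marker_ids=list(genotypes.marker_ids),
        line_ids=list(genotypes.line_ids),
    )


def fit_gblup(
    kinship: KinshipMatrix,
    y: pd.Series,
    structure: StructureDesign | None = None,
    fixed_ratio: float | None = None,
    psd_tol: float = 1e-6,
) -> GSFit:
    """Animal-model BLUP of breeding values on a genomic kinship matrix.

    ``fixed_ratio`` is delta = sigma_e^2 / sigma_g^2; REML otherwise.
    """
    k = kinship.values
    min_eig = float(np.linalg.eigvalsh(k).min())
    if min_eig < -psd_tol * max(1.0, np.abs(np.diag(k)).max()):
        raise ValueError(
            f"kinship not PSD (min eigenvalue {min_eig:.3g}); add diagonal jitter"
        )
    yv = np.asarray(y.reindex(kinship.line_ids), dtype=float)
    if np.isnan(yv).any():
        raise ValueError("phenotype must cover all kinship lines")
    x = _fixed_design(len(yv), structure)
    if yv.std() == 0:
        warnings.warn("constant phenotype: all breeding values are zero")
        b = np.linalg.lstsq(x, yv, rcond=None)[0]
        bv = np.zeros(len(yv))
        alpha = np.zeros(len(yv))
        delta = float("inf")
    else:
        delta = fixed_ratio if fixed_ratio is not None else spectral_reml(yv, x, k)
        v = k + delta * np.eye(len(yv))
        b, alpha = _gls_fixed(yv, x, v)  # alpha = (K + delta I)^-1 (y - Xb)
        bv = k @ alpha
    return GSFit(
        model_kind="gblup",
        mu=float(b[0]) if structure is None else float(np.mean(b)),
        fixed_effects=b,
        structure_pops=None if structure is None else list(structure.pop_labels),
        breeding_values=pd.Series(bv, index=kinship.line_ids),
        lam=float(delta),
        line_ids=list(kinship.line_ids),
        _alpha=alpha,
    )


def fit_bayeslasso(
    genotypes: GenotypeMatrix,
    y: pd.Series,
    structure: StructureDesign | None = None,
    chain_length: int = 12000,
    burn_in: int = 2000,
    thin: int = 5,
    seed: int = 0,
    lambda_shape: float = 1.0,
    lambda_rate: float = 0.1,
) -> GSFit:
    """Bayesian Lasso via the Park & Casella Gibbs sampler.

    Double-exponential prior on marker effects through the exponential
    scale mixture of normals; gamma(``lambda_shape``, ``lambda_rate``)
    hyperprior on the squared regularization parameter. Posterior means of
    the thinned post-burn-in draws are returned. Deterministic given ``seed``.
    """
    if chain_length <= burn_in:
        raise ValueError("chain_length must exceed burn_in")
    if genotypes.has_missing():
        raise ValueError("Bayesian Lasso requires complete genotype data")
    yv = np.asarray(y.reindex(genotypes.line_ids), dtype=float)
    if np.isnan(yv).any():
        raise ValueError("phenotype must cover all genotyped lines")
    x = _fixed_design(len(yv), structure)
    marker_means = genotypes.dosage.mean(axis=0)
    z = np.ascontiguousarray(genotypes.dosage - marker_means)

    beta_draws, b_draws, sigma2_draws, lam2_draws = _bl_gibbs(
        yv, x, z, chain_length, burn_in, thin,
        lambda_shape, lambda_rate, seed,
    )
    if not np.isfinite(beta_draws).all():
        bad = int(np.argwhere(~np.isfinite(beta_draws).all(axis=1))[0][0])
        raise RuntimeError(f"divergent chain: non-finite draw at saved sample {bad}")
    beta = beta_draws.mean(axis=0)
    b = b_draws.mean(axis=0)
    return GSFit(
        model_kind="bayeslasso",
        mu=float(b[0]) if structure is None else float(np.mean(b)),
        fixed_effects=b,
        structure_pops=None if structure is None else list(structure.pop_labels),
        marker_effects=beta,
        marker_means=marker_means,
        marker_ids=list(genotypes.marker_ids),
        line_ids=list(genotypes.line_ids),
        mcmc_summary={
            "chain_length": chain_length,
            "burn_in": burn_in,
            "thin": thin,
            "seed": seed,
            "n_saved": beta_draws.shape[0],
            "posterior_sd_effects": beta_draws.std(axis=0),
            "sigma2_mean": float(sigma2_draws.mean()),
            "lambda2_mean": float(lam2_draws.mean()),
        },
    )


def _bl_gibbs_py(y, x, z, chain_length, burn_in, thin, lam_shape, lam_rate, seed):
    """Reference NumPy implementation; superseded by the numba kernel."""
    rng = np.random.RandomState(seed)
    n, p = z.shape
    q = x.shape[1]
    ztz = (z**2).sum(axis=0)
    xtx = (x**2).sum(axis=0)
    beta = np.zeros(p)
    b = np.linalg.lstsq(x, y, rcond=None)[0]
    tau2 = np.ones(p)
    sigma2 = max(y.var(), 1e-8)
    lam2 = 1.0
    resid = y - x @ b
    n_saved = (chain_length - burn_in) // thin
    beta_out = np.zeros((n_saved, p))
    b_out = np.zeros((n_saved, q))
    s2_out = np.zeros(n_saved)
    l2_out = np.zeros(n_saved)
    saved = 0
    for it in range(chain_length):
        for f in range(q):
            resid += x[:, f] * b[f]
            mean = x[:, f] @ resid / xtx[f]
            b[f] = rng.normal(mean, np.sqrt(sigma2 / xtx[f]))
            resid -= x[:, f] * b[f]
        for j in range(p):
            resid += z[:, j] * beta[j]
            a = ztz[j] + 1.0 / tau2[j]
            mean = z[:, j] @ resid / a
            beta[j] = rng.normal(mean, np.sqrt(sigma2 / a))
            resid -= z[:, j] * beta[j]
        for j in range(p):
            mu_ig = np.sqrt(lam2 * sigma2 / max(beta[j] ** 2, 1e-12))
            inv_tau2 = rng.wald(mu_ig, lam2)
            tau2[j] = 1.0 / max(inv_tau2, 1e-12)
        shape = (n + p) / 2.0
        scale = (resid @ resid + np.sum(beta**2 / tau2)) / 2.0
        sigma2 = scale / rng.gamma(shape, 1.0)
        lam2 = rng.gamma(p + lam_shape, 1.0 / (np.sum(tau2) / 2.0 + lam_rate))
        if it >= burn_in and (it - burn_in) % thin == 0 and saved < n_saved:
            beta_out[saved] = beta
            b_out[saved] = b
            s2_out[saved] = sigma2
            l2_out[saved] = lam2
            saved += 1
    return beta_out, b_out, s2_out, l2_out


try:  # single-site Gibbs is loop-heavy; compile it when numba is available
    import numba

    @numba.njit(cache=True)
    def _rinvgauss(mu, lam):
        v = np.random.normal()
        ysq = v * v
        xx = (
            mu
            + mu * mu * ysq / (2.0 * lam)
            - mu / (2.0 * lam) * np.sqrt(4.0 * mu * lam * ysq + mu * mu * ysq * ysq)
        )
        if np.random.random() <= mu / (mu + xx):
            return xx
        return mu * mu / xx

    @numba.njit(cache=True)
    def _bl_gibbs_kernel(y, x, z, chain_length, burn_in, thin, lam_shape, lam_rate, seed):
        np.random.seed(seed)
        n, p = z.shape
        q = x.shape[1]
        ztz = np.zeros(p)
        for j in range(p):
            for i in range(n):
                ztz[j] += z[i, j] * z[i, j]
        xtx = np.zeros(q)
        for f in range(q):
            for i in range(n):
                xtx[f] += x[i, f] * x[i, f]
        beta = np.zeros(p)
        b = np.zeros(q)
        ybar = y.mean()
        for f in range(q):
            b[f] = ybar
        tau2 = np.ones(p)
        sigma2 = max(y.var(), 1e-8)
        lam2 = 1.0
        resid = y.copy()
        for i in range(n):
            for f in range(q):
                resid[i] -= x[i, f] * b[f]
        n_saved = (chain_length - burn_in) // thin
        beta_out = np.zeros((n_saved, p))
        b_out = np.zeros((n_saved, q))
        s2_out = np.zeros(n_saved)
        l2_out = np.zeros(n_saved)
        saved = 0
        for it in range(chain_length):
            for f in range(q):
                dot = 0.0
                for i in range(n):
                    resid[i] += x[i, f] * b[f]
                    dot += x[i, f] * resid[i]
                mean = dot / xtx[f]
                b[f] = np.random.normal() * np.sqrt(sigma2 / xtx[f]) + mean
                for i in range(n):
                    resid[i] -= x[i, f] * b[f]
            for j in range(p):
                old = beta[j]
                a = ztz[j] + 1.0 / tau2[j]
                dot = 0.0
                for i in range(n):
                    resid[i] += z[i, j] * old
                    dot += z[i, j] * resid[i]
                mean = dot / a
                beta[j] = np.random.normal() * np.sqrt(sigma2 / a) + mean
                for i in range(n):
                    resid[i] -= z[i, j] * beta[j]
            for j in range(p):
                b2 = beta[j] * beta[j]
                if b2 < 1e-12:
                    b2 = 1e-12
                mu_ig = np.sqrt(lam2 * sigma2 / b2)
                inv_tau2 = _rinvgauss(mu_ig, lam2)
                if inv_tau2 < 1e-12:
                    inv_tau2 = 1e-12
                tau2[j] = 1.0 / inv_tau2
            rss = 0.0
            for i in range(n):
                rss += resid[i] * resid[i]
            pen = 0.0
            tausum = 0.0
            for j in range(p):
                pen += beta[j] * beta[j] / tau2[j]
                tausum += tau2[j]
            shape = (n + p) / 2.0
            scale = (rss + pen) / 2.0
            sigma2 = scale / np.random.gamma(shape, 1.0)
            lam2 = np.random.gamma(p + lam_shape, 1.0 / (tausum / 2.0 + lam_rate))
            if it >= burn_in and (it - burn_in) % thin == 0 and saved < n_saved:
                for j in range(p):
                    beta_out[saved, j] = beta[j]
                for f in range(q):
                    b_out[saved, f] = b[f]
                s2_out[saved] = sigma2
                l2_out[saved] = lam2
                saved += 1
        return beta_out, b_out, s2_out, l2_out

    def _bl_gibbs(y, x, z, chain_length, burn_in, thin, lam_shape, lam_rate, seed):
        return _bl_gibbs_kernel(
            np.ascontiguousarray(y, dtype=np.float64),
            np.ascontiguousarray(x, dtype=np.float64),
            np.ascontiguousarray(z, dtype=np.float64),
            int(chain_length), int(burn_in), int(thin),
            float(lam_shape), float(lam_rate), int(seed) % (2**31 - 1),
        )

except ImportError:  # pragma: no cover - numba is a hard speed dependency
    _bl_gibbs = _bl_gibbs_py


def predict(
    fit: GSFit,
    genotypes_new: GenotypeMatrix | None = None,
    kinship_cross: np.ndarray | None = None,
    structure_new: StructureDesign | None = None,
) -> pd.Series:
    """Predicted values for new lines.

    Marker models: fixed effects + centered-dosage x marker effects
    (centering constants come from training). G-BLUP: fixed effects +
    K_cross (K + delta I)^-1 (y - Xb), algebraically equal to
    K_cross K^-1 BLUP.
    """
    if (fit.structure_pops is None) != (structure_new is None):
        raise ValueError("structure usage must match between fit and prediction")
    if fit.model_kind in ("rrblup", "bayeslasso"):
        if genotypes_new is None:
            raise ValueError("marker models need genotypes_new")
        missing = set(fit.marker_ids) - set(genotypes_new.marker_ids)
        if missing:
            raise ValueError(f"markers absent from new genotypes: {sorted(missing)[:5]}")
        if genotypes_new.marker_ids != fit.marker_ids:
            order = [genotypes_new.marker_ids.index(mk) for mk in fit.marker_ids]
            dose = genotypes_new.dosage[:, order]
        else:
            dose = genotypes_new.dosage
        if np.isnan(dose).any():
            raise ValueError("prediction requires complete genotype data")
        x_new = _fixed_design(genotypes_new.n_lines, structure_new)
        values = x_new @ fit.fixed_effects + (dose - fit.marker_means) @ fit.marker_effects
        return pd.Series(values, index=genotypes_new.line_ids)
    if fit.model_kind == "gblup":
        if kinship_cross is None:
            raise ValueError("gblup prediction needs a new-by-training cross kinship")
        kc = np.atleast_2d(np.asarray(kinship_cross, dtype=float))
        if kc.shape[1] != len(fit.line_ids):
            raise ValueError("cross kinship columns must match training lines")
        x_new = _fixed_design(kc.shape[0], structure_new)
        values = x_new @ fit.fixed_effects + kc @ fit._alpha
        return pd.Series(values)
    raise ValueError(f"unknown model kind {fit.model_kind!r}")


def fitted_values(fit: GSFit, genotypes: GenotypeMatrix | None = None,
                  structure: StructureDesign | None = None) -> pd.Series:
    """Training-set fitted values (definitional identity for marker models)."""
    if fit.model_kind == "gblup":
        x = _fixed_design(len(fit.line_ids), structure)
        return pd.Series(x @ fit.fixed_effects, index=fit.line_ids) + fit.breeding_values
    return predict(fit, genotypes_new=genotypes, structure_new=structure)
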