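"""Synthetic connected RIL populations and multi-environment RCB phenotypes.

Three (by default) fully homozygous parents are crossed pairwise; each cross
is advanced by single-seed descent for a configurable number of selfing
meioses (five by default, giving F6-like material with residual
heterozygosity 0.5^5 per segregating locus). Markers live on 7 abstract
linkage groups with uniform positions; recombination follows a Haldane
(no-interference) model, i.e. Poisson crossovers per chromosome per meiosis.

Phenotypes follow a randomized-complete-block design in every environment:
plot value = environment mean + genetic value + GEI deviation + block effect
+ residual. GEI is low-rank (rank 1 by default): per-environment loadings on
a second set of QTL effects, so a PC1-dominant interaction structure is
reproduced. Residual variance is scaled per environment to hit the requested
heritability on a genotype-mean basis (see ``h2_basis``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from peagain.genotypes import GenotypeMatrix
from peagain.quantgen import PhenotypeTable

__all__ = [
    "SimConfig",
    "TraitModel",
    "simulate_parents",
    "simulate_ril_population",
    "sample_trait_model",
    "simulate_phenotypes",
    "mask_missing",
    "simulate_study",
    "N_CHROMOSOMES",
]

N_CHROMOSOMES = 7  # pea has 7 linkage groups
CHROM_LENGTH_MORGAN = 1.0


class ConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Configuration of a synthetic connected-RIL study."""

    n_parents: int = 3
    n_markers: int = 1000
    lines_per_pop: int = 100
    crosses: list[tuple[int, int]] | None = None
    inbreeding_generations: int = 5
    n_qtl: int = 50
    h2_per_env: dict[str, float] = field(default_factory=lambda: {"env1": 0.5, "env2": 0.5, "env3": 0.5})
    gei_sd_ratio: float = 0.5
    n_environments: int = 3
    n_blocks: int = 3
    block_sd: float = 0.2
    maf_min: float = 0.05
    missing_rate: float = 0.0
    h2_basis: str = "line_mean"  # or "plot"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.crosses is None:
            # paired crosses among the first three parents, mirroring a
            # three-parent connected design
            self.crosses = [(0, 1), (1, 2), (2, 0)][: max(1, self.n_parents)]
        for a, b in self.crosses:
            if not (0 <= a < self.n_parents and 0 <= b < self.n_parents) or a == b:
                raise ConfigError(f"cross ({a},{b}) references invalid parents")
        for env, h2 in self.h2_per_env.items():
            if not 0.0 < h2 < 1.0:
                raise ConfigError(f"h2 for {env!r} must lie strictly in (0,1)")
        for name in ("n_parents", "n_markers", "lines_per_pop",
                     "inbreeding_generations", "n_qtl", "n_environments", "n_blocks"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate must lie in [0, 1)")
        if self.gei_sd_ratio < 0:
            raise ConfigError("gei_sd_ratio must be >= 0")
        if self.h2_basis not in ("line_mean", "plot"):
            raise ConfigError("h2_basis must be 'line_mean' or 'plot'")
        if len(self.h2_per_env) != self.n_environments:
            # fill/truncate a uniform map when the default does not match
            base = next(iter(self.h2_per_env.values()))
            self.h2_per_env = {f"env{j + 1}": base for j in range(self.n_environments)}

    @property
    def environments(self) -> list[str]:
        return sorted(self.h2_per_env)


@dataclass
class TraitModel:
    """Additive polygenic trait with low-rank environment-specific deviations.

    ``env_effects[j, q]`` is the deviation effect of QTL ``q`` in environment
    ``j`` (already scaled); genetic and GEI values are dosage-weighted sums.
    """

    qtl_indices: np.ndarray
    main_effects: np.ndarray
    env_effects: np.ndarray  # (n_env, n_qtl)
    env_means: np.ndarray  # (n_env,)

    def __post_init__(self) -> None:
        self.qtl_indices = np.asarray(self.qtl_indices, dtype=int)
        self.main_effects = np.asarray(self.main_effects, dtype=float)
        self.env_effects = np.atleast_2d(np.asarray(self.env_effects, dtype=float))
        self.env_means = np.asarray(self.env_means, dtype=float)
        if len(np.unique(self.qtl_indices)) != len(self.qtl_indices):
            raise ValueError("qtl_indices must be unique")
        if self.main_effects.shape != self.qtl_indices.shape:
            raise ValueError("one main effect per QTL required")
        if self.env_effects.shape[1] != len(self.qtl_indices):
            raise ValueError("env_effects must have one column per QTL")


def marker_positions(n_markers: int) -> tuple[np.ndarray, np.ndarray]:
    """Chromosome index and position (Morgan) for uniformly placed markers."""
    chrom = np.arange(n_markers) * N_CHROMOSOMES // n_markers
    pos = np.empty(n_markers)
    for c in range(N_CHROMOSOMES):
        on_c = chrom == c
        k = int(on_c.sum())
        if k:
            pos[on_c] = np.linspace(0, CHROM_LENGTH_MORGAN, k + 2)[1:-1]
    return chrom, pos


def _recomb_probs(n_markers: int) -> np.ndarray:
    """Haldane recombination fraction between adjacent markers.

    Chromosome boundaries get r = 0.5 (independent assortment).
    """
    chrom, pos = marker_positions(n_markers)
    r = np.empty(n_markers)
    r[0] = 0.5  # start of first chromosome: random starting haplotype handled via XOR
    d = np.diff(pos)
    r[1:] = 0.5 * (1.0 - np.exp(-2.0 * d))
    r[1:][np.diff(chrom) != 0] = 0.5
    return r


def simulate_parents(cfg: SimConfig, seed: int | None = None) -> GenotypeMatrix:
    """Draw fully homozygous parents (dosages in {0, 2}).

    Each parental allele is an independent fair coin, so a cross segregates
    at roughly half of the markers and post-cross MAF of 0.5 at segregating
    loci is achievable for any ``maf_min`` <= 0.5.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    dosage = 2.0 * rng.integers(0, 2, size=(cfg.n_parents, cfg.n_markers)).astype(float)
    line_ids = [f"P{i + 1}" for i in range(cfg.n_parents)]
    return GenotypeMatrix(
        line_ids,
        [f"m{j + 1}" for j in range(cfg.n_markers)],
        dosage,
        {l: "parents" for l in line_ids},
    )


def _gametes(hap_a: np.ndarray, hap_b: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One gamete per row pair, vectorized over lines.

    ``hap_a``/``hap_b`` have shape (n_lines, n_markers); the returned gamete
    picks alleles by a cumulative-XOR recombination indicator whose switch
    probabilities follow the Haldane map.
    """
    n_lines, n_markers = hap_a.shape
    r = _recomb_probs(n_markers)
    switch = rng.random((n_lines, n_markers)) < r
    take_b = np.bitwise_xor.accumulate(switch, axis=1)
    return np.where(take_b, hap_b, hap_a)


def simulate_ril_population(
    parent_a: np.ndarray,
    parent_b: np.ndarray,
    n_lines: int,
    generations: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Advance an F1 by single-seed descent for ``generations`` meioses.

    Parameters are parental dosage rows (homozygous, values in {0, 2});
    the result is an ``n_lines x n_markers`` dosage matrix in {0, 1, 2} with
    expected residual heterozygosity 0.5^generations at segregating loci.
    """
    parent_a = np.asarray(parent_a, dtype=float)
    parent_b = np.asarray(parent_b, dtype=float)
    if parent_a.shape != parent_b.shape:
        raise ValueError("parents must share the same marker set")
    if generations < 1:
        raise ValueError("generations must be >= 1")
    rng = np.random.default_rng(seed)
    hap1 = np.tile(parent_a / 2.0, (n_lines, 1)).astype(np.int8)
    hap2 = np.tile(parent_b / 2.0, (n_lines, 1)).astype(np.int8)
    for _ in range(generations):
        new1 = _gametes(hap1, hap2, rng)
        new2 = _gametes(hap1, hap2, rng)
        hap1, hap2 = new1, new2
    return (hap1 + hap2).astype(float)


def sample_trait_model(cfg: SimConfig, genotypes: GenotypeMatrix,
                       seed: int | None = None) -> TraitModel:
    """Draw QTL positions and effects, scaling GEI to ``gei_sd_ratio``.

    GEI deviations are rank 1: per-environment loadings multiply one shared
    vector of QTL deviation effects, scaled so the per-line deviation SD is
    ``gei_sd_ratio`` times the SD of genetic values. The loadings are
    normalized so that the loading mean squares to 1/e and the centered
    loadings have sum of squares e - 1: with that normalization the balanced
    ANOVA expected-mean-square identities hold for the rank-1 interaction
    exactly as they would for an iid one, so variance-ratio recovery is
    unbiased while PC1 still carries all the interaction.
    """
    rng = np.random.default_rng((cfg.seed + 101) if seed is None else seed)
    qtl = rng.choice(cfg.n_markers, size=min(cfg.n_qtl, cfg.n_markers), replace=False)
    main = rng.normal(0.0, 1.0, size=len(qtl))
    dev = rng.normal(0.0, 1.0, size=len(qtl))
    e = cfg.n_environments
    raw = rng.normal(0.0, 1.0, size=e)
    centered = raw - raw.mean()
    norm = np.sqrt((centered**2).sum())
    direction = centered / norm * np.sqrt(e - 1) if norm > 0 and e > 1 else np.zeros(e)
    sign = 1.0 if rng.random() < 0.5 else -1.0
    loadings = sign / np.sqrt(e) + direction

    dose = genotypes.dosage[:, qtl]
    g_values = dose @ main
    sd_g = g_values.std()
    env_effects = np.outer(loadings, dev)
    if cfg.gei_sd_ratio > 0 and sd_g > 0:
        d_values = dose @ dev  # shared per-line deviation
        sd_d = d_values.std()
        if sd_d > 0:
            env_effects *= cfg.gei_sd_ratio * sd_g / sd_d
    else:
        env_effects[:] = 0.0
    env_means = rng.normal(10.0, 2.0, size=cfg.n_environments)
    return TraitModel(qtl, main, env_effects, env_means)


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    trait: TraitModel,
    cfg: SimConfig,
    seed: int | None = None,
    trait_name: str = "trait",
) -> PhenotypeTable:
    """Full RCB phenotypes: every line in every block of every environment.

    Residual SD per environment is chosen so that the target heritability in
    ``cfg.h2_per_env`` is met either on a genotype-mean basis over
    ``n_blocks`` replicates (``h2_basis='line_mean'``, the default, matching
    the H2 = S_G2/(S_G2 + S_e2/n) estimator) or on a single-plot basis.
    """
    if trait.qtl_indices.max() >= genotypes.n_markers:
        raise ValueError("trait QTL outside genotype marker range")
    rng = np.random.default_rng((cfg.seed + 202) if seed is None else seed)
    envs = cfg.environments
    n_lines = genotypes.n_lines
    dose = genotypes.dosage[:, trait.qtl_indices]
    if np.isnan(dose).any():
        raise ValueError("phenotype simulation requires complete genotype data")
    g_values = dose @ trait.main_effects
    gei = dose @ trait.env_effects.T  # (lines, env)

    records = []
    pops = genotypes.population_labels
    for j, env in enumerate(envs):
        h2 = cfg.h2_per_env[env]
        total_g = g_values + gei[:, j]
        var_g = total_g.var()
        s_e2 = var_g * (1.0 - h2) / h2
        if cfg.h2_basis == "line_mean":
            s_e2 *= cfg.n_blocks
        sd_e = np.sqrt(s_e2)
        for b in range(cfg.n_blocks):
            block_effect = rng.normal(0.0, cfg.block_sd)
            noise = rng.normal(0.0, sd_e, size=n_lines)
            values = trait.env_means[j] + total_g + block_effect + noise
            for i in range(n_lines):
                records.append(
                    (genotypes.line_ids[i], pops[i], env, f"b{b + 1}", values[i])
                )
    df = pd.DataFrame.from_records(
        records, columns=["line", "population", "environment", "block", trait_name]
    )
    return PhenotypeTable(df)


def mask_missing(genotypes: GenotypeMatrix, missing_rate: float, seed: int = 0) -> GenotypeMatrix:
    """Set entries to missing independently with probability ``missing_rate``."""
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must lie in [0, 1)")
    out = genotypes.copy()
    if missing_rate == 0.0:
        return out
    rng = np.random.default_rng(seed)
    mask = rng.random(out.dosage.shape) < missing_rate
    out.dosage[mask] = np.nan
    return out


def simulate_study(cfg: SimConfig, trait_names: tuple[str, ...] = ("trait",)):
    """Convenience driver: parents -> RIL populations -> phenotypes.

    Returns ``(genotypes, phenotypes, trait_models)`` where phenotypes is a
    single long table with one column per trait and genotypes already carry
    per-cross population labels (``popAxB`` style).
    """
    parents = simulate_parents(cfg)
    blocks, line_ids, populations = [], [], {}
    for c, (a, b) in enumerate(cfg.crosses):
        label = f"pop{a + 1}x{b + 1}"
        dosage = simulate_ril_population(
            parents.dosage[a], parents.dosage[b],
            cfg.lines_per_pop, cfg.inbreeding_generations,
            seed=cfg.seed * 1000 + 7 * c + 1,
        )
        ids = [f"{label}_L{i + 1}" for i in range(cfg.lines_per_pop)]
        blocks.append(dosage)
        line_ids.extend(ids)
        populations.update({l: label for l in ids})
    genotypes = GenotypeMatrix(
        line_ids, list(parents.marker_ids), np.vstack(blocks), populations
    )

    tables, models = [], {}
    for t, name in enumerate(trait_names):
        trait = sample_trait_model(cfg, genotypes, seed=cfg.seed * 1000 + 401 + t)
        ph = simulate_phenotypes(genotypes, trait, cfg,
                                 seed=cfg.seed * 1000 + 501 + t, trait_name=name)
        tables.append(ph.data.set_index(["line", "population", "environment", "block"]))
        models[name] = trait
    merged = pd.concat(tables, axis=1).reset_index()
    phenotypes = PhenotypeTable(merged)

    if cfg.missing_rate > 0:
        genotypes = mask_missing(genotypes, cfg.missing_rate, seed=cfg.seed * 1000 + 601)
    return genotypes, phenotypes, models
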