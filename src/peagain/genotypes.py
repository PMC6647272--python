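"""Marker data handling: I/O, QC filters, imputation, kinship and Nei distance.

The central container is :class:`GenotypeMatrix`, a lines x markers matrix of
alt-allele dosages in {0, 1, 2} with ``NaN`` marking missing calls, plus a
line -> population map. Filtering follows the fixed order missing-rate first,
then MAF; imputation comes last.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "KinshipMatrix",
    "read_genotypes",
    "write_vcf",
    "write_csv",
    "filter_missing_rate",
    "filter_maf",
    "impute_missing",
    "compute_kinship",
    "allele_frequencies",
    "nei_distance",
]


class GenotypeParseError(ValueError):
    """Raised when a genotype file cannot be interpreted."""


class ImputationError(ValueError):
    """Raised when a marker cannot be imputed (e.g. all calls missing)."""


@dataclass
class GenotypeMatrix:
    """Lines x markers dosage matrix with population labels.

    Parameters
    ----------
    line_ids : list of str
        Unique line identifiers (rows).
    marker_ids : list of str
        Unique marker identifiers (columns).
    dosage : ndarray of float, shape (n_lines, n_markers)
        Alt-allele dosages in {0, 1, 2}; ``NaN`` encodes a missing call.
    populations : dict
        Maps every line id to a population label.
    """

    line_ids: list[str]
    marker_ids: list[str]
    dosage: np.ndarray
    populations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.marker_ids)} markers"
            )
        if len(set(self.line_ids)) != len(self.line_ids):
            raise ValueError("duplicate line ids")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("duplicate marker ids")
        if not self.populations:
            self.populations = {l: "pop1" for l in self.line_ids}
        missing_pop = [l for l in self.line_ids if l not in self.populations]
        if missing_pop:
            raise ValueError(f"lines without population label: {missing_pop[:5]}")
        valid = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not valid.all():
            bad = np.unique(self.dosage[~valid])
            raise ValueError(f"dosage values outside {{0,1,2,NaN}}: {bad[:5]}")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def population_labels(self) -> np.ndarray:
        """Population label per line, in row order."""
        return np.array([self.populations[l] for l in self.line_ids])

    def has_missing(self) -> bool:
        return bool(np.isnan(self.dosage).any())

    def missing_rate_per_marker(self) -> np.ndarray:
        return np.isnan(self.dosage).mean(axis=0)

    def maf(self) -> np.ndarray:
        """Minor allele frequency per marker, from non-missing calls only."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p = np.nanmean(self.dosage, axis=0) / 2.0
        return np.minimum(p, 1.0 - p)

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            line_ids=list(self.line_ids),
            marker_ids=[self.marker_ids[i] for i in keep],
            dosage=self.dosage[:, keep].copy(),
            populations=dict(self.populations),
        )

    def subset_lines(self, line_ids: list[str]) -> "GenotypeMatrix":
        idx = {l: i for i, l in enumerate(self.line_ids)}
        rows = [idx[l] for l in line_ids]
        return GenotypeMatrix(
            line_ids=list(line_ids),
            marker_ids=list(self.marker_ids),
            dosage=self.dosage[rows, :].copy(),
            populations={l: self.populations[l] for l in line_ids},
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.line_ids),
            list(self.marker_ids),
            self.dosage.copy(),
            dict(self.populations),
        )


@dataclass
class KinshipMatrix:
    """Symmetric lines x lines genomic relationship matrix."""

    line_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.line_ids)
        if self.values.shape != (n, n):
            raise ValueError("kinship dimension does not match line count")
        if np.abs(self.values - self.values.T).max() > 1e-8:
            raise ValueError("kinship matrix not symmetric")
        if np.any(np.diag(self.values) <= 0):
            raise ValueError("kinship diagonal must be strictly positive")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_genotypes(path, format: str = "vcf", populations=None) -> GenotypeMatrix:
    """Read a genotype matrix from a VCF or CSV file.

    VCF: biallelic SNPs only; GT field mapped to alt-allele dosage
    (0/0 -> 0, 0/1 -> 1, 1/1 -> 2, ./. -> missing). Multi-allelic records
    are rejected with the offending marker named. CSV: first column line id,
    header row marker ids, missing encoded as ``NA`` (or empty).

    Parameters
    ----------
    populations : dict or None
        Optional line -> population map (VCF carries no such metadata).
    """
    if format == "vcf":
        return _read_vcf(path, populations)
    if format == "csv":
        return _read_csv(path, populations)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path, populations) -> GenotypeMatrix:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad input
        raise GenotypeParseError(f"cannot parse VCF {path}: {exc}") from exc
    line_ids = list(vcf.samples)
    if not line_ids:
        raise GenotypeParseError("VCF has no sample columns")
    marker_ids: list[str] = []
    columns: list[np.ndarray] = []
    for record_no, variant in enumerate(vcf, start=1):
        marker = variant.ID or f"{variant.CHROM}:{variant.POS}"
        if len(variant.ALT) != 1:
            raise GenotypeParseError(
                f"record {record_no}: multi-allelic marker {marker!r} not supported"
            )
        col = np.empty(len(line_ids))
        for i, gt in enumerate(variant.genotypes):
            a, b = gt[0], gt[1]
            col[i] = np.nan if (a < 0 or b < 0) else float(a + b)
        marker_ids.append(marker)
        columns.append(col)
    vcf.close()
    dosage = np.column_stack(columns) if columns else np.empty((len(line_ids), 0))
    return GenotypeMatrix(line_ids, marker_ids, dosage, dict(populations or {}))


def _read_csv(path, populations) -> GenotypeMatrix:
    df = pd.read_csv(path, index_col=0, na_values=["NA"])
    return GenotypeMatrix(
        [str(i) for i in df.index],
        [str(c) for c in df.columns],
        df.to_numpy(dtype=float),
        dict(populations or {}),
    )


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write as minimal VCF v4.2 (unphased GT only, one fake chromosome)."""
    code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(g.line_ids) + "\n")
        for j, marker in enumerate(g.marker_ids):
            gts = "\t".join(
                "./." if np.isnan(v) else code[v] for v in g.dosage[:, j]
            )
            fh.write(f"1\t{j + 1}\t{marker}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


def write_csv(g: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(g.dosage, index=g.line_ids, columns=g.marker_ids)
    df.to_csv(path, na_rep="NA", index_label="line")


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_missing_rate(g: GenotypeMatrix, threshold: float) -> GenotypeMatrix:
    """Drop markers whose per-marker missing fraction exceeds ``threshold``."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    return g.subset_markers(g.missing_rate_per_marker() <= threshold)


def filter_maf(g: GenotypeMatrix, min_maf: float = 0.05) -> GenotypeMatrix:
    """Drop monomorphic markers and markers with MAF strictly below ``min_maf``.

    MAF is computed on observed (non-missing) calls as min(p, 1-p) with
    p = mean(dosage)/2.
    """
    if not 0.0 <= min_maf <= 0.5:
        raise ValueError("min_maf must lie in [0, 0.5]")
    maf = g.maf()
    keep = (maf > 0) & (maf >= min_maf) & ~np.isnan(maf)
    return g.subset_markers(keep)


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------

def _marker_mode(col: np.ndarray) -> float:
    obs = col[~np.isnan(col)]
    values, counts = np.unique(obs, return_counts=True)
    return float(values[np.argmax(counts)])  # ties -> smallest dosage


def impute_missing(g: GenotypeMatrix, method: str = "mode", seed: int = 0) -> GenotypeMatrix:
    """Fill missing dosages; non-missing entries are never touched.

    ``mode`` replaces by the per-marker most frequent dosage,
    ``marker_mean_rounded`` by the per-marker mean rounded to {0,1,2}, and
    ``iterative_forest`` runs a missForest-style loop (random-forest
    classifiers on categorical dosages, 100 trees, at most 10 iterations).
    The forest path is markedly slower and therefore not the default.
    """
    missing = np.isnan(g.dosage)
    if not missing.any():
        return g.copy()
    all_missing = missing.all(axis=0)
    if all_missing.any():
        j = int(np.flatnonzero(all_missing)[0])
        raise ImputationError(f"marker {g.marker_ids[j]!r} has no observed calls")

    out = g.copy()
    if method == "mode":
        for j in np.flatnonzero(missing.any(axis=0)):
            out.dosage[missing[:, j], j] = _marker_mode(g.dosage[:, j])
    elif method == "marker_mean_rounded":
        means = np.nanmean(g.dosage, axis=0)
        filled = np.clip(np.round(means), 0, 2)
        for j in np.flatnonzero(missing.any(axis=0)):
            out.dosage[missing[:, j], j] = filled[j]
    elif method == "iterative_forest":
        out.dosage = _forest_impute(g.dosage, seed=seed)
    else:
        raise ValueError(f"unknown imputation method {method!r}")
    assert not np.isnan(out.dosage).any()
    return out


def _forest_impute(dosage: np.ndarray, seed: int, n_trees: int = 100,
                   max_iter: int = 10) -> np.ndarray:
    from sklearn.ensemble import RandomForestClassifier

    missing = np.isnan(dosage)
    filled = dosage.copy()
    # warm start from per-marker modes
    for j in np.flatnonzero(missing.any(axis=0)):
        filled[missing[:, j], j] = _marker_mode(dosage[:, j])

    targets = np.flatnonzero(missing.any(axis=0))
    # fewest-missing markers first, as missForest does
    targets = targets[np.argsort(missing[:, targets].sum(axis=0), kind="stable")]
    prev = filled[missing].copy()
    rng = np.random.default_rng(seed)
    for _ in range(max_iter):
        for j in targets:
            rows_obs = ~missing[:, j]
            other = np.delete(filled, j, axis=1)
            y_obs = filled[rows_obs, j].astype(int)
            if np.unique(y_obs).size < 2:
                filled[missing[:, j], j] = float(y_obs[0])
                continue
            clf = RandomForestClassifier(
                n_estimators=n_trees,
                random_state=int(rng.integers(2**31 - 1)),
                n_jobs=1,
            )
            clf.fit(other[rows_obs], y_obs)
            filled[missing[:, j], j] = clf.predict(other[missing[:, j]]).astype(float)
        changed = (filled[missing] != prev).mean() if missing.any() else 0.0
        if changed == 0.0:
            break
        prev = filled[missing].copy()
    return filled


# ---------------------------------------------------------------------------
# Kinship & distance
# ---------------------------------------------------------------------------

def compute_kinship(g: GenotypeMatrix) -> KinshipMatrix:
    """VanRaden-style genomic relationship matrix K = Z Z' / c.

    Z is the column-centered dosage matrix and c = 2 * sum_j p_j (1 - p_j)
    with p_j the observed alt-allele frequency. Requires complete data.
    """
    if g.has_missing():
        raise ValueError("kinship requires complete (imputed) genotype data")
    p = g.dosage.mean(axis=0) / 2.0
    z = g.dosage - 2.0 * p
    c = 2.0 * np.sum(p * (1.0 - p))
    if c <= 0:
        raise ValueError("all markers monomorphic; kinship undefined")
    k = z @ z.T / c
    k = (k + k.T) / 2.0
    return KinshipMatrix(list(g.line_ids), k)


def allele_frequencies(g: GenotypeMatrix, lines: list[str] | None = None) -> np.ndarray:
    """Per-marker alt-allele frequency over the given lines (default: all)."""
    sub = g if lines is None else g.subset_lines(lines)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(sub.dosage, axis=0) / 2.0


def nei_distance(freq_a: np.ndarray, freq_b: np.ndarray) -> float:
    """Nei's standard genetic distance between two biallelic frequency vectors.

    D = -ln( J_ab / sqrt(J_a J_b) ) with the homozygosity terms averaged
    over loci. Identical frequencies give 0; J_ab = 0 gives ``inf``.
    """
    a = np.asarray(freq_a, dtype=float)
    b = np.asarray(freq_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("frequency vectors must cover the same marker set")
    if np.any((a < 0) | (a > 1) | (b < 0) | (b > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    j_a = np.mean(a**2 + (1 - a) ** 2)
    j_b = np.mean(b**2 + (1 - b) ** 2)
    j_ab = np.mean(a * b + (1 - a) * (1 - b))
    if j_ab <= 0:
        return float("inf")
    return float(-np.log(j_ab / np.sqrt(j_a * j_b)))
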