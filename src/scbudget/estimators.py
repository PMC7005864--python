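"""Plug-in and empirical-Bayes (EB) estimators under the Poisson noise model.

The observation model is Y_cg | X_cg ~ Poisson(s_c * X_cg) with per-cell scale
s_c = gamma_c * n_reads. The plug-in estimators treat Y_cg / s_c as if it were
the latent relative expression X_cg; the EB estimators remove the Poisson
sampling contribution exactly:

* k-th moment: the falling factorial Y(Y-1)...(Y-k+1) / s^k is unbiased for
  X^k because E[Y(Y-1)...(Y-k+1) | X] = (sX)^k.
* variance: var_eb = M2_eb - M1^2, i.e. the plug-in variance minus the mean,
  removing the E[X]/s Poisson inflation.
* inactive probability p0(kappa) = E[exp(-kappa X)]: the coefficient
  a_y = (1 - kappa/s)^y satisfies E[a_Y | X] = exp(-kappa X) (the Poisson
  probability generating function), making the EB estimator exactly unbiased.

All moment sums use 1/n_cells normalization (population moments) over the
usable cells, matching the estimator definitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .counts import CountMatrix, SizeFactors

__all__ = [
    "MomentEstimates", "GeneStatistics", "GammaFit", "CorrelationEstimate",
    "InactiveProbEstimate", "moments", "gene_statistics", "fit_gamma_mom",
    "correlation", "inactive_probability", "pairwise_inactive_probability",
]


# ---------------------------------------------------------------------------
# Array kernels (shared with the design sweeps, which bypass the containers)
# ---------------------------------------------------------------------------

def moments_arrays(y: np.ndarray, s: np.ndarray, k_max: int) -> tuple[np.ndarray, np.ndarray]:
    """Plug-in and EB moments for a dense (cells x genes) count array.

    Returns two (k_max, n_genes) arrays: plugin[k-1] = mean((Y/s)^k) and
    eb[k-1] = mean(falling_factorial(Y, k) / s^k).
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    s = np.asarray(s, dtype=float)
    if (s <= 0).any():
        raise ValueError("all Poisson scales must be positive")
    n_genes = y.shape[1]
    plugin = np.empty((k_max, n_genes))
    eb = np.empty((k_max, n_genes))
    s_col = s[:, None]
    power = y.copy()       # Y^k accumulator
    falling = y.copy()     # Y(Y-1)...(Y-k+1) accumulator
    s_pow = s_col.copy()
    for k in range(1, k_max + 1):
        if k > 1:
            power *= y
            falling *= y - (k - 1)
            s_pow *= s_col
        plugin[k - 1] = (power / s_pow).mean(axis=0)
        eb[k - 1] = (falling / s_pow).mean(axis=0)
    return plugin, eb


def variance_arrays(y: np.ndarray, s: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(mean, var_plugin, var_eb) per gene; the fast path for CV sweeps."""
    plugin, eb = moments_arrays(y, s, 2)
    mean = plugin[0]
    return mean, plugin[1] - mean**2, eb[1] - mean**2


def inactive_coeffs(y: np.ndarray, s: np.ndarray, kappa: float) -> np.ndarray:
    """EB coefficients a_y = (1 - kappa/s_c)^y, exact and possibly alternating."""
    base = 1.0 - kappa / np.asarray(s, dtype=float)
    y = np.asarray(y)
    if y.ndim == 1:
        y = y[:, None]
    # Integer exponents keep negative bases well-defined.
    return np.power(base[:, None], y.astype(np.int64))


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class MomentEstimates:
    """Per-gene moment estimates M_k on the relative-expression scale.

    ``plugin`` and ``eb`` are (k_max, n_genes); row k-1 holds the k-th moment.
    The first rows are identical by construction. EB moments of order >= 2 may
    be negative (noise of the correction); ``negative_eb`` flags such genes.
    """

    gene_ids: list[str]
    plugin: np.ndarray
    eb: np.ndarray
    n_cells: int

    @property
    def k_max(self) -> int:
        return self.plugin.shape[0]

    @property
    def negative_eb(self) -> np.ndarray:
        return (self.eb < 0).any(axis=0)

    def moment(self, k: int, variant: str = "eb") -> np.ndarray:
        arr = {"plugin": self.plugin, "eb": self.eb}[variant]
        return arr[k - 1]


@dataclass
class GeneStatistics:
    """Mean/variance/CV/Fano per gene, plug-in and EB variants.

    ``valid_eb`` is False exactly where the EB variance is non-positive (the
    plug-in variance did not exceed the plug-in mean); CV and Fano are NaN
    there for the EB variant, and NaN wherever the mean is zero.
    """

    gene_ids: list[str]
    n_cells: int
    mean: np.ndarray
    var_plugin: np.ndarray
    var_eb: np.ndarray
    cv_plugin: np.ndarray
    cv_eb: np.ndarray
    fano_plugin: np.ndarray
    fano_eb: np.ndarray
    valid_eb: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "gene": self.gene_ids,
            "n_cells_used": self.n_cells,
            "mean": self.mean,
            "var_plugin": self.var_plugin,
            "var_eb": self.var_eb,
            "cv_plugin": self.cv_plugin,
            "cv_eb": self.cv_eb,
            "fano_plugin": self.fano_plugin,
            "fano_eb": self.fano_eb,
            "valid_eb": self.valid_eb,
        }).set_index("gene")

    def write_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t")


@dataclass
class GammaFit:
    """Method-of-moments gamma parameters: r = mean^2/var_eb, theta = var_eb/mean."""

    gene_ids: list[str]
    shape: np.ndarray
    scale: np.ndarray
    valid: np.ndarray


@dataclass
class CorrelationEstimate:
    """Gene-pair moments, covariance and Pearson correlation (both variants).

    The first pairwise moment M11 is identical for both variants (distinct
    genes are conditionally independent Poissons, so E[Y1 Y2 / s^2 | X] =
    X1 X2 exactly). The variants differ only through the variances in the
    Pearson denominator. EB Pearson values are clamped to [-1, 1]; the raw
    values are retained in ``pearson_eb_raw``.
    """

    gene_ids: list[str]
    m11: np.ndarray
    cov_plugin: np.ndarray
    cov_eb: np.ndarray
    pearson_plugin: np.ndarray
    pearson_eb: np.ndarray
    pearson_eb_raw: np.ndarray
    valid: np.ndarray
    n_cells: int

    def to_long(self) -> pd.DataFrame:
        g = self.gene_ids
        rows = []
        for i in range(len(g)):
            for j in range(i + 1, len(g)):
                rows.append((g[i], g[j], self.pearson_plugin[i, j],
                             self.pearson_eb[i, j], bool(self.valid[i, j])))
        return pd.DataFrame(rows, columns=["gene1", "gene2", "pearson_plugin",
                                           "pearson_eb", "valid"])


@dataclass
class InactiveProbEstimate:
    """p0(kappa) = E[exp(-kappa X)] estimates per gene or gene pair.

    EB values are clamped to [0, 1] with the raw value retained.
    ``n_unstable_cells`` counts cells with |1 - kappa/s_c| > 1, where the EB
    coefficients alternate in sign and can be numerically explosive.
    """

    index: list
    kappa: float
    p0_plugin: np.ndarray
    p0_eb: np.ndarray
    p0_eb_raw: np.ndarray
    n_unstable_cells: int


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def moments(counts: CountMatrix, sf: SizeFactors, k_max: int = 2) -> MomentEstimates:
    """Estimate per-gene moments M_k = E[X^k], plug-in and EB variants."""
    if len(sf.gamma) != counts.n_cells:
        raise ValueError("size factors were computed on a different cell set")
    y = counts.values[sf.usable]
    plugin, eb = moments_arrays(y, sf.scales(), k_max)
    return MomentEstimates(gene_ids=list(counts.gene_ids), plugin=plugin,
                           eb=eb, n_cells=int(sf.n_usable))


def gene_statistics(m: MomentEstimates) -> GeneStatistics:
    """Derive mean, variance, CV and Fano factor from first two moments.

    Quantities are on the relative-expression scale: variance = M2 - M1^2,
    cv = sqrt(variance)/mean, fano = variance/mean.
    """
    if m.k_max < 2:
        raise ValueError("gene statistics require moments up to k = 2")
    mean = m.plugin[0]
    var_plugin = m.plugin[1] - mean**2
    var_eb = m.eb[1] - mean**2
    valid_eb = var_eb > 0
    pos_mean = mean > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        cv_plugin = np.where(pos_mean, np.sqrt(np.maximum(var_plugin, 0.0)) / mean, np.nan)
        fano_plugin = np.where(pos_mean, var_plugin / mean, np.nan)
        cv_eb = np.where(valid_eb & pos_mean, np.sqrt(np.maximum(var_eb, 0.0)) / mean, np.nan)
        fano_eb = np.where(valid_eb & pos_mean, var_eb / mean, np.nan)
    return GeneStatistics(gene_ids=list(m.gene_ids), n_cells=m.n_cells,
                          mean=mean, var_plugin=var_plugin, var_eb=var_eb,
                          cv_plugin=cv_plugin, cv_eb=cv_eb,
                          fano_plugin=fano_plugin, fano_eb=fano_eb,
                          valid_eb=valid_eb)


def fit_gamma_mom(stats: GeneStatistics) -> GammaFit:
    """Method-of-moments gamma fit on EB-corrected moments (valid genes only)."""
    valid = stats.valid_eb & (stats.mean > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        shape = np.where(valid, stats.mean**2 / stats.var_eb, np.nan)
        scale = np.where(valid, stats.var_eb / stats.mean, np.nan)
    return GammaFit(gene_ids=list(stats.gene_ids), shape=shape, scale=scale,
                    valid=valid)


def correlation(counts: CountMatrix, sf: SizeFactors,
                genes: list[str] | None = None) -> CorrelationEstimate:
    """Noise-corrected gene-gene covariance and Pearson correlation.

    Off-diagonal covariances are M11 - M1_g1 * M1_g2 with
    M11 = mean(Y_g1 Y_g2 / s^2), shared by both variants; the diagonal is the
    variant's variance. Pearson denominators use the variant's variances, so
    the plug-in correlation is attenuated by the Poisson noise while the EB
    correlation is not. Pairs involving a gene with non-positive EB variance
    are marked invalid.
    """
    cm = counts if genes is None else counts.subset_genes(genes)
    if sf.n_usable < 2:
        raise ValueError("correlation requires at least 2 usable cells")
    y = cm.values[sf.usable].astype(float)
    s = sf.scales()
    n = y.shape[0]
    w = y / s[:, None]
    m11 = (w.T @ w) / n
    stats = gene_statistics(moments(cm, sf, k_max=2))
    m1 = stats.mean
    cov = m11 - np.outer(m1, m1)
    cov_plugin = cov.copy()
    np.fill_diagonal(cov_plugin, stats.var_plugin)
    cov_eb = cov.copy()
    np.fill_diagonal(cov_eb, stats.var_eb)

    with np.errstate(invalid="ignore", divide="ignore"):
        denom_p = np.sqrt(np.outer(stats.var_plugin, stats.var_plugin))
        pearson_plugin = np.where(denom_p > 0, cov_plugin / denom_p, np.nan)
        var_eb_pos = np.where(stats.valid_eb, stats.var_eb, np.nan)
        denom_e = np.sqrt(np.outer(var_eb_pos, var_eb_pos))
        pearson_eb_raw = cov_eb / denom_e
    valid = np.outer(stats.valid_eb, stats.valid_eb)
    np.fill_diagonal(pearson_eb_raw, np.where(stats.valid_eb, 1.0, np.nan))
    pearson_eb = np.clip(pearson_eb_raw, -1.0, 1.0)
    return CorrelationEstimate(gene_ids=list(cm.gene_ids), m11=m11,
                               cov_plugin=cov_plugin, cov_eb=cov_eb,
                               pearson_plugin=pearson_plugin,
                               pearson_eb=pearson_eb,
                               pearson_eb_raw=pearson_eb_raw,
                               valid=valid, n_cells=n)


def inactive_probability(counts: CountMatrix, sf: SizeFactors, kappa: float,
                         clamp: float | None = None) -> InactiveProbEstimate:
    """Estimate p0(kappa) = E[exp(-kappa X_g)] per gene.

    Plug-in: the observed zero fraction (exact only when kappa = s_c for every
    cell). EB: mean of a_y = (1 - kappa/s_c)^y, the unbiased estimator under
    Poisson noise. ``clamp``, if given, clips the coefficients to [-clamp,
    clamp] — a robustness opt-in for kappa > s_c where they alternate in sign.
    """
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    y = counts.values[sf.usable]
    s = sf.scales()
    n_unstable = int((np.abs(1.0 - kappa / s) > 1.0).sum())
    if n_unstable:
        warnings.warn(
            f"kappa={kappa} exceeds 2*s_c for {n_unstable} cells; EB "
            "inactive-probability coefficients alternate and may be unstable",
            RuntimeWarning, stacklevel=2)
    a = inactive_coeffs(y, s, kappa)
    if clamp is not None:
        a = np.clip(a, -clamp, clamp)
    p0_plugin = (y == 0).mean(axis=0)
    p0_eb_raw = a.mean(axis=0)
    return InactiveProbEstimate(index=list(counts.gene_ids), kappa=kappa,
                                p0_plugin=p0_plugin,
                                p0_eb=np.clip(p0_eb_raw, 0.0, 1.0),
                                p0_eb_raw=p0_eb_raw,
                                n_unstable_cells=n_unstable)


def pairwise_inactive_probability(counts: CountMatrix, sf: SizeFactors,
                                  kappa: float, pairs: list[tuple[str, str]],
                                  clamp: float | None = None) -> InactiveProbEstimate:
    """Estimate p0_{g1,g2}(kappa) = E[exp(-kappa (X_g1 + X_g2))] per pair.

    EB uses the product a_{Y_g1} * a_{Y_g2}, unbiased because the two counts
    are conditionally independent Poissons given the latent expressions.
    """
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    for g1, g2 in pairs:
        if g1 == g2:
            raise ValueError(f"pair ({g1!r}, {g2!r}) duplicates a gene")
    all_genes = sorted({g for pair in pairs for g in pair})
    idx = {g: i for i, g in enumerate(all_genes)}
    cm = counts.subset_genes(all_genes)
    y = cm.values[sf.usable]
    s = sf.scales()
    n_unstable = int((np.abs(1.0 - kappa / s) > 1.0).sum())
    a = inactive_coeffs(y, s, kappa)
    if clamp is not None:
        a = np.clip(a, -clamp, clamp)
    p0_plugin = np.empty(len(pairs))
    p0_eb_raw = np.empty(len(pairs))
    for k, (g1, g2) in enumerate(pairs):
        i, j = idx[g1], idx[g2]
        p0_plugin[k] = ((y[:, i] == 0) & (y[:, j] == 0)).mean()
        p0_eb_raw[k] = (a[:, i] * a[:, j]).mean()
    return InactiveProbEstimate(index=list(pairs), kappa=kappa,
                                p0_plugin=p0_plugin,
                                p0_eb=np.clip(p0_eb_raw, 0.0, 1.0),
                                p0_eb_raw=p0_eb_raw,
                                n_unstable_cells=n_unstable)
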