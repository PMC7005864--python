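"""Nonparametric recovery of a gene's latent expression distribution.

The marginal distribution P_X of a gene's relative expression is estimated by
maximizing the mixture likelihood sum_c log sum_j w_j Poi(y_c; s_c x_j) over
the weights w on a fixed support grid. The grid is geometric over the
identifiable range with an explicit atom at zero (inactive mass); the weights
are fit by EM, which for a fixed grid is a convex problem with a monotone
log-likelihood. Support-point optimization is deliberately not attempted:
the fixed grid keeps the fit deterministic and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

from .counts import SizeFactors

__all__ = ["DiscretePrior", "DeconvolutionSettings", "deconvolve_gene",
           "prior_tv_distance", "project_prior", "predictive_pmf"]


@dataclass
class DiscretePrior:
    """A discrete distribution on a non-negative expression grid."""

    support: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.support = np.asarray(self.support, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.support.shape != self.weights.shape or self.support.ndim != 1:
            raise ValueError("support and weights must be matching 1-D arrays")
        if (self.support < 0).any():
            raise ValueError("support must be non-negative")
        if (np.diff(self.support) <= 0).any():
            raise ValueError("support must be strictly increasing")
        if (self.weights < -1e-12).any():
            raise ValueError("weights must be non-negative")
        self.weights = np.maximum(self.weights, 0.0)
        total = self.weights.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"weights sum to {total!r}, expected 1")

    def mean(self) -> float:
        return float(self.support @ self.weights)

    def moment(self, k: int) -> float:
        return float((self.support**k) @ self.weights)

    def exp_moment(self, kappa: float) -> float:
        """E[exp(-kappa X)], the inactive probability at scale kappa."""
        return float(np.exp(-kappa * self.support) @ self.weights)

    def write_tsv(self, path: str, **metadata) -> None:
        with open(path, "w") as fh:
            for key, value in metadata.items():
                fh.write(f"# {key}: {value}\n")
            fh.write("support\tweight\n")
            for x, w in zip(self.support, self.weights):
                fh.write(f"{x:.12g}\t{w:.12g}\n")


@dataclass
class DeconvolutionSettings:
    grid_size: int = 100
    grid_max_multiplier: float = 2.0
    tol: float = 1e-6
    max_iter: int = 2000

    def __post_init__(self) -> None:
        if self.grid_size < 2:
            raise ValueError("grid_size must be >= 2")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class DeconvolutionResult:
    prior: DiscretePrior
    log_likelihood: float
    n_iter: int
    converged: bool
    degenerate: bool = False
    log_likelihood_path: np.ndarray = field(default_factory=lambda: np.empty(0))


def _support_grid(y: np.ndarray, s: np.ndarray, settings: DeconvolutionSettings) -> np.ndarray:
    scaled = y / s
    positive = scaled[y > 0]
    lo = 0.1 * positive.min()
    hi = settings.grid_max_multiplier * scaled.max()
    grid = np.geomspace(lo, hi, settings.grid_size)
    return np.concatenate([[0.0], grid])


def deconvolve_gene(counts_g: np.ndarray, sf: SizeFactors,
                    settings: DeconvolutionSettings | None = None) -> DeconvolutionResult:
    """Grid-constrained maximum-likelihood deconvolution of one gene by EM.

    ``counts_g`` holds the gene's per-cell UMI counts (all cells; unusable
    cells are dropped via the size factors). E-step responsibilities are
    proportional to w_j Poi(y_c; s_c x_j); the M-step sets each weight to the
    mean responsibility. Iteration stops when the total log-likelihood gain
    falls below ``tol``; the log-likelihood is asserted non-decreasing.
    """
    settings = settings or DeconvolutionSettings()
    y_all = np.asarray(counts_g)
    if y_all.ndim != 1:
        raise ValueError("deconvolve_gene expects a single gene's count vector")
    if len(y_all) != len(sf.gamma):
        raise ValueError("size factors were computed on a different cell set")
    y = y_all[sf.usable].astype(np.int64)
    s = sf.scales()
    if (y == 0).all():
        prior = DiscretePrior(np.array([0.0]), np.array([1.0]))
        return DeconvolutionResult(prior=prior, log_likelihood=0.0, n_iter=0,
                                   converged=True, degenerate=True)

    grid = _support_grid(y, s, settings)
    # Collapse duplicate (y, s) observations; EM cost scales with unique pairs.
    pairs = np.stack([y.astype(float), s], axis=1)
    uniq, counts_per = np.unique(pairs, axis=0, return_counts=True)
    yu, su = uniq[:, 0], uniq[:, 1]
    mult = counts_per.astype(float)
    n = float(len(y))

    # log Poi(y; s*x) for every unique observation x grid point
    lam = su[:, None] * grid[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        log_pmf = yu[:, None] * np.log(lam) - lam - gammaln(yu + 1.0)[:, None]
    # x = 0: pmf is the indicator of y == 0
    log_pmf[:, grid == 0.0] = np.where(yu[:, None] == 0, 0.0, -np.inf)

    log_w = np.full(len(grid), -np.log(len(grid)))
    ll_prev = -np.inf
    ll_path = []
    converged = False
    for it in range(1, settings.max_iter + 1):
        joint = log_pmf + log_w[None, :]
        per_obs = logsumexp(joint, axis=1)
        ll = float(mult @ per_obs)
        if not np.isfinite(ll):
            raise FloatingPointError("non-finite log-likelihood in deconvolution")
        if ll < ll_prev - 1e-8 * max(1.0, abs(ll_prev)):
            raise AssertionError(
                f"EM log-likelihood decreased: {ll_prev} -> {ll}")
        ll_path.append(ll)
        if ll - ll_prev < settings.tol and it > 1:
            converged = True
            break
        ll_prev = ll
        resp = np.exp(joint - per_obs[:, None])
        w = (mult @ resp) / n
        with np.errstate(divide="ignore"):
            log_w = np.log(w)
    w = np.exp(log_w)
    prior = DiscretePrior(grid, w / w.sum())
    return DeconvolutionResult(prior=prior, log_likelihood=ll, n_iter=len(ll_path),
                               converged=converged, degenerate=False,
                               log_likelihood_path=np.array(ll_path))


def prior_tv_distance(p: DiscretePrior, q: DiscretePrior) -> float:
    """Total-variation distance after aligning the two supports exactly.

    Supports are merged on their union grid (atoms match only at identical
    x values), so two disjoint point masses are at distance 1.
    """
    union = np.union1d(p.support, q.support)
    wp = np.zeros(len(union))
    wq = np.zeros(len(union))
    wp[np.searchsorted(union, p.support)] = p.weights
    wq[np.searchsorted(union, q.support)] = q.weights
    return float(0.5 * np.abs(wp - wq).sum())


def project_prior(p: DiscretePrior, support: np.ndarray) -> DiscretePrior:
    """Project a prior onto a coarser support by nearest-point assignment.

    Each atom's mass moves to the nearest target support point (ties toward
    the smaller point). Used to compare a grid-fitted prior against a
    few-atom ground truth.
    """
    support = np.asarray(support, dtype=float)
    order = np.argsort(support)
    target = support[order]
    weights = np.zeros(len(target))
    for x, w in zip(p.support, p.weights):
        weights[int(np.argmin(np.abs(target - x)))] += w
    return DiscretePrior(target, weights)


def predictive_pmf(prior: DiscretePrior, s: float, tail_mass: float = 1e-12) -> np.ndarray:
    """Mixture pmf m(y) = sum_j w_j Poi(y; s x_j), truncated at tail mass.

    Returns the pmf over y = 0, 1, ..., Y where the remaining tail mass is
    below ``tail_mass``. Used for goodness-of-fit checks and for comparing a
    recovered distribution against an empirical count distribution.
    """
    if s <= 0:
        raise ValueError("depth s must be positive")
    from scipy.stats import poisson

    lam = s * prior.support
    y_max = int(poisson.isf(tail_mass, lam.max()) + 1) if lam.max() > 0 else 0
    ys = np.arange(y_max + 1)
    pmf = (poisson.pmf(ys[:, None], lam[None, :]) @ prior.weights)
    return pmf
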