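"""Ground-truth generators for the gamma/general-Poisson hierarchical model.

Every generator draws per-cell latent expressions X_cg from a stated prior,
per-cell size factors gamma_c (normalized to mean 1 after sampling), and
observed counts Y_cg ~ Poisson(gamma_c * depth * X_cg). The ``depth``
parameter is therefore the mean reads per cell per gene for unit-mean priors.
Each prior exposes exact closed-form functionals (moments, CV, Fano,
correlation, inactive probabilities), so estimators can be scored against
analytic truth rather than a simulated proxy.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .counts import CountMatrix, write_counts
from .deconv import DiscretePrior

__all__ = [
    "GammaPrior", "PointPrior", "TwoPointPrior", "DiscretePriorSpec",
    "CorrelatedGammaPrior", "GeneratorSpec", "TruthRecord",
    "sample_counts", "truth_functionals", "fixture_suite",
]


# ---------------------------------------------------------------------------
# Prior specifications (each spans one or more genes)
# ---------------------------------------------------------------------------

class _PriorBase:
    n_genes = 1

    def moment(self, k: int) -> float:
        raise NotImplementedError

    def mean(self) -> float:
        return self.moment(1)

    def variance(self) -> float:
        return self.moment(2) - self.moment(1) ** 2

    def cv(self) -> float:
        m = self.mean()
        return float(np.sqrt(self.variance()) / m) if m > 0 else np.nan

    def fano(self) -> float:
        m = self.mean()
        return self.variance() / m if m > 0 else np.nan

    def p0(self, kappa: float) -> float:
        """E[exp(-kappa X)]."""
        raise NotImplementedError

    def sample(self, rng: np.random.Generator, n_cells: int) -> np.ndarray:
        """(n_cells, n_genes) latent expression draws."""
        raise NotImplementedError

    def as_discrete(self) -> DiscretePrior | None:
        return None


@dataclass(frozen=True)
class GammaPrior(_PriorBase):
    """X ~ Gamma(shape, scale); counts are negative binomial (overdispersed)."""

    shape: float
    scale: float

    def __post_init__(self):
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("gamma shape and scale must be positive")

    def moment(self, k: int) -> float:
        out = 1.0
        for i in range(k):
            out *= (self.shape + i) * self.scale
        return out

    def p0(self, kappa: float) -> float:
        return float((1.0 + kappa * self.scale) ** (-self.shape))

    def sample(self, rng, n_cells):
        return rng.gamma(self.shape, self.scale, size=(n_cells, 1))


@dataclass(frozen=True)
class PointPrior(_PriorBase):
    """Degenerate prior X = x0: a pure-Poisson gene with zero biological CV."""

    x0: float

    def __post_init__(self):
        if self.x0 < 0:
            raise ValueError("x0 must be non-negative")

    def moment(self, k: int) -> float:
        return self.x0**k

    def p0(self, kappa: float) -> float:
        return float(np.exp(-kappa * self.x0))

    def sample(self, rng, n_cells):
        return np.full((n_cells, 1), self.x0)

    def as_discrete(self):
        return DiscretePrior(np.array([self.x0]), np.array([1.0]))


@dataclass(frozen=True)
class TwoPointPrior(_PriorBase):
    """X in {x_lo, x_hi} with P(X = x_lo) = w_lo: a bimodal (on/off) gene."""

    x_lo: float
    x_hi: float
    w_lo: float = 0.5

    def __post_init__(self):
        if not (0.0 <= self.w_lo <= 1.0):
            raise ValueError("w_lo must be in [0, 1]")
        if not (0.0 <= self.x_lo < self.x_hi):
            raise ValueError("require 0 <= x_lo < x_hi")

    def moment(self, k: int) -> float:
        return self.w_lo * self.x_lo**k + (1 - self.w_lo) * self.x_hi**k

    def p0(self, kappa: float) -> float:
        return float(self.w_lo * np.exp(-kappa * self.x_lo)
                     + (1 - self.w_lo) * np.exp(-kappa * self.x_hi))

    def sample(self, rng, n_cells):
        lo = rng.random(size=(n_cells, 1)) < self.w_lo
        return np.where(lo, self.x_lo, self.x_hi)

    def as_discrete(self):
        return DiscretePrior(np.array([self.x_lo, self.x_hi]),
                             np.array([self.w_lo, 1 - self.w_lo]))


@dataclass(frozen=True)
class DiscretePriorSpec(_PriorBase):
    """A gene whose latent expression follows an arbitrary discrete prior."""

    prior: DiscretePrior

    def moment(self, k: int) -> float:
        return self.prior.moment(k)

    def p0(self, kappa: float) -> float:
        return self.prior.exp_moment(kappa)

    def sample(self, rng, n_cells):
        idx = rng.choice(len(self.prior.support), size=(n_cells, 1),
                         p=self.prior.weights)
        return self.prior.support[idx]

    def as_discrete(self):
        return self.prior


@dataclass(frozen=True)
class CorrelatedGammaPrior(_PriorBase):
    """A block of genes with exact Gamma(shape, scale) marginals and exact
    pairwise Pearson correlation ``rho``.

    Construction: X_g = S + E_g with a shared factor S ~ Gamma(rho * shape,
    scale) and independent E_g ~ Gamma((1 - rho) * shape, scale). Gamma sums
    with a common scale are gamma, so the marginals are exact, and
    Cov(X_g1, X_g2) = Var(S) = rho * shape * scale^2 gives Pearson = rho.
    """

    shape: float
    scale: float
    block_size: int
    rho: float

    def __post_init__(self):
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("gamma shape and scale must be positive")
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError("rho must be in [0, 1]")
        if self.block_size < 2:
            raise ValueError("block_size must be >= 2")

    @property
    def n_genes(self):
        return self.block_size

    def moment(self, k: int) -> float:
        return GammaPrior(self.shape, self.scale).moment(k)

    def p0(self, kappa: float) -> float:
        return GammaPrior(self.shape, self.scale).p0(kappa)

    def pairwise_p0(self, kappa: float) -> float:
        """E[exp(-kappa (X_g1 + X_g2))] for two genes in the block."""
        shared = self.rho * self.shape
        indep = (1.0 - self.rho) * self.shape
        return float((1 + 2 * kappa * self.scale) ** (-shared)
                     * (1 + kappa * self.scale) ** (-2 * indep))

    def sample(self, rng, n_cells):
        shared_shape = self.rho * self.shape
        indep_shape = (1.0 - self.rho) * self.shape
        s = (rng.gamma(shared_shape, self.scale, size=(n_cells, 1))
             if shared_shape > 0 else np.zeros((n_cells, 1)))
        e = (rng.gamma(indep_shape, self.scale, size=(n_cells, self.block_size))
             if indep_shape > 0 else np.zeros((n_cells, self.block_size)))
        return s + e


# ---------------------------------------------------------------------------
# Generator spec + truth record
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratorSpec:
    """Full description of a synthetic experiment.

    ``priors`` is a sequence of prior blocks laid out left to right across the
    gene axis. ``depth`` is n_reads: counts are Poisson(gamma_c * depth * X).
    ``size_factor_sigma`` = 0 gives gamma = 1 for every cell; otherwise gamma
    is lognormal(sigma) renormalized to mean 1 after sampling, so the realized
    mean depth matches ``depth`` in expectation.
    """

    priors: tuple
    depth: float
    size_factor_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.depth < 0:
            raise ValueError("depth must be non-negative")
        if self.size_factor_sigma < 0:
            raise ValueError("size_factor_sigma must be non-negative")
        if not self.priors:
            raise ValueError("at least one prior block is required")
        object.__setattr__(self, "priors", tuple(self.priors))

    @classmethod
    def single(cls, prior, depth: float, n_genes: int = 1, **kwargs) -> "GeneratorSpec":
        """Replicate one single-gene prior across ``n_genes`` i.i.d. genes."""
        return cls(priors=(prior,) * n_genes, depth=depth, **kwargs)

    @property
    def n_genes(self) -> int:
        return sum(p.n_genes for p in self.priors)

    def gene_blocks(self):
        """Yield (prior, gene index slice) pairs in gene order."""
        start = 0
        for p in self.priors:
            yield p, slice(start, start + p.n_genes)
            start += p.n_genes


@dataclass
class TruthRecord:
    """Latent draws and exact functionals accompanying a synthetic matrix."""

    spec: GeneratorSpec
    x: np.ndarray
    gamma: np.ndarray
    m: np.ndarray              # (4, n_genes): exact moments M_1..M_4
    variance: np.ndarray
    cv: np.ndarray
    fano: np.ndarray
    gamma_shape: np.ndarray
    gamma_scale: np.ndarray
    pearson: np.ndarray        # exact correlation matrix (identity off blocks)
    priors: list = field(default_factory=list)  # DiscretePrior or None per gene

    def size_factors(self):
        """The generator's true size factors (gamma, n_reads = depth).

        Estimating size factors from a matrix with only a handful of genes
        conflates biological variation with cell size; synthetic studies
        should score estimators under the true scales, which this returns.
        """
        from .counts import SizeFactors
        return SizeFactors(gamma=self.gamma.copy(), n_reads=self.spec.depth)

    def p0(self, kappa: float) -> np.ndarray:
        out = np.empty(self.m.shape[1])
        for prior, sl in self.spec.gene_blocks():
            out[sl] = prior.p0(kappa)
        return out

    def to_json(self) -> str:
        def clean(arr):
            return [None if not np.isfinite(v) else float(v) for v in np.ravel(arr)]

        payload = {
            "depth": self.spec.depth,
            "n_genes": int(self.m.shape[1]),
            "m1": clean(self.m[0]),
            "m2": clean(self.m[1]),
            "variance": clean(self.variance),
            "cv": clean(self.cv),
            "fano": clean(self.fano),
            "gamma_shape": clean(self.gamma_shape),
            "gamma_scale": clean(self.gamma_scale),
            "pearson": self.pearson.tolist(),
        }
        return json.dumps(payload, indent=1)


def truth_functionals(spec: GeneratorSpec) -> TruthRecord:
    """Exact target values for every gene of a generator spec (no sampling)."""
    n = spec.n_genes
    m = np.empty((4, n))
    pearson = np.eye(n)
    gamma_shape = np.full(n, np.nan)
    gamma_scale = np.full(n, np.nan)
    priors: list = [None] * n
    for prior, sl in spec.gene_blocks():
        for k in range(1, 5):
            m[k - 1, sl] = prior.moment(k)
        if isinstance(prior, (GammaPrior, CorrelatedGammaPrior)):
            gamma_shape[sl] = prior.shape
            gamma_scale[sl] = prior.scale
        if isinstance(prior, CorrelatedGammaPrior):
            idx = np.arange(sl.start, sl.stop)
            for i in idx:
                for j in idx:
                    if i != j:
                        pearson[i, j] = prior.rho
        disc = prior.as_discrete()
        for i in range(sl.start, sl.stop):
            priors[i] = disc
    variance = m[1] - m[0] ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(m[0] > 0, np.sqrt(variance) / m[0], np.nan)
        fano = np.where(m[0] > 0, variance / m[0], np.nan)
    return TruthRecord(spec=spec, x=np.empty((0, n)), gamma=np.empty(0), m=m,
                       variance=variance, cv=cv, fano=fano,
                       gamma_shape=gamma_shape, gamma_scale=gamma_scale,
                       pearson=pearson, priors=priors)


def _sample_size_factors(rng: np.random.Generator, n_cells: int,
                         sigma: float) -> np.ndarray:
    if sigma == 0.0:
        return np.ones(n_cells)
    gamma = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n_cells)
    return gamma / gamma.mean()


def sample_counts(spec: GeneratorSpec, n_cells: int,
                  seed: int | None = None) -> tuple[CountMatrix, TruthRecord]:
    """Draw a synthetic count matrix and its ground-truth record."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    truth = truth_functionals(spec)
    gamma = _sample_size_factors(rng, n_cells, spec.size_factor_sigma)
    x = np.empty((n_cells, spec.n_genes))
    for prior, sl in spec.gene_blocks():
        x[:, sl] = prior.sample(rng, n_cells)
    lam = gamma[:, None] * spec.depth * x
    y = rng.poisson(lam)
    cm = CountMatrix(y,
                     cell_ids=[f"cell{c:05d}" for c in range(n_cells)],
                     gene_ids=[f"gene{g:04d}" for g in range(spec.n_genes)])
    truth.x = x
    truth.gamma = gamma
    return cm, truth


# ---------------------------------------------------------------------------
# Deterministic fixture suite
# ---------------------------------------------------------------------------

def fixture_suite(seed: int, outdir: str) -> dict[str, str]:
    """Write small deterministic fixtures covering the model's corner cases.

    Includes pure-Poisson genes, overdispersed genes, a correlated 3-block
    structure, a low-depth stress gene for the inactive-probability
    coefficients, and an all-zero gene. Returns {name: mtx path}.
    """
    os.makedirs(outdir, exist_ok=True)
    suite = {
        "poisson_overdispersed": GeneratorSpec(
            priors=(PointPrior(1.0), PointPrior(0.5),
                    GammaPrior(2.0, 0.5), GammaPrior(0.5, 2.0)),
            depth=5.0, size_factor_sigma=0.3, seed=seed),
        "correlated_blocks": GeneratorSpec(
            priors=(CorrelatedGammaPrior(2.0, 0.5, block_size=4, rho=0.9),
                    CorrelatedGammaPrior(1.0, 1.0, block_size=3, rho=0.8),
                    CorrelatedGammaPrior(4.0, 0.25, block_size=3, rho=0.7)),
            depth=5.0, seed=seed + 1),
        "kappa_stress": GeneratorSpec(
            priors=(GammaPrior(2.0, 0.5), PointPrior(0.0)),
            depth=0.5, seed=seed + 2),
    }
    paths = {}
    for name, spec in suite.items():
        subdir = os.path.join(outdir, name)
        os.makedirs(subdir, exist_ok=True)
        cm, truth = sample_counts(spec, n_cells=2000)
        mtx_path = os.path.join(subdir, "matrix.mtx")
        write_counts(cm, mtx_path, format="mtx")
        with open(os.path.join(subdir, "truth.json"), "w") as fh:
            fh.write(truth.to_json())
        paths[name] = mtx_path
    return paths
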