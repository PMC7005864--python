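"""Sequencing-budget design: depth/cells tradeoff, optimal depth, post hoc
reliability tables, the 1/p* design rule, and correlation networks.

The central tradeoff fixes a per-gene read budget B and varies the sequencing
depth s (mean reads per cell per gene); the number of cells is then
n_cells = floor(B / s). Estimation error at each grid point is measured by
Monte-Carlo simulation from a stated generator against its exact functionals.
The design rule for a whole experiment is n_reads* = 1/p*, n_cells* = B * p*,
where p* is the relative mean expression of the weakest gene of interest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimators import (GeneStatistics, CorrelationEstimate, moments_arrays,
                         inactive_coeffs)
from .simulate import GeneratorSpec, truth_functionals, _sample_size_factors

__all__ = [
    "DesignSpec", "ErrorSpec", "TradeoffCurve", "PosthocTable",
    "optimal_design", "detection_limit", "relative_error", "tradeoff_sweep",
    "optimal_depth", "posthoc_min_depth", "correlation_network",
]

QUANTITIES = ("mean", "second_moment", "cv", "fano", "gamma_r", "gamma_theta",
              "pearson", "inactive_prob")

# Variance-like quantities are scored by relative squared error, everything
# else by plain relative error (both thresholded at 0.1 by default).
_DEFAULT_ERROR_KIND = {
    "second_moment": "relative_squared",
    "fano": "relative_squared",
}


# ---------------------------------------------------------------------------
# Design rule
# ---------------------------------------------------------------------------

@dataclass
class DesignSpec:
    """Recommended (depth, cells) split for a budget and detection limit."""

    p_star: float
    budget: float
    n_reads_star: float
    n_cells_star: float
    saturation_flag: bool = False
    advice: str = ""

    def to_dict(self) -> dict:
        return {
            "p_star": self.p_star,
            "budget": self.budget,
            "n_reads_star": self.n_reads_star,
            "n_cells_star": self.n_cells_star,
            "saturation_flag": self.saturation_flag,
            "advice": self.advice,
        }


def optimal_design(p_star: float, budget: float,
                   platform_ceiling: float | None = None) -> DesignSpec:
    """Apply the 1/p* rule: depth 1/p* reads per cell, budget * p* cells.

    At this depth the weakest gene of interest averages one read per cell,
    which minimizes the worst-case error over all genes of interest. If the
    recommended depth exceeds a stated platform ceiling (UMIs per cell), the
    saturation flag is set: the platform cannot reach the depth, so the
    guidance is to sequence until saturation.
    """
    if not (0.0 < p_star < 1.0):
        if p_star == 1.0:
            pass  # boundary: one read per cell, all budget into cells
        else:
            raise ValueError(f"p_star must be in (0, 1], got {p_star}")
    if budget <= 0:
        raise ValueError("budget must be positive")
    n_reads_star = 1.0 / p_star
    n_cells_star = budget * p_star
    saturated = platform_ceiling is not None and n_reads_star > platform_ceiling
    return DesignSpec(p_star=p_star, budget=budget, n_reads_star=n_reads_star,
                      n_cells_star=n_cells_star, saturation_flag=saturated,
                      advice="sequence until saturation" if saturated else "")


def detection_limit(reference_means: pd.Series | dict,
                    genes_of_interest: list[str]) -> float:
    """Reliable detection limit p*: the smallest relative mean expression
    among the genes of interest.

    ``reference_means`` maps genes to mean expression from a pilot or
    reference dataset. Values summing to at most 1 are taken as relative
    expression already; raw count totals (sum > 1) are normalized internally.
    Either way the argmin over the gene list is unchanged by the scaling.
    """
    means = pd.Series(reference_means, dtype=float)
    missing = [g for g in genes_of_interest if g not in means.index]
    if missing:
        raise KeyError(f"genes missing from reference: {missing}")
    if not genes_of_interest:
        raise ValueError("genes_of_interest is empty")
    total = means.sum()
    if total <= 0:
        raise ValueError("reference means must have positive total")
    if total > 1.0:
        means = means / total
    return float(means[list(genes_of_interest)].min())


def relative_error(estimate: float, truth: float, kind: str = "relative") -> float:
    """|est - truth| / |truth| or its square; truth must be nonzero."""
    if truth == 0:
        raise ValueError("relative error undefined for zero truth")
    rel = abs(estimate - truth) / abs(truth)
    if kind == "relative":
        return rel
    if kind == "relative_squared":
        return rel**2
    raise ValueError(f"unknown error kind {kind!r}")


# ---------------------------------------------------------------------------
# Error specification and per-replicate quantity evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ErrorSpec:
    """Which quantity to score, with which error, against which threshold."""

    quantity: str
    error_kind: str | None = None
    threshold: float = 0.1
    kappa: float = 1.0   # evaluation scale for inactive_prob

    def __post_init__(self):
        if self.quantity not in QUANTITIES:
            raise ValueError(f"unknown quantity {self.quantity!r}")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.error_kind is None:
            object.__setattr__(self, "error_kind",
                               _DEFAULT_ERROR_KIND.get(self.quantity, "relative"))

    def score(self, est: np.ndarray, truth: np.ndarray) -> float:
        """Mean error across genes/pairs for one replicate."""
        est = np.atleast_1d(np.asarray(est, dtype=float))
        truth = np.atleast_1d(np.asarray(truth, dtype=float))
        rel = np.abs(est - truth) / np.abs(truth)
        if self.error_kind == "relative_squared":
            rel = rel**2
        return float(rel.mean())


def _pair_indices(spec: GeneratorSpec) -> list[tuple[int, int]]:
    pairs = []
    for prior, sl in spec.gene_blocks():
        idx = list(range(sl.start, sl.stop))
        if len(idx) >= 2:
            pairs.extend((idx[i], idx[j]) for i in range(len(idx))
                         for j in range(i + 1, len(idx)))
    return pairs


def _evaluate_replicate(y: np.ndarray, s: np.ndarray, error: ErrorSpec,
                        truth, pairs) -> tuple[float, float]:
    """(plug-in error, EB error) for one simulated replicate.

    EB variances are floored at zero when deriving CV/Fano/gamma parameters,
    so invalid replicates contribute their full (large) error instead of
    being silently dropped.
    """
    q = error.quantity
    if q == "pearson":
        n = y.shape[0]
        mean, var_p, var_e = _mean_vars(y, s)
        w = y / s[:, None]
        truth_vals, est_p, est_e = [], [], []
        for i, j in pairs:
            m11 = float(w[:, i] @ w[:, j]) / n
            cov = m11 - mean[i] * mean[j]
            denom_p = np.sqrt(max(var_p[i], 0.0) * max(var_p[j], 0.0))
            denom_e = np.sqrt(max(var_e[i], 0.0) * max(var_e[j], 0.0))
            est_p.append(cov / denom_p if denom_p > 0 else 0.0)
            est_e.append(np.clip(cov / denom_e, -1, 1) if denom_e > 0 else 0.0)
            truth_vals.append(truth.pearson[i, j])
        return (error.score(est_p, truth_vals), error.score(est_e, truth_vals))

    if q == "inactive_prob":
        kappa = error.kappa
        truth_vals = truth.p0(kappa)
        p_plugin = (y == 0).mean(axis=0)
        p_eb = np.clip(inactive_coeffs(y, s, kappa).mean(axis=0), 0.0, 1.0)
        return (error.score(p_plugin, truth_vals), error.score(p_eb, truth_vals))

    plugin, eb = moments_arrays(y, s, 2)
    mean = plugin[0]
    var_p = plugin[1] - mean**2
    var_e = np.maximum(eb[1] - mean**2, 0.0)
    if q == "mean":
        return (error.score(mean, truth.m[0]),) * 2
    if q == "second_moment":
        return (error.score(plugin[1], truth.m[1]), error.score(eb[1], truth.m[1]))
    if q == "cv":
        t = truth.cv
        return (error.score(np.sqrt(np.maximum(var_p, 0)) / mean, t),
                error.score(np.sqrt(var_e) / mean, t))
    if q == "fano":
        t = truth.fano
        return (error.score(var_p / mean, t), error.score(var_e / mean, t))
    if q == "gamma_r":
        t = truth.gamma_shape
        with np.errstate(divide="ignore"):
            return (error.score(mean**2 / var_p, t), error.score(mean**2 / var_e, t))
    if q == "gamma_theta":
        t = truth.gamma_scale
        return (error.score(var_p / mean, t), error.score(var_e / mean, t))
    raise AssertionError(q)


def _mean_vars(y, s):
    plugin, eb = moments_arrays(y, s, 2)
    return plugin[0], plugin[1] - plugin[0]**2, eb[1] - plugin[0]**2


# ---------------------------------------------------------------------------
# Tradeoff sweep
# ---------------------------------------------------------------------------

@dataclass
class TradeoffCurve:
    """Mean estimation error vs sequencing depth under a fixed per-gene budget."""

    budget_per_gene: float
    depths: np.ndarray
    n_cells: np.ndarray
    err_plugin: np.ndarray
    se_plugin: np.ndarray
    err_eb: np.ndarray
    se_eb: np.ndarray
    n_reps: int
    error: ErrorSpec
    skipped: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.skipped is None:
            self.skipped = np.zeros(len(self.depths), dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "depth": self.depths, "n_cells": self.n_cells,
            "err_plugin": self.err_plugin, "se_plugin": self.se_plugin,
            "err_eb": self.err_eb, "se_eb": self.se_eb,
            "skipped": self.skipped,
        })

    def write_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def tradeoff_sweep(generator: GeneratorSpec, budget_per_gene: float,
                   depths, error: ErrorSpec, n_reps: int = 200,
                   seed: int = 0) -> TradeoffCurve:
    """Simulate the fixed-budget depth/cells tradeoff.

    For each depth s in the grid, n_cells = floor(budget / s) cells are
    simulated from the generator (with its prior and size-factor model but
    depth overridden to s), the quantity is estimated with both the plug-in
    and the EB estimator, and errors against the generator's exact truth are
    averaged over ``n_reps`` independent replicates. Replicate r of depth d
    uses the seeded stream (seed, d, r), so curves are reproducible and
    depths are independent.
    """
    depths = np.asarray(sorted(depths), dtype=float)
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    truth = truth_functionals(generator)
    pairs = _pair_indices(generator) if error.quantity == "pearson" else None
    if error.quantity == "pearson" and not pairs:
        raise ValueError("pearson sweep requires a correlated block prior")
    n_cells_arr = np.floor(budget_per_gene / depths).astype(int)
    skipped = n_cells_arr < 2
    if skipped.all():
        raise ValueError("no feasible depth in the grid")
    if skipped.any():
        warnings.warn(f"skipping infeasible depths {depths[skipped].tolist()} "
                      f"(fewer than 2 cells)", RuntimeWarning, stacklevel=2)

    err_p = np.full(len(depths), np.nan)
    se_p = np.full(len(depths), np.nan)
    err_e = np.full(len(depths), np.nan)
    se_e = np.full(len(depths), np.nan)
    root = np.random.SeedSequence(seed)
    for i, (depth, n_cells) in enumerate(zip(depths, n_cells_arr)):
        if skipped[i]:
            continue
        rep_p = np.empty(n_reps)
        rep_e = np.empty(n_reps)
        for r, child in enumerate(root.spawn(n_reps)):
            rng = np.random.default_rng(child)
            gamma = _sample_size_factors(rng, n_cells, generator.size_factor_sigma)
            x = np.empty((n_cells, generator.n_genes))
            for prior, sl in generator.gene_blocks():
                x[:, sl] = prior.sample(rng, n_cells)
            y = rng.poisson(gamma[:, None] * depth * x)
            s = gamma * depth
            rep_p[r], rep_e[r] = _evaluate_replicate(y, s, error, truth, pairs)
        err_p[i], err_e[i] = rep_p.mean(), rep_e.mean()
        se_p[i] = rep_p.std(ddof=1) / np.sqrt(n_reps)
        se_e[i] = rep_e.std(ddof=1) / np.sqrt(n_reps)
    return TradeoffCurve(budget_per_gene=budget_per_gene, depths=depths,
                         n_cells=n_cells_arr, err_plugin=err_p, se_plugin=se_p,
                         err_eb=err_e, se_eb=se_e, n_reps=n_reps, error=error,
                         skipped=skipped)


@dataclass
class OptimalDepth:
    depth: float
    argmin_depth: float
    flat_region: tuple[float, float]
    error: float


def optimal_depth(curve: TradeoffCurve, estimator: str = "eb") -> OptimalDepth:
    """Read the optimal depth off a tradeoff curve.

    ``argmin_depth`` is the raw minimizer of the mean error. Monte-Carlo
    curves are typically flat near the optimum, so points whose error is
    within one standard error (of the difference) of the minimum are treated
    as ties, broken toward the smaller depth — cells are the scarcer
    scientific resource. ``flat_region`` reports the [lowest, highest] depth
    inside that one-SE band.
    """
    err = curve.err_eb if estimator == "eb" else curve.err_plugin
    se = curve.se_eb if estimator == "eb" else curve.se_plugin
    valid = ~curve.skipped & np.isfinite(err)
    if valid.sum() < 2:
        raise ValueError("optimal_depth requires at least 2 valid sweep points")
    idx = np.flatnonzero(valid)
    i_min = idx[np.argmin(err[idx])]
    se_diff = np.sqrt(se**2 + se[i_min]**2)
    flat = idx[(err[idx] - err[i_min]) <= se_diff[idx]]
    return OptimalDepth(depth=float(curve.depths[flat[0]]),
                        argmin_depth=float(curve.depths[i_min]),
                        flat_region=(float(curve.depths[flat[0]]),
                                     float(curve.depths[flat[-1]])),
                        error=float(err[i_min]))


# ---------------------------------------------------------------------------
# Post hoc reliability table
# ---------------------------------------------------------------------------

@dataclass
class PosthocTable:
    """Minimum depth achieving error < threshold, per quantity x cell count.

    NaN marks (quantity, n_cells) combinations where no depth in the searched
    grid qualifies ("unattainable").
    """

    table: pd.DataFrame      # index: quantity, columns: n_cells
    threshold: float
    depth_grid: np.ndarray

    def write_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t")


def posthoc_min_depth(generator: GeneratorSpec, n_cells_grid,
                      errors: list[ErrorSpec] | ErrorSpec,
                      depth_grid=None, n_reps: int = 50,
                      seed: int = 0) -> PosthocTable:
    """Smallest sequencing depth with mean error below threshold.

    For each requested quantity and each cell count, depths are scanned in
    increasing order; the first depth whose Monte-Carlo mean error falls
    below the quantity's threshold is recorded. Unlike the budget sweep, the
    cell count here is held fixed while the depth varies.
    """
    if isinstance(errors, ErrorSpec):
        errors = [errors]
    if depth_grid is None:
        depth_grid = DEFAULT_DEPTH_GRID
    depth_grid = np.asarray(sorted(depth_grid), dtype=float)
    n_cells_grid = sorted(int(n) for n in n_cells_grid)
    if not len(depth_grid) or not n_cells_grid:
        raise ValueError("grids must be nonempty")
    rows = {}
    root = np.random.SeedSequence(seed)
    for error in errors:
        truth = truth_functionals(generator)
        pairs = _pair_indices(generator) if error.quantity == "pearson" else None
        row = {}
        for n_cells in n_cells_grid:
            found = np.nan
            for depth in depth_grid:
                rep_e = np.empty(n_reps)
                for r, child in enumerate(root.spawn(n_reps)):
                    rng = np.random.default_rng(child)
                    gamma = _sample_size_factors(rng, n_cells,
                                                 generator.size_factor_sigma)
                    x = np.empty((n_cells, generator.n_genes))
                    for prior, sl in generator.gene_blocks():
                        x[:, sl] = prior.sample(rng, n_cells)
                    y = rng.poisson(gamma[:, None] * depth * x)
                    _, rep_e[r] = _evaluate_replicate(y, gamma * depth, error,
                                                      truth, pairs)
                if rep_e.mean() < error.threshold:
                    found = depth
                    break
            row[n_cells] = found
        rows[error.quantity] = row
    table = pd.DataFrame(rows).T
    table.index.name = "quantity"
    table.columns.name = "n_cells"
    return PosthocTable(table=table, threshold=errors[0].threshold,
                        depth_grid=depth_grid)


DEFAULT_DEPTH_GRID = (0.02, 0.05, 0.1, 0.2, 0.5, 1.0, 2.0, 5.0, 10.0)


# ---------------------------------------------------------------------------
# Correlation network
# ---------------------------------------------------------------------------

def correlation_network(corr: CorrelationEstimate, stats: GeneStatistics,
                        edge_threshold: float = 0.8,
                        min_eb_variance: float = 0.1) -> pd.DataFrame:
    """Undirected gene-gene edges from the EB Pearson correlation.

    Genes are first filtered to EB variance > ``min_eb_variance``; an edge is
    drawn where the EB correlation exceeds ``edge_threshold``. Self-edges and
    pairs with invalid EB variance are excluded.
    """
    if list(corr.gene_ids) != list(stats.gene_ids):
        raise ValueError("correlation and statistics cover different gene sets")
    genes = np.asarray(corr.gene_ids)
    keep = stats.valid_eb & (stats.var_eb > min_eb_variance)
    rows = []
    idx = np.flatnonzero(keep)
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            i, j = idx[a], idx[b]
            if corr.valid[i, j] and corr.pearson_eb[i, j] > edge_threshold:
                rows.append((genes[i], genes[j], corr.pearson_eb[i, j]))
    return pd.DataFrame(rows, columns=["gene1", "gene2", "pearson_eb"])
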