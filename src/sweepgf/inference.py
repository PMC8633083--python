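"""Composite-likelihood inference of (theta, Ta, s) from blockwise SFS data.

The composite likelihood multiplies, over blocks i and subsamples j of size
x (x = 4 throughout, so topology information enters), the analytic
probability of the observed blockwise mutation configuration:

    lnCL_s(theta, Ta, s) = sum_i sum_j ln P[k_ij | alpha_i(s), Ta, theta]

with ``alpha_i = (r*d_i/s)*ln(2*Ne*s)`` at the block's distance.  Support
for a sweep is the difference ``dlnCL = lnCL_s - lnCL_0`` against the
neutral composite likelihood.  Subsample terms are summed as defined even
though subsamples overlap: this is a composite likelihood and no variance
correction is applied.

Fitting is a two-step grid optimization: theta is first estimated from
blocks far from the target (alpha above a threshold, default 0.5), then
(Ta, s) jointly conditional on theta.  Exact table evaluation with
memoization is the reference path; an optional cubic interpolation of log
probabilities over log-alpha nodes accelerates batch power studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.stats import rankdata

from .observables import (BsfsTable, MutationModel, bsfs_probabilities,
                          neutral_bsfs_probabilities)
from .partition import ParameterError, SweepParams, alpha as alpha_fn
from .simulate import ReplicateDataset

__all__ = [
    "SampleConfig",
    "GridSpec",
    "CLResult",
    "tabulate_bsfs",
    "ln_cl",
    "estimate_theta",
    "fit_grid",
    "fit_batch",
    "roc_curve",
    "TableSet",
]

LOG_FLOOR = math.log(1e-300)


@dataclass(frozen=True)
class SampleConfig:
    """Sampled lineages n and subsample size x (4 for topology-aware bSFS)."""

    n: int
    x: int = 4

    def __post_init__(self):
        if not 2 <= self.x <= self.n:
            raise ParameterError("need 2 <= x <= n")

    @property
    def n_subsamples(self) -> int:
        return math.comb(self.n, self.x)


@dataclass(frozen=True)
class GridSpec:
    """Grid axes for the two-step (theta, then Ta and s) optimization."""

    thetas: tuple
    tas: tuple
    ss: tuple
    Ne: float
    r: float

    def __post_init__(self):
        for name, ax in (("thetas", self.thetas), ("tas", self.tas),
                         ("ss", self.ss)):
            if len(ax) == 0:
                raise ParameterError(f"empty grid axis {name}")
            if any(b <= a for a, b in zip(ax, ax[1:])):
                raise ParameterError(f"grid axis {name} must be strictly "
                                     "increasing")
        if any(2 * self.Ne * s <= 1 for s in self.ss):
            raise ParameterError("all s values must satisfy 2*Ne*s > 1")

    def cells(self):
        """(Ta, s) cells ordered so the neutral-most (largest Ta, smallest
        s) comes first: argmax ties then resolve conservatively."""
        return [(ta, s) for ta in sorted(self.tas, reverse=True)
                for s in self.ss]


@dataclass
class CLResult:
    """Two-step composite-likelihood fit of one blockwise dataset."""

    theta_hat: float
    ta_hat: float
    s_hat: float
    lncl_sweep: float
    lncl_neutral: float
    delta_lncl: float
    surface: dict = field(default_factory=dict)   # (Ta, s) -> lnCL
    theta_surface: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "theta_hat": self.theta_hat, "ta_hat": self.ta_hat,
            "s_hat": self.s_hat, "lncl_sweep": self.lncl_sweep,
            "lncl_neutral": self.lncl_neutral, "delta_lncl": self.delta_lncl,
            "surface": {f"{ta}:{s}": v for (ta, s), v in
                        self.surface.items()},
            "theta_surface": {str(th): v for th, v in
                              self.theta_surface.items()},
        }


# ---------------------------------------------------------------------------
# tabulation of observed configurations
# ---------------------------------------------------------------------------

def tabulate_bsfs(block_variants: list, cfg: SampleConfig, kmax: int
                  ) -> np.ndarray:
    """Capped bSFS configurations for every subsample of x lineages.

    ``block_variants[b]`` is the list of derived-allele carrier index sets
    for block b (phased, polarized data).  Returns an array
    ``(B, C(n,x), 3)``: per block and subsample, the counts of mutations at
    subsample-frequency 1, 2 and 3, capped at ``kmax+1``.  Sites fixed
    (derived count x) or absent (0) within the subsample are not
    segregating there and contribute nothing.
    """
    if cfg.x != 4:
        raise ParameterError("the topology-aware bSFS uses subsamples of 4")
    subs = list(combinations(range(cfg.n), cfg.x))
    B = len(block_variants)
    out = np.zeros((B, len(subs), 3), dtype=np.uint8)
    for b, variants in enumerate(block_variants):
        for si, sub in enumerate(subs):
            ss = set(sub)
            counts = [0, 0, 0]
            for carriers in variants:
                c = len(set(carriers) & ss)
                if 1 <= c <= cfg.x - 1:
                    counts[c - 1] += 1
            out[b, si] = np.minimum(counts, kmax + 1)
    return out


# ---------------------------------------------------------------------------
# log-probability tables
# ---------------------------------------------------------------------------

_EXACT_CACHE: dict = {}


def _exact_logp(alpha: float, Ta, theta: float, kmax: int,
                ta_correction: float = 0.0) -> np.ndarray:
    """Memoized flat log-probability table (64 entries for kmax=2).

    ``Ta=None`` or ``alpha=inf`` selects the neutral table.
    """
    neutral = Ta is None or not math.isfinite(alpha)
    key = (None if neutral else (round(alpha, 12), round(Ta, 12),
                                 round(ta_correction, 12)),
           round(theta, 12), kmax)
    if key not in _EXACT_CACHE:
        mut = MutationModel(theta, kmax)
        if neutral:
            tab = neutral_bsfs_probabilities(mut)
        else:
            tab = bsfs_probabilities(alpha, Ta, mut,
                                     ta_correction=ta_correction)
        _EXACT_CACHE[key] = np.log(np.maximum(tab.flat, 1e-300))
    return _EXACT_CACHE[key]


class TableSet:
    """Interpolated log-probability tables over a (theta, Ta) grid.

    Tables are computed exactly at log-spaced alpha nodes and interpolated
    (cubic in log alpha, per configuration) to arbitrary block distances;
    since alpha depends on s only through the composite alpha = f(d, s),
    one node set serves every s in the grid.
    """

    def __init__(self, grid: GridSpec, kmax: int, n_nodes: int = 24,
                 alpha_range: tuple | None = None, include_ta0: bool = False):
        self.grid = grid
        self.kmax = kmax
        self.nflat = (kmax + 2) ** 3
        if alpha_range is None:
            raise ParameterError("alpha_range (min, max) is required")
        lo, hi = alpha_range
        if not (0 < lo < hi):
            raise ParameterError("invalid alpha range")
        self.nodes = np.geomspace(lo, hi, n_nodes)
        self.tas = tuple(grid.tas) + ((0.0,) if include_ta0 and
                                      0.0 not in grid.tas else ())
        self.sweep_logp: dict = {}
        for th in grid.thetas:
            mut = MutationModel(th, kmax)
            for ta in self.tas:
                arr = np.empty((n_nodes, self.nflat))
                for i, a in enumerate(self.nodes):
                    tab = bsfs_probabilities(a, ta, mut)
                    arr[i] = np.log(np.maximum(tab.flat, 1e-300))
                self.sweep_logp[(th, ta)] = CubicSpline(
                    np.log(self.nodes), arr, axis=0)
        self.neutral_logp = {
            th: np.log(np.maximum(
                neutral_bsfs_probabilities(MutationModel(th, kmax)).flat,
                1e-300))
            for th in grid.thetas}

    def block_logp(self, theta: float, ta: float, alphas: np.ndarray
                   ) -> np.ndarray:
        """(B, nflat) log probabilities at the blocks' alphas."""
        sp = self.sweep_logp[(theta, ta)]
        la = np.log(np.clip(alphas, self.nodes[0], self.nodes[-1]))
        return sp(la)


# ---------------------------------------------------------------------------
# composite likelihood
# ---------------------------------------------------------------------------

def _dataset_codes(dataset: ReplicateDataset) -> np.ndarray:
    return dataset.codes()          # (B, S)


def ln_cl(dataset: ReplicateDataset, theta: float, Ta: float | None = None,
          s: float | None = None, Ne: float | None = None,
          r: float | None = None, ta_correction: float = 0.0) -> float:
    """Exact composite log likelihood of one dataset.

    Pass ``Ta`` and ``s`` (plus Ne, r to map distances to alpha) for the
    sweep model; omit them for the neutral model.  Zero-probability
    configurations are floored at log(1e-300) (a warning-level guard; the
    analytic tables are strictly positive for theta > 0).
    """
    codes = _dataset_codes(dataset)
    if Ta is None:
        lp = _exact_logp(np.inf, None, theta, dataset.kmax)
        return float(lp[codes].sum())
    if s is None or Ne is None or r is None:
        raise ParameterError("sweep model needs s, Ne and r")
    total = 0.0
    for b in range(dataset.B):
        a = alpha_fn(r, dataset.distances[b], s, Ne)
        lp = _exact_logp(a, Ta, theta, dataset.kmax, ta_correction)
        total += float(lp[codes[b]].sum())
    return total


def estimate_theta(dataset: ReplicateDataset, grid: GridSpec,
                   alpha_threshold: float = 0.5,
                   s_ref: float | None = None) -> tuple:
    """Maximize the neutral composite likelihood over the theta grid using
    blocks far from the target.

    A block qualifies if its alpha at ``s_ref`` (default: the largest s of
    the grid, the most conservative choice) exceeds ``alpha_threshold``.
    Returns ``(theta_hat, {theta: lnCL0_distant})``.
    """
    if s_ref is None:
        s_ref = max(grid.ss)
    al = np.array([alpha_fn(grid.r, d, s_ref, grid.Ne)
                   for d in dataset.distances])
    keep = al > alpha_threshold
    if not keep.any():
        raise ParameterError(
            f"no blocks with alpha > {alpha_threshold} at s_ref={s_ref}; "
            "cannot estimate theta")
    codes = _dataset_codes(dataset)[keep]
    surface = {}
    for th in grid.thetas:
        lp = _exact_logp(np.inf, None, th, dataset.kmax)
        surface[th] = float(lp[codes].sum())
    theta_hat = max(surface, key=surface.get)
    return theta_hat, surface


def fit_grid(dataset: ReplicateDataset, grid: GridSpec,
             alpha_threshold: float = 0.5, s_ref: float | None = None,
             tables: TableSet | None = None,
             ta_correction: bool = False) -> CLResult:
    """Two-step composite-likelihood fit: theta, then (Ta, s) jointly.

    Ties in the (Ta, s) argmax break toward the neutral-most cell (largest
    Ta, then smallest s).  ``tables`` switches from exact per-alpha
    evaluation to interpolated tables.
    """
    if ta_correction and tables is not None:
        raise ParameterError("the duration correction shifts Ta by an "
                             "s-dependent amount; use the exact path "
                             "(tables=None)")
    theta_hat, th_surface = estimate_theta(dataset, grid, alpha_threshold,
                                           s_ref)
    codes = _dataset_codes(dataset)
    lp0 = _exact_logp(np.inf, None, theta_hat, dataset.kmax)
    lncl0 = float(lp0[codes].sum())
    surface = {}
    best = None
    for ta, s in grid.cells():
        corr = (SweepParams(grid.Ne, s, grid.r, ta).t_fix_coal
                if ta_correction else 0.0)
        if tables is not None:
            al = np.array([alpha_fn(grid.r, d, s, grid.Ne)
                           for d in dataset.distances])
            lp = tables.block_logp(theta_hat, ta, al)
            val = float(np.take_along_axis(
                lp, codes.astype(int), axis=1).sum())
        else:
            val = ln_cl(dataset, theta_hat, Ta=ta, s=s, Ne=grid.Ne,
                        r=grid.r, ta_correction=corr)
        surface[(ta, s)] = val
        if best is None or val > best[0] + 1e-12:
            best = (val, ta, s)
    val, ta_hat, s_hat = best
    return CLResult(theta_hat=theta_hat, ta_hat=ta_hat, s_hat=s_hat,
                    lncl_sweep=val, lncl_neutral=lncl0,
                    delta_lncl=val - lncl0, surface=surface,
                    theta_surface=th_surface)


# ---------------------------------------------------------------------------
# batch fitting for power studies
# ---------------------------------------------------------------------------

def fit_batch(codes: np.ndarray, distances: np.ndarray, grid: GridSpec,
              tables: TableSet, alpha_threshold: float = 0.5,
              s_ref: float | None = None, constrain_ta: float | None = None,
              chunk: int = 200) -> dict:
    """Vectorized two-step fits of many replicates sharing one geometry.

    ``codes`` is (R, B) flat configuration codes (n = x datasets).  Returns
    arrays of theta/Ta/s estimates and delta lnCL.  ``constrain_ta`` fixes
    the sweep age (e.g. 0.0, the standard sweep-scan assumption) and
    optimizes s only.
    """
    R, B = codes.shape
    codes = codes.astype(np.int64)
    if s_ref is None:
        s_ref = max(grid.ss)
    al_ref = np.array([alpha_fn(grid.r, d, s_ref, grid.Ne)
                       for d in distances])
    keep = al_ref > alpha_threshold
    if not keep.any():
        raise ParameterError("no distant blocks for theta estimation")

    # step 1: theta from distant blocks under neutrality
    nth = len(grid.thetas)
    lncl0_dist = np.empty((R, nth))
    lncl0_all = np.empty((R, nth))
    for i, th in enumerate(grid.thetas):
        lp = tables.neutral_logp[th]
        lncl0_dist[:, i] = lp[codes[:, keep]].sum(axis=1)
        lncl0_all[:, i] = lp[codes].sum(axis=1)
    th_idx = lncl0_dist.argmax(axis=1)
    theta_hat = np.asarray(grid.thetas)[th_idx]
    lncl0 = lncl0_all[np.arange(R), th_idx]

    # step 2: (Ta, s) conditional on theta, cells ordered neutral-most first
    cells = ([(constrain_ta, s) for s in grid.ss] if constrain_ta is not None
             else grid.cells())
    ncell = len(cells)
    # per (theta, cell): (B, nflat) block log-probability matrices
    lncl_s = np.full((R, ncell), -np.inf)
    for ti, th in enumerate(grid.thetas):
        rows = np.nonzero(th_idx == ti)[0]
        if rows.size == 0:
            continue
        for ci, (ta, s) in enumerate(cells):
            al = np.array([alpha_fn(grid.r, d, s, grid.Ne)
                           for d in distances])
            lp = tables.block_logp(th, ta, al)        # (B, nflat)
            for start in range(0, rows.size, chunk):
                rr = rows[start:start + chunk]
                lncl_s[rr, ci] = np.take_along_axis(
                    lp.T, codes[rr], axis=0).sum(axis=1)
    best = lncl_s.argmax(axis=1)        # first maximum = neutral-most tie
    ta_hat = np.array([cells[c][0] for c in best])
    s_hat = np.array([cells[c][1] for c in best])
    lncl_best = lncl_s[np.arange(R), best]
    return {
        "theta_hat": theta_hat, "ta_hat": ta_hat, "s_hat": s_hat,
        "lncl_sweep": lncl_best, "lncl_neutral": lncl0,
        "delta_lncl": lncl_best - lncl0,
    }


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

def roc_curve(delta_sweep, delta_neutral) -> dict:
    """ROC from jointly ranked sweep-support scores.

    True (sweep) and false (neutral) replicates are ranked in descending
    order of delta lnCL; ties are pooled at equal thresholds.  AUC is the
    Mann-Whitney statistic (ties counted half).
    """
    ds = np.asarray(delta_sweep, dtype=float)
    dn = np.asarray(delta_neutral, dtype=float)
    if ds.size == 0 or dn.size == 0:
        raise ParameterError("both score lists must be non-empty")
    scores = np.concatenate([ds, dn])
    labels = np.concatenate([np.ones(ds.size), np.zeros(dn.size)])
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    l_sorted = labels[order]
    # pool ties: step only at distinct thresholds
    distinct = np.nonzero(np.diff(s_sorted))[0]
    edges = np.concatenate([distinct, [s_sorted.size - 1]])
    tp = np.cumsum(l_sorted)[edges]
    fp = np.cumsum(1 - l_sorted)[edges]
    tpr = np.concatenate([[0.0], tp / ds.size])
    fpr = np.concatenate([[0.0], fp / dn.size])
    ranks = rankdata(scores)
    auc = (ranks[:ds.size].sum() - ds.size * (ds.size + 1) / 2) \
        / (ds.size * dn.size)
    return {"fpr": fpr, "tpr": tpr, "auc": float(auc)}
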