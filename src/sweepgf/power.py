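"""Batch simulation + fitting protocol for parameter recovery and power.

The standard study emulates the sweep-detection experiment: replicate
datasets of B = 2000 blocks of l = 500 bases flanking the selected site
(theta = 4*Ne*mu*l = 0.5 per block with mu = 2.5e-8, k_max = 2, n = x = 4
lineages, 500 kb of flank per side), simulated either under the hybrid
sweep model at (s, Ta) or under neutrality, then fitted by the two-step
composite-likelihood grid optimization.  Sweep support (delta lnCL) of
true and false replicates is ranked into ROC curves.

Problem sizes (200 sweep replicates per condition against a shared pool of
2000 neutral replicates) keep the study on a desk scale while leaving the
power ordering and recovery patterns well resolved; the block length is
chosen so that the distant-block theta estimator keeps ample blocks beyond
the conservative alpha > 0.5 cut at every s on the grid.
"""

from __future__ import annotations

import numpy as np

from .inference import GridSpec, TableSet, fit_batch, roc_curve
from .observables import BsfsTable
from .partition import SweepParams, alpha as alpha_fn
from .simulate import block_distances, hybrid_iton_sample

__all__ = [
    "standard_grid",
    "simulate_replicate_codes",
    "standard_power_study",
]

NE_DEFAULT = 10_000
R_DEFAULT = 1e-7


def standard_grid(Ne: float = NE_DEFAULT, r: float = R_DEFAULT) -> GridSpec:
    """Default optimization grid bracketing the simulated conditions."""
    return GridSpec(thetas=(0.3, 0.4, 0.5, 0.6, 0.7),
                    tas=(0.1, 0.5, 1.0, 2.0),
                    ss=(0.005, 0.015, 0.05, 0.15),
                    Ne=Ne, r=r)


def simulate_replicate_codes(Ta: float, alphas: np.ndarray, theta: float,
                             kmax: int, reps: int, rng,
                             chunk_rows: int = 500_000) -> np.ndarray:
    """(reps, B) flat bSFS configuration codes for n = x = 4 replicates.

    Each replicate draws one independent genealogy per block at the block's
    alpha (use ``inf`` for neutral data) and drops Poisson mutations on the
    i-Ton class totals at rate theta/2.
    """
    B = alphas.size
    total = reps * B
    out = np.empty(total, dtype=np.int64)
    al_tiled = np.tile(alphas, reps)
    for start in range(0, total, chunk_rows):
        stop = min(start + chunk_rows, total)
        res = hybrid_iton_sample(4, al_tiled[start:stop], Ta, stop - start,
                                 rng=rng)
        k = rng.poisson(theta / 2.0 * res["titon"])
        out[start:stop] = BsfsTable.config_code(k, kmax)
    return out.reshape(reps, B)


def standard_power_study(seed, n_sweep: int = 200, n_neutral: int = 2000,
                         B: int = 2000, l: float = 500.0, theta: float = 0.5,
                         kmax: int = 2,
                         conditions=((0.05, 0.1), (0.05, 1.0), (0.005, 1.0)),
                         constrained_conditions=((0.05, 1.0),),
                         grid: GridSpec | None = None,
                         n_nodes: int = 28, alpha_threshold: float = 0.5,
                         s_ref: float | None = None) -> dict:
    """Simulate and fit the full recovery/power experiment.

    Returns a dict with, per (s, Ta) condition, the batch fit results and
    the ROC against the shared neutral pool, plus Ta = 0 constrained fits
    for the requested conditions (the standard sweep-scan assumption).
    """
    if grid is None:
        grid = standard_grid()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    dist = block_distances(B, l)
    amin = min(alpha_fn(grid.r, dist.min(), s, grid.Ne) for s in grid.ss)
    amax = max(alpha_fn(grid.r, dist.max(), s, grid.Ne) for s in grid.ss)
    tables = TableSet(grid, kmax, n_nodes=n_nodes,
                      alpha_range=(amin * 0.99, amax * 1.01),
                      include_ta0=True)

    kw = {"alpha_threshold": alpha_threshold, "s_ref": s_ref}
    neutral_codes = simulate_replicate_codes(
        0.0, np.full(B, np.inf), theta, kmax, n_neutral, rng)
    fits_neutral = fit_batch(neutral_codes, dist, grid, tables, **kw)
    fits_neutral_ta0 = fit_batch(neutral_codes, dist, grid, tables,
                                 constrain_ta=0.0, **kw)

    out = {"grid": grid, "distances": dist,
           "neutral": fits_neutral, "neutral_ta0": fits_neutral_ta0,
           "conditions": {}}
    for s, ta in conditions:
        params = SweepParams(grid.Ne, s, grid.r, ta)
        alphas = np.array([params.alpha_at(d) for d in dist])
        codes = simulate_replicate_codes(ta, alphas, theta, kmax, n_sweep,
                                         rng)
        fits = fit_batch(codes, dist, grid, tables, **kw)
        roc = roc_curve(fits["delta_lncl"], fits_neutral["delta_lncl"])
        entry = {"fits": fits, "auc": roc["auc"], "roc": roc}
        if (s, ta) in tuple(constrained_conditions):
            fits0 = fit_batch(codes, dist, grid, tables, constrain_ta=0.0,
                              **kw)
            roc0 = roc_curve(fits0["delta_lncl"],
                             fits_neutral_ta0["delta_lncl"])
            entry["fits_ta0"] = fits0
            entry["auc_ta0"] = roc0["auc"]
        out["conditions"][(s, ta)] = entry
    return out
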