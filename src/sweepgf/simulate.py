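"""Coalescent simulators for sweep-linked genealogies.

Two samplers are provided:

* the **hybrid** simulator draws exactly from the analytic model behind the
  GF: neutral Kingman coalescence more recently than the sweep, an
  instantaneous partition of the surviving lineages at ``Ta`` (star-like or
  any :class:`~sweepgf.gf.PartitionModel`), and neutral coalescence beyond.
  It is the package's testing oracle and synthetic-data generator; a
  vectorized array implementation serves large replicate counts and a
  labeled per-replicate implementation returns full genealogies.

* the **trajectory** simulator runs the structured coalescent along the
  beneficial-allele frequency path (the "full model" reference): during the
  sweep, lineages on the beneficial background coalesce pairwise at rate
  1/X and recombine onto the ancestral background at rate ``2*Ne*r*d*(1-X)``
  per unit of 2*Ne generations; at the sweep's origin the remaining
  beneficial-background lineages merge into the founder.  The default
  frequency path is the deterministic logistic of duration
  ``t_fix = 2*ln(2*Ne*s)/s`` generations, symmetric about its midpoint.

Mutations are dropped on i-Ton class totals at rate ``theta/2`` per unit
branch length (the bSFS depends only on class totals); per-branch placement
is available from the labeled simulator for subsampling and topology
diagnostics.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .gf import PartitionModel
from .partition import (EmpiricalPartitionModel, ParameterError,
                        StarlikeModel, SweepParams)

__all__ = [
    "Genealogy",
    "Trajectory",
    "ReplicateDataset",
    "simulate_hybrid_genealogy",
    "hybrid_iton_sample",
    "topology_class_freqs_n4",
    "simulate_trajectory_sweep",
    "pair_sweep_outcomes",
    "simulate_blocks",
    "block_distances",
]

# root-class codes for n=4 (trifurcating roots count as symmetric when
# compared with the closed-form topology probabilities)
ROOT_SYM, ROOT_ASYM, ROOT_TRIFURC, ROOT_STAR = 0, 1, 2, 3


# ---------------------------------------------------------------------------
# labeled genealogies
# ---------------------------------------------------------------------------

@dataclass
class Genealogy:
    """A labeled genealogy: branches with carrier sets and durations."""

    n: int
    branches: list                      # (carriers frozenset, length)
    tmrca: float
    event_times: list = field(default_factory=list)
    root_children: tuple = ()           # sizes of the root's child blocks

    def iton_lengths(self) -> np.ndarray:
        out = np.zeros(self.n - 1)
        for carriers, length in self.branches:
            i = len(carriers)
            if 1 <= i <= self.n - 1:
                out[i - 1] += length
        return out

    def root_class(self) -> int:
        sizes = sorted(self.root_children, reverse=True)
        if len(sizes) == 2:
            return ROOT_SYM if sizes[0] == sizes[1] else ROOT_ASYM
        if len(sizes) == 3:
            return ROOT_TRIFURC
        return ROOT_STAR

    def drop_mutations(self, half_theta: float, rng) -> list:
        """Poisson mutations per branch; returns a list of carrier sets."""
        out = []
        for carriers, length in self.branches:
            if 1 <= len(carriers) <= self.n - 1:
                for _ in range(rng.poisson(half_theta * length)):
                    out.append(carriers)
        return out


def simulate_hybrid_genealogy(n: int, Ta: float, model: PartitionModel,
                              seed=None, rng=None) -> Genealogy:
    """Exact draw from the analytic model: Kingman / partition at Ta / Kingman."""
    if n < 2:
        raise ParameterError("n must be >= 2")
    if not isinstance(model, PartitionModel):
        raise ParameterError("model must be a PartitionModel")
    if rng is None:
        rng = np.random.default_rng(seed)
    labels = [frozenset({i}) for i in range(n)]
    birth = {l: 0.0 for l in labels}
    lineages = list(labels)
    t = 0.0
    swept = False
    branches = []
    events = []
    root_children: tuple = ()
    while len(lineages) > 1:
        k = len(lineages)
        dt = rng.exponential(2.0 / (k * (k - 1)))
        if not swept and t + dt > Ta:
            t = Ta
            swept = True
            part = _sample_partition(model, lineages, rng)
            newlin = []
            for block in part:
                if len(block) == 1:
                    newlin.append(block[0])
                else:
                    merged = frozenset().union(*block)
                    for child in block:
                        branches.append((child, t - birth[child]))
                    birth[merged] = t
                    newlin.append(merged)
            if len(newlin) == 1:
                big = max(part, key=len)
                root_children = tuple(len(c) for c in big)
            lineages = newlin
            events.append(("sweep", t))
            continue
        t += dt
        i, j = rng.choice(k, size=2, replace=False)
        a, b = lineages[i], lineages[j]
        merged = a | b
        for child in (a, b):
            branches.append((child, t - birth[child]))
        birth[merged] = t
        lineages = [x for m, x in enumerate(lineages) if m not in (i, j)]
        lineages.append(merged)
        events.append(("coal", t))
        if len(lineages) == 1:
            root_children = (len(a), len(b))
    return Genealogy(n=n, branches=branches, tmrca=t, event_times=events,
                     root_children=root_children)


def _sample_partition(model: PartitionModel, lineages: list, rng) -> list:
    """Sample a partition of the lineages; blocks are lists of lineages."""
    k = len(lineages)
    if isinstance(model, StarlikeModel):
        esc = rng.random(k) < model.pe
        singles = [[l] for l, e in zip(lineages, esc) if e]
        stay = [l for l, e in zip(lineages, esc) if not e]
        if len(stay) >= 2:
            return singles + [stay]
        return singles + [[l] for l in stay]
    if isinstance(model, EmpiricalPartitionModel):
        probs = model.shape_probs.get(k)
        if not probs:
            raise ParameterError(f"no partition law for subset size {k}")
        shapes = list(probs)
        p = np.array([probs[s] for s in shapes])
        shape = shapes[rng.choice(len(shapes), p=p / p.sum())]
        order = list(rng.permutation(k))
        out, pos = [], 0
        for sz in shape:
            out.append([lineages[order[pos + m]] for m in range(sz)])
            pos += sz
        return out
    raise ParameterError(f"cannot sample from model {model!r}")


# ---------------------------------------------------------------------------
# vectorized hybrid sampler (star-like)
# ---------------------------------------------------------------------------

def hybrid_iton_sample(n: int, alpha, Ta, reps: int, seed=None, rng=None,
                       want_root: bool = False):
    """Vectorized exact sampler of the star-like hybrid model.

    ``alpha`` and ``Ta`` may be scalars or per-replicate arrays (so a whole
    blockwise dataset can be drawn in one call).  Returns a dict with i-Ton
    class totals ``titon`` (reps, n-1), ``tmrca`` (reps,), and for n=4
    optionally the root-class codes.
    """
    if n < 2:
        raise ParameterError("n must be >= 2")
    if rng is None:
        rng = np.random.default_rng(seed)
    al = np.broadcast_to(np.asarray(alpha, dtype=float), (reps,))
    if np.any(al[np.isfinite(al)] < 0):
        raise ParameterError("alpha must be non-negative")
    pe = -np.expm1(-al)
    pe = np.where(np.isfinite(al), pe, 1.0)
    ta = np.broadcast_to(np.asarray(Ta, dtype=float), (reps,))

    sizes = np.ones((reps, n), dtype=np.int64)
    t = np.zeros(reps)
    swept = np.zeros(reps, dtype=bool)
    titon = np.zeros((reps, n - 1))
    tmrca = np.zeros(reps)
    root = np.full(reps, -1, dtype=np.int8)
    active = np.ones(reps, dtype=bool)

    while active.any():
        idx = np.nonzero(active)[0]
        sz = sizes[idx]
        k = (sz > 0).sum(axis=1)
        rate = k * (k - 1) / 2.0
        dt = rng.exponential(1.0, size=idx.size) / rate
        tnew = t[idx] + dt
        cross = (~swept[idx]) & (tnew > ta[idx])

        # --- sweep crossing: advance to Ta and apply the partition --------
        cidx = idx[cross]
        if cidx.size:
            dtc = ta[cidx] - t[cidx]
            _accumulate(titon, sizes, cidx, dtc, n)
            t[cidx] = ta[cidx]
            swept[cidx] = True
            alive = sizes[cidx] > 0
            esc = (rng.random((cidx.size, n)) < pe[cidx, None]) & alive
            stay = alive & ~esc
            nstay = stay.sum(axis=1)
            merge = nstay >= 2
            if merge.any():
                rows = np.nonzero(merge)[0]
                sub = sizes[cidx]                       # fancy-index copy
                stay_m = stay[rows]
                stay_sizes = np.where(stay_m, sub[rows], 0)
                msz = stay_sizes.sum(axis=1)
                first = stay_m.argmax(axis=1)
                tmp = sub[rows]
                tmp[stay_m] = 0
                tmp[np.arange(rows.size), first] = msz
                sub[rows] = tmp
                sizes[cidx] = sub
                done = msz == n
                if done.any():
                    drows = rows[done]
                    gidx = cidx[drows]
                    tmrca[gidx] = ta[gidx]
                    active[gidx] = False
                    if want_root:
                        ns = nstay[drows]
                        mx = stay_sizes[done].max(axis=1)
                        code = np.full(drows.size, ROOT_STAR, dtype=np.int8)
                        code[ns == 3] = ROOT_TRIFURC
                        code[(ns == 2) & (mx * 2 == n)] = ROOT_SYM
                        code[(ns == 2) & (mx * 2 != n)] = ROOT_ASYM
                        root[gidx] = code

        # --- ordinary coalescence ----------------------------------------
        nidx = idx[~cross]
        if nidx.size:
            dtn = dt[~cross]
            _accumulate(titon, sizes, nidx, dtn, n)
            t[nidx] = tnew[~cross]
            kk = (sizes[nidx] > 0).sum(axis=1)
            u1 = rng.integers(0, kk)
            u2 = rng.integers(0, kk - 1)
            u2 = u2 + (u2 >= u1)
            order = np.argsort(sizes[nidx] <= 0, axis=1, kind="stable")
            r = np.arange(nidx.size)
            c1 = order[r, u1]
            c2 = order[r, u2]
            s1 = sizes[nidx, c1]
            s2 = sizes[nidx, c2]
            sizes[nidx, c1] = s1 + s2
            sizes[nidx, c2] = 0
            fin = kk == 2
            if fin.any():
                frows = np.nonzero(fin)[0]
                gidx = nidx[frows]
                tmrca[gidx] = t[gidx]
                active[gidx] = False
                if want_root:
                    mx = np.maximum(s1[frows], s2[frows])
                    root[gidx] = np.where(mx * 2 == n, ROOT_SYM, ROOT_ASYM)

    out = {"titon": titon, "tmrca": tmrca}
    if want_root:
        out["root"] = root
    return out


def _accumulate(titon, sizes, rows, dt, n):
    for i in range(1, n):
        titon[rows, i - 1] += dt * (sizes[rows] == i).sum(axis=1)


def topology_class_freqs_n4(model, Ta: float, reps: int = 200_000, seed=None):
    """Monte-Carlo root-class frequencies (Psym, Pasym, Pstar) for n=4.

    Trifurcating roots are pooled with the symmetric class, the convention
    under which the closed-form expressions sum to one.
    """
    if isinstance(model, StarlikeModel):
        res = hybrid_iton_sample(4, model.alpha, Ta, reps, seed=seed,
                                 want_root=True)
        rc = res["root"]
    else:
        rng = np.random.default_rng(seed)
        rc = np.empty(reps, dtype=np.int8)
        for i in range(reps):
            g = simulate_hybrid_genealogy(4, Ta, model, rng=rng)
            rc[i] = g.root_class()
    psym = ((rc == ROOT_SYM) | (rc == ROOT_TRIFURC)).mean()
    pasym = (rc == ROOT_ASYM).mean()
    pstar = (rc == ROOT_STAR).mean()
    return psym, pasym, pstar


# ---------------------------------------------------------------------------
# structured coalescent along the sweep trajectory
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Beneficial-allele frequency path, pastward from fixation.

    ``times`` are in generations since fixation (increasing pastward) and
    ``X`` decreases from ~1 at fixation to 1/(2*Ne) at the origin.
    """

    times: np.ndarray
    X: np.ndarray

    def __post_init__(self):
        if np.any(np.diff(self.X) > 1e-12):
            raise ParameterError("X must be non-increasing pastward")

    @classmethod
    def logistic(cls, params: SweepParams, step: float = 1.0) -> "Trajectory":
        """Deterministic logistic path of duration t_fix, symmetric about
        its midpoint (so the integrated heterozygosity matches alpha)."""
        tfix = params.t_fix
        times = np.linspace(0.0, tfix, max(int(math.ceil(tfix / step)), 2) + 1)
        X = 1.0 / (1.0 + np.exp(params.s * (times - tfix / 2.0)))
        return cls(times=times, X=X)


def simulate_trajectory_sweep(n: int, params: SweepParams, d: float,
                              seed=None, rng=None,
                              trajectory: Trajectory | None = None
                              ) -> Genealogy:
    """Structured coalescent along the frequency path (full-model reference).

    Pastward: neutral Kingman on [0, Ta); during the sweep, beneficial-
    background lineages coalesce pairwise at rate 1/X and escape at rate
    2*Ne*r*d*(1-X) (per 2*Ne generations), escaped lineages coalesce among
    themselves at rate 1/(1-X); the sweep's origin forces the remaining
    beneficial lineages into the founder; the pre-sweep epoch is neutral.
    Time steps of one generation discretize the sweep phase.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if trajectory is None:
        trajectory = Trajectory.logistic(params)
    Ta = params.Ta
    twoN = 2.0 * params.Ne
    labels = [frozenset({i}) for i in range(n)]
    birth = {l: 0.0 for l in labels}
    branches = []
    events = []

    # phase 1: neutral Kingman on [0, Ta)
    root_children: tuple = ()
    lineages = list(labels)
    t = 0.0
    while len(lineages) > 1:
        k = len(lineages)
        dt = rng.exponential(2.0 / (k * (k - 1)))
        if t + dt > Ta:
            break
        t += dt
        lineages, birth, branches, pair = _merge_pair(lineages, birth,
                                                      branches, t, rng)
        events.append(("coal", t))
        if len(lineages) == 1:
            root_children = tuple(len(b) for b in pair)
    if len(lineages) > 1:
        # phase 2: the sweep, pastward from fixation at coalescent time Ta
        ben = list(lineages)     # all lineages sit on the beneficial background
        escd: list = []
        rd = params.r * d
        times, X = trajectory.times, trajectory.X
        for gi in range(len(times) - 1):
            dtg = (times[gi + 1] - times[gi])        # generations
            dtc = dtg / twoN                         # coalescent units
            x = X[gi]
            tnow = Ta + times[gi] / twoN
            if len(ben) >= 2:
                p = -math.expm1(-len(ben) * (len(ben) - 1) / 2.0 / x * dtc)
                if rng.random() < p:
                    ben, birth, branches, pair = _merge_pair(
                        ben, birth, branches, tnow, rng)
                    events.append(("sweep-coal", tnow))
                    if len(ben) + len(escd) == 1:
                        root_children = tuple(len(b) for b in pair)
            if ben and rd > 0:
                pesc = -math.expm1(-twoN * rd * (1 - x) * dtc)
                keep = []
                for l in ben:
                    if rng.random() < pesc:
                        escd.append(l)
                        events.append(("escape", tnow))
                    else:
                        keep.append(l)
                ben = keep
            if len(escd) >= 2 and x < 1.0:
                p = -math.expm1(
                    -len(escd) * (len(escd) - 1) / 2.0 / (1 - x) * dtc)
                if rng.random() < p:
                    escd, birth, branches, pair = _merge_pair(
                        escd, birth, branches, tnow, rng)
                    events.append(("coal", tnow))
                    if len(ben) + len(escd) == 1:
                        root_children = tuple(len(b) for b in pair)
        t_origin = Ta + times[-1] / twoN
        if len(ben) >= 2:
            merged = frozenset().union(*ben)
            for child in ben:
                branches.append((child, t_origin - birth[child]))
            birth[merged] = t_origin
            if not escd:
                root_children = tuple(len(b) for b in ben)
            ben = [merged]
            events.append(("founder", t_origin))
        lineages = ben + escd
        t = t_origin

        # phase 3: neutral Kingman before the sweep's origin
        while len(lineages) > 1:
            k = len(lineages)
            t += rng.exponential(2.0 / (k * (k - 1)))
            lineages, birth, branches, pair = _merge_pair(lineages, birth,
                                                          branches, t, rng)
            events.append(("coal", t))
            if len(lineages) == 1:
                root_children = tuple(len(b) for b in pair)
    return Genealogy(n=n, branches=branches, tmrca=t, event_times=events,
                     root_children=root_children)


def _merge_pair(lineages, birth, branches, t, rng):
    k = len(lineages)
    i, j = rng.choice(k, size=2, replace=False)
    a, b = lineages[i], lineages[j]
    merged = a | b
    for child in (a, b):
        branches.append((child, t - birth[child]))
    birth[merged] = t
    out = [x for m, x in enumerate(lineages) if m not in (i, j)]
    out.append(merged)
    return out, birth, branches, (a, b)


def pair_sweep_outcomes(params: SweepParams, d: float, reps: int, seed=None):
    """Vectorized pair outcomes through the sweep phase alone.

    Both lineages enter the sweep on the beneficial background.  Returns the
    fraction that fail to escape (coalesce during the sweep, including the
    forced founder merger) and, for those, the pastward coalescence time as
    a fraction of t_fix.
    """
    rng = np.random.default_rng(seed)
    traj = Trajectory.logistic(params)
    twoN = 2.0 * params.Ne
    rd = params.r * d
    nben = np.full(reps, 2, dtype=np.int8)
    coal_u = np.full(reps, np.nan)
    times, X = traj.times, traj.X
    for gi in range(len(times) - 1):
        dtg = times[gi + 1] - times[gi]
        x = 0.5 * (X[gi] + X[gi + 1])      # midpoint frequency for the step
        lc = 1.0 / (twoN * x)              # pair coalescence rate per gen
        le = rd * (1 - x)                  # escape rate per lineage per gen
        pair = nben == 2
        if pair.any():
            # competing risks within the step: total rate lc + 2*le
            tot = lc + 2 * le
            pev = -math.expm1(-tot * dtg)
            u = rng.random(reps)
            ev = pair & (u < pev)
            ucoal = rng.random(reps) < lc / tot
            hit = ev & ucoal
            coal_u[hit] = times[gi]
            nben[hit] = 0
            esc1 = ev & ~ucoal
            nben[esc1] -= 1
        single = nben == 1
        if single.any() and le > 0:
            pe = -math.expm1(-le * dtg)
            drop = single & (rng.random(reps) < pe)
            nben[drop] -= 1
    both_left = nben == 2
    coal_u[both_left] = times[-1]
    failed = ~np.isnan(coal_u)
    return {
        "fail_to_escape": failed.mean(),
        "coal_frac_of_tfix": coal_u[failed] / params.t_fix,
        "t_fix": params.t_fix,
    }


# ---------------------------------------------------------------------------
# blockwise replicate datasets
# ---------------------------------------------------------------------------

def block_distances(B: int, l: float) -> np.ndarray:
    """Physical distances of B blocks of length l flanking the sweep target.

    Blocks are laid out contiguously outward on both sides; block i has
    center distance i*l - l/2.
    """
    if B % 2:
        raise ParameterError("B must be even (blocks split left/right)")
    if l < 1:
        raise ParameterError("block length must be >= 1")
    one_side = (np.arange(1, B // 2 + 1) * l) - l / 2.0
    return np.concatenate([one_side[::-1], one_side])


@dataclass
class ReplicateDataset:
    """Per-block, per-subsample observed bSFS configurations."""

    distances: np.ndarray          # (B,)
    alphas: np.ndarray             # (B,) scaled distances (inf for neutral)
    configs: np.ndarray            # (B, S, 3) capped counts, S subsamples
    kmax: int
    n: int
    x: int
    mode: str
    provenance: dict = field(default_factory=dict)

    @property
    def B(self) -> int:
        return self.configs.shape[0]

    def codes(self) -> np.ndarray:
        from .observables import BsfsTable

        return BsfsTable.config_code(self.configs, self.kmax)

    def to_tsv(self, path):
        sidecar = str(path) + ".json"
        with open(sidecar, "w") as fh:
            json.dump({"kmax": self.kmax, "n": self.n, "x": self.x,
                       "mode": self.mode, "provenance": self.provenance},
                      fh, indent=1)
        with open(path, "w") as fh:
            fh.write("block\tdistance\talpha\tsubsample\tk1\tk2\tk3\n")
            for b in range(self.B):
                for s in range(self.configs.shape[1]):
                    k1, k2, k3 = self.configs[b, s]
                    fh.write(f"{b}\t{self.distances[b]:.10g}\t"
                             f"{self.alphas[b]:.10g}\t{s}\t{k1}\t{k2}\t{k3}\n")

    @classmethod
    def from_tsv(cls, path) -> "ReplicateDataset":
        sidecar = str(path) + ".json"
        with open(sidecar) as fh:
            meta = json.load(fh)
        rows = np.loadtxt(path, skiprows=1,
                          dtype=[("b", int), ("d", float), ("a", float),
                                 ("s", int), ("k1", int), ("k2", int),
                                 ("k3", int)])
        rows = np.atleast_1d(rows)
        B = int(rows["b"].max()) + 1
        S = int(rows["s"].max()) + 1
        cfg = np.zeros((B, S, 3), dtype=np.uint8)
        dist = np.zeros(B)
        alph = np.zeros(B)
        for row in rows:
            cfg[row["b"], row["s"]] = (row["k1"], row["k2"], row["k3"])
            dist[row["b"]] = row["d"]
            alph[row["b"]] = row["a"]
        return cls(distances=dist, alphas=alph, configs=cfg,
                   kmax=meta["kmax"], n=meta["n"], x=meta["x"],
                   mode=meta["mode"], provenance=meta["provenance"])


def simulate_blocks(params: SweepParams, geometry: tuple, n: int, mut,
                    mode: str = "sweep", seed=None, x: int = 4,
                    model_kind: str = "star-like",
                    yule_model: EmpiricalPartitionModel | None = None
                    ) -> ReplicateDataset:
    """Simulate one blockwise replicate dataset (independent genealogies).

    ``geometry = (B, l)``: B blocks of l bases flanking the target.  In
    sweep mode each block's genealogy is drawn at its own alpha; neutral
    mode ignores the sweep.  For n == x the fast class-total path is used;
    for n > x genealogies are labeled, mutations are placed on branches and
    all C(n, x) subsamples are tabulated.
    """
    B, l = geometry
    rng = np.random.default_rng(seed)
    dist = block_distances(B, l)
    if mode == "sweep":
        alphas = np.array([params.alpha_at(di) for di in dist])
    elif mode == "neutral":
        alphas = np.full(B, np.inf)
    else:
        raise ParameterError("mode must be 'sweep' or 'neutral'")
    prov = {"Ne": params.Ne, "s": params.s, "r": params.r, "Ta": params.Ta,
            "theta": mut.theta, "kmax": mut.kmax, "B": B, "l": l,
            "n": n, "x": x, "mode": mode, "model": model_kind,
            "seed": None if seed is None else str(seed)}
    if n == x and model_kind == "star-like":
        res = hybrid_iton_sample(n, alphas, params.Ta, B, rng=rng)
        k = rng.poisson(mut.theta / 2.0 * res["titon"])
        cfg = np.minimum(k, mut.kmax + 1).astype(np.uint8)[:, None, :]
        return ReplicateDataset(distances=dist, alphas=alphas, configs=cfg,
                                kmax=mut.kmax, n=n, x=x, mode=mode,
                                provenance=prov)
    # labeled path: per-branch mutation placement, subsample projection
    from itertools import combinations

    subs = list(combinations(range(n), x))
    cfg = np.zeros((B, len(subs), 3), dtype=np.uint8)
    for b in range(B):
        if mode == "neutral" or not math.isfinite(alphas[b]):
            model: PartitionModel = StarlikeModel(np.inf)
        elif model_kind == "star-like":
            model = StarlikeModel(alphas[b])
        else:
            if yule_model is None:
                raise ParameterError("yule model required for model_kind="
                                     "'yule'")
            model = yule_model
        g = simulate_hybrid_genealogy(n, params.Ta, model, rng=rng)
        muts = g.drop_mutations(mut.theta / 2.0, rng)
        for si, sub in enumerate(subs):
            ss = set(sub)
            counts = np.zeros(3, dtype=int)
            for carriers in muts:
                c = len(carriers & ss)
                if 1 <= c <= x - 1:
                    counts[c - 1] += 1
            cfg[b, si] = np.minimum(counts, mut.kmax + 1)
    return ReplicateDataset(distances=dist, alphas=alphas, configs=cfg,
                            kmax=mut.kmax, n=n, x=x, mode=mode,
                            provenance=prov)
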