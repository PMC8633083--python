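"""Closed-form observables of genealogies linked to a sweep of age Ta.

All quantities are functions of the scaled recombination distance ``alpha``
(or a partition model) and the sweep age ``Ta`` in units of 2*Ne generations:
the expected pairwise coalescence time and its full distribution, the
expected site frequency spectrum, the probabilities of the three genealogical
topology classes for samples of four, the marginal distributions of i-Ton
branch lengths, and the probabilities of blockwise mutation configurations
(the blockwise SFS, bSFS).

Mutation convention: ``theta = 4*Ne*mu*l`` for a block of ``l`` bases, and
mutations of i-Ton type accrue at rate ``theta/2`` per unit of i-Ton branch
length on the 2*Ne-generation time scale, so a neutral pair carries
``E[pairwise differences] = theta``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache
from itertools import combinations

import numpy as np

from .gf import GFError, gf_with_sweep, make_sample, neutral_gf
from .partition import (ParameterError, StarlikeModel, escape_probability)

__all__ = [
    "MutationModel",
    "PiecewiseExpDensity",
    "BsfsTable",
    "expected_tmrca",
    "expected_tmrca_gf",
    "tmrca_distribution",
    "expected_sfs",
    "topology_probs_n4",
    "iton_marginal_distribution",
    "bsfs_probabilities",
    "neutral_bsfs_probabilities",
]


@dataclass(frozen=True)
class MutationModel:
    """Scaled block mutation rate theta = 4*Ne*mu*l and the bSFS cap k_max."""

    theta: float
    kmax: int = 2

    def __post_init__(self):
        if not self.theta > 0:
            raise ParameterError("theta must be positive")
        if self.kmax < 0:
            raise ParameterError("kmax must be non-negative")


# ---------------------------------------------------------------------------
# cached GF construction
# ---------------------------------------------------------------------------

_GF_CACHE: dict = {}


def sweep_iton_gf(n: int, model) -> "GFExpr":
    """Inverted, i-Ton-collapsed sweep GF, cached by model structure."""
    key = ("sweep", n, model.signature() if model.kind != "star-like"
           else ("star-like",))
    if key not in _GF_CACHE:
        gf = gf_with_sweep(make_sample(n), model)
        _GF_CACHE[key] = gf.collapse_to_iton().invert_delta()
    return _GF_CACHE[key]


def neutral_iton_gf(n: int) -> "GFExpr":
    key = ("neutral", n)
    if key not in _GF_CACHE:
        _GF_CACHE[key] = neutral_gf(make_sample(n)).collapse_to_iton()
    return _GF_CACHE[key]


def _marginalized(gf, subset: frozenset, nvars: int):
    """GF with the i-Ton variables in ``subset`` set to zero, cached."""
    cache = getattr(gf, "_marg_cache", None)
    if cache is None:
        cache = {}
        gf._marg_cache = cache
    if subset not in cache:
        g = gf
        for i in sorted(subset):
            g = g.subs(i, 0.0)
        cache[subset] = g
    return cache[subset]


# ---------------------------------------------------------------------------
# pairwise diversity and the tmrca distribution
# ---------------------------------------------------------------------------

def expected_tmrca(alpha: float, Ta: float, ta_correction: float = 0.0) -> float:
    """E[tmrca] = 1 - exp(-Ta - 2*alpha) for a pair, in 2*Ne generations.

    ``ta_correction`` (default off) adds t_fix/(2*Ne) to Ta to correct for
    the sweep's duration: the burst of coalescence sits at the origin, not
    the completion, of the sweep.
    """
    if alpha < 0 or Ta < 0:
        raise ParameterError("alpha and Ta must be non-negative")
    return 1.0 - math.exp(-(Ta + ta_correction) - 2.0 * alpha)


def expected_tmrca_gf(alpha: float, Ta: float) -> float:
    """E[tmrca] recomputed from the GF by differentiation (dual path)."""
    model = StarlikeModel(alpha)
    key = ("tmrca2",)
    if key not in _GF_CACHE:
        gf = gf_with_sweep(make_sample(2), StarlikeModel(0.0))
        _GF_CACHE[key] = gf.collapse_time("w").invert_delta().diff("w")
    return -_GF_CACHE[key].evaluate({"w": 0.0}, Ta=Ta, model=model)


def tmrca_distribution(alpha: float, Ta: float,
                       ta_correction: float = 0.0) -> "PiecewiseExpDensity":
    """Distribution of the pairwise tmrca near a sweep of age Ta.

    Density exp(-t) below Ta (the sweep cannot affect the genealogy more
    recently than it happened), an atom of size exp(-Ta-2*alpha) at t = Ta
    (the instantaneous burst of coalescence), and the neutral density scaled
    by the probability 1-P_{0,2} that at least one lineage escapes beyond.
    """
    if alpha < 0 or Ta < 0:
        raise ParameterError("alpha and Ta must be non-negative")
    ta = Ta + ta_correction
    p02 = math.exp(-2.0 * alpha)
    mass = math.exp(-ta) * p02
    if ta == 0.0:
        breaks = [0.0]
        pieces = [[(1.0 - p02, 0, 1.0)]]
    else:
        breaks = [0.0, ta]
        pieces = [[(1.0, 0, 1.0)], [(1.0 - p02, 0, 1.0)]]
    masses = [(ta, mass)] if mass > 0 else []
    return PiecewiseExpDensity(breaks, pieces, masses)


# ---------------------------------------------------------------------------
# piecewise exponential densities with atoms
# ---------------------------------------------------------------------------

def _int_poly_exp(c: float, q: int, d: float, u: float, v: float) -> float:
    """Integral of c * t^q * exp(-d*t) over [u, v] (v may be inf)."""
    if d == 0.0:
        hi = v ** (q + 1) if math.isfinite(v) else math.inf
        return c * (hi - u ** (q + 1)) / (q + 1)

    def anti(t):
        # antiderivative -exp(-d t) * sum_r q!/(q-r)! t^(q-r) / d^(r+1)
        if not math.isfinite(t):
            return 0.0 if d > 0 else math.copysign(math.inf, -c)
        s = 0.0
        for r in range(q + 1):
            s += (math.factorial(q) / math.factorial(q - r)
                  * t ** (q - r) / d ** (r + 1))
        return -math.exp(-d * t) * s

    return c * (anti(v) - anti(u))


class PiecewiseExpDensity:
    """Density that is a sum of c*t^q*exp(-d*t) pieces per interval, plus atoms.

    ``breaks`` are the ordered interval boundaries starting at 0 (the last
    interval extends to infinity); ``pieces[i]`` is a list of ``(c, q, d)``
    triples on ``[breaks[i], breaks[i+1])``.  Atoms are kept explicitly and
    are reflected in the CDF, never smeared into the density.
    """

    def __init__(self, breaks, pieces, masses):
        if not breaks or breaks[0] != 0.0:
            raise GFError("breakpoints must start at 0")
        if any(b2 <= b1 for b1, b2 in zip(breaks, breaks[1:])):
            raise GFError("breakpoints must be strictly increasing")
        self.breaks = list(map(float, breaks))
        self.pieces = [list(p) for p in pieces]
        self.masses = sorted((float(l), float(m)) for l, m in masses
                             if m > 1e-14)
        if len(self.pieces) != len(self.breaks):
            raise GFError("need one piece list per interval")

    @classmethod
    def from_components(cls, masses: dict, comps: list,
                        tol: float = 1e-9) -> "PiecewiseExpDensity":
        """Assemble from shifted components (shift, coef, k, rate).

        Each component is ``coef*(t-shift)^k*exp(-rate*(t-shift))`` on
        ``t >= shift``.  Within each interval the shifted pieces are expanded
        in absolute t and merged; on the final (unbounded) interval any
        non-decaying exponents must cancel, which is asserted.
        """
        atom_locs = [l for l, m in masses.items() if abs(m) > 1e-12]
        shifts = sorted({0.0} | {round(s, 12) for s, *_ in comps})
        scale = max([abs(c) for _, c, _, _ in comps], default=1.0)
        breaks = shifts
        pieces = []
        nb = len(breaks)
        for bi in range(nb):
            lo = breaks[bi]
            acc: dict = {}
            for tau, coef, k, d in comps:
                if round(tau, 12) > lo + 1e-12:
                    continue
                # (t-tau)^k e^{-d(t-tau)} = e^{d tau} sum_q C(k,q)(-tau)^{k-q} t^q e^{-dt}
                damp = math.exp(d * tau)
                for q in range(k + 1):
                    cc = coef * math.comb(k, q) * (-tau) ** (k - q) * damp
                    key = (q, round(d, 10))
                    acc[key] = acc.get(key, 0.0) + cc
            plist = []
            for (q, d), c in acc.items():
                if abs(c) < tol * scale * 1e-3:
                    continue
                if bi == nb - 1 and d <= 1e-12:
                    if abs(c) > tol * scale:
                        raise GFError(
                            f"non-decaying tail component survives: {c, q, d}")
                    continue
                plist.append((c, q, d))
            pieces.append(sorted(plist, key=lambda x: (x[2], x[1])))
        atoms = [(l, m) for l, m in sorted(masses.items()) if m > 1e-14]
        for l, m in masses.items():
            if m < -1e-9:
                raise GFError(f"negative point mass {m} at {l}")
        return cls(breaks, pieces, atoms)

    # -- evaluation ---------------------------------------------------------
    def pdf(self, t):
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        idx = np.clip(np.searchsorted(self.breaks, t, side="right") - 1,
                      0, len(self.breaks) - 1)
        for i, plist in enumerate(self.pieces):
            sel = idx == i
            if not sel.any():
                continue
            ts = t[sel]
            val = np.zeros_like(ts)
            for c, q, d in plist:
                val += c * ts ** q * np.exp(-d * ts)
            out[sel] = val
        out[t < 0] = 0.0
        return out if out.ndim else float(out)

    def cdf(self, t):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.zeros_like(t)
        edges = self.breaks + [math.inf]
        for i, plist in enumerate(self.pieces):
            lo, hi = edges[i], edges[i + 1]
            full = math.fsum(_int_poly_exp(c, q, d, lo, hi)
                             for c, q, d in plist)
            for j, tj in enumerate(t):
                if tj >= hi:
                    out[j] += full
                elif tj > lo:
                    out[j] += math.fsum(_int_poly_exp(c, q, d, lo, tj)
                                        for c, q, d in plist)
        for loc, m in self.masses:
            out[t >= loc - 1e-12] += m
        res = np.clip(out, 0.0, None)
        return res if res.shape != (1,) else float(res[0])

    def total_mass(self) -> float:
        edges = self.breaks + [math.inf]
        cont = math.fsum(_int_poly_exp(c, q, d, edges[i], edges[i + 1])
                         for i, plist in enumerate(self.pieces)
                         for c, q, d in plist)
        return cont + math.fsum(m for _, m in self.masses)

    def mean(self) -> float:
        edges = self.breaks + [math.inf]
        cont = math.fsum(_int_poly_exp(c, q + 1, d, edges[i], edges[i + 1])
                         for i, plist in enumerate(self.pieces)
                         for c, q, d in plist)
        return cont + math.fsum(l * m for l, m in self.masses)

    def discontinuities(self, tol: float = 1e-8) -> list:
        """Atom locations plus breakpoints of the piecewise representation.

        A breakpoint counts when the functional form genuinely changes
        across it (the per-(power, rate) coefficients differ), which
        includes both jump discontinuities of the PDF and removable ones
        where only higher derivatives jump.
        """
        locs = {round(l, 10) for l, _ in self.masses}
        scale = max([abs(c) for p in self.pieces for c, _, _ in p],
                    default=1.0)
        for i, b in enumerate(self.breaks[1:], start=1):
            left = {(q, d): c for c, q, d in self.pieces[i - 1]}
            right = {(q, d): c for c, q, d in self.pieces[i]}
            keys = set(left) | set(right)
            if any(abs(left.get(k, 0.0) - right.get(k, 0.0)) > tol * scale
                   for k in keys):
                locs.add(round(b, 10))
        return sorted(locs)

    def to_tsv(self, path, grid=None, meta: dict | None = None):
        """Write pdf/cdf on a grid as TSV with a JSON metadata header line."""
        if grid is None:
            hi = max(self.breaks[-1] * 2.0, 5.0)
            grid = np.linspace(0.0, hi, 501)
        grid = np.asarray(grid, dtype=float)
        with open(path, "w") as fh:
            fh.write("# " + json.dumps(
                {"masses": self.masses, "breaks": self.breaks,
                 **(meta or {})}) + "\n")
            fh.write("t\tpdf\tcdf\n")
            pdf = self.pdf(grid)
            cdf = np.atleast_1d(self.cdf(grid))
            for t, p, c in zip(grid, pdf, cdf):
                fh.write(f"{t:.10g}\t{p:.10g}\t{c:.10g}\n")


# ---------------------------------------------------------------------------
# expected SFS: marginal-moments path (scales to n ~ 10)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _tavare_coefs(n: int, k: int):
    """Exact coefficients of P(A_n(t)=k) = sum_j c_jk exp(-j(j-1)t/2)."""
    out = []
    for j in range(k, n + 1):
        num = Fraction(2 * j - 1) * (-1) ** (j - k)
        # rising k_(j-1), falling n_[j], rising n_(j)
        rk = math.prod(range(k, k + j - 1)) if j > 1 else 1
        fn = math.prod(range(n - j + 1, n + 1))
        rn = math.prod(range(n, n + j))
        c = num * rk * fn / (Fraction(math.factorial(k))
                             * math.factorial(j - k) * rn)
        out.append((j, c))
    return tuple(out)


def lineage_count_pmf(n: int, k: int, t: float) -> float:
    """P(a sample of n has k ancestral lineages time t ago), neutral Kingman."""
    return float(sum(float(c) * math.exp(-j * (j - 1) / 2.0 * t)
                     for j, c in _tavare_coefs(n, k)))


def _occupancy(n: int, k: int, T: float) -> float:
    """Integral over [0, T] of P(A_n(t)=k): expected time with k lineages."""
    tot = 0.0
    for j, c in _tavare_coefs(n, k):
        lam = j * (j - 1) / 2.0
        tot += float(c) * (T if lam == 0 else -math.expm1(-lam * T) / lam)
    return tot


def _q_subtend(i: int, k: int, n: int) -> float:
    """P(a given one of k ancestral lineages subtends i of n samples)."""
    if k == 1:
        return 1.0 if i == n else 0.0
    if i > n - k + 1:
        return 0.0
    return math.comb(n - i - 1, k - 2) / math.comb(n - 1, k - 1)


def _partitions(n: int, k: int):
    """Unordered partitions of n into exactly k positive parts."""
    def rec(rem, k, maxp):
        if k == 1:
            if rem <= maxp:
                yield (rem,)
            return
        for p in range(min(rem - k + 1, maxp), 0, -1):
            for tail in rec(rem - p, k - 1, p):
                yield (p,) + tail
    yield from rec(n, k, n)


def _subset_sum_counts(blocks: tuple, n: int):
    """N[j][i] = number of j-subsets of the block multiset with size-sum i."""
    K = len(blocks)
    N = np.zeros((K + 1, n + 1))
    N[0, 0] = 1.0
    for b in blocks:
        N2 = N.copy()
        N2[1:, b:] += N[:-1, :-(b) or None]
        N = N2
    return N


def _post_sweep_sfs(blocks: tuple, n: int) -> np.ndarray:
    """Expected i-Ton lengths from a neutral coalescent over labeled blocks.

    The surviving lineages subtend ``blocks`` samples each; while kappa of
    them remain the expected duration is 2/(kappa*(kappa-1)) and a given
    lineage subtends j of the K blocks with the usual Kingman probability,
    each j-subset being equally likely.
    """
    K = len(blocks)
    out = np.zeros(n + 1)
    if K < 2:
        return out[1:n]
    N = _subset_sum_counts(blocks, n)
    for kappa in range(2, K + 1):
        dur = 2.0 / (kappa * (kappa - 1))
        for j in range(1, K):
            pj = _q_subtend(j, kappa, K)
            if pj == 0.0:
                continue
            w = dur * kappa * pj / math.comb(K, j)
            out += w * N[j]
    return out[1:n]


def expected_sfs(n: int, alpha: float, Ta: float,
                 ta_correction: float = 0.0) -> np.ndarray:
    """Expected SFS (i-Ton proportions, i=1..n-1) near a sweep of age Ta.

    Uses the marginal-moments decomposition rather than the full joint GF,
    so it scales to n ~ 10: i-Ton branch lengths accrue during the neutral
    phase more recent than the sweep (lineage-count occupancy times), and
    after the instantaneous partition of the survivors the remaining blocks
    coalesce neutrally.  The star-like partition law is assumed.
    """
    if not 2 <= n <= 10:
        raise ParameterError("expected_sfs supports 2 <= n <= 10")
    ta = Ta + ta_correction
    if alpha == 0.0 and ta == 0.0:
        raise ParameterError(
            "alpha=0 and Ta=0 give a zero-length tree: the SFS is undefined")
    pe = escape_probability(alpha)
    et = np.zeros(n - 1)
    # (1) neutral accumulation on [0, Ta)
    for k in range(2, n + 1):
        occ = _occupancy(n, k, ta)
        if occ <= 0.0:
            continue
        for i in range(1, n):
            et[i - 1] += occ * k * _q_subtend(i, k, n)
    # (2) survivors at Ta, their family sizes, the partition, and the
    # neutral continuation
    for k in range(2, n + 1):
        pk = lineage_count_pmf(n, k, ta)
        if pk < 1e-15:
            continue
        ncomp = math.comb(n - 1, k - 1)
        for part in _partitions(n, k):
            mult = {}
            for p in part:
                mult[p] = mult.get(p, 0) + 1
            w_part = (math.factorial(k)
                      // math.prod(math.factorial(m) for m in mult.values())
                      ) / ncomp
            sizes = sorted(mult)
            ranges = [range(mult[s] + 1) for s in sizes]
            for esc in np.ndindex(*[len(r) for r in ranges]):
                w_esc = 1.0
                escaped, stay = [], []
                for sz, e in zip(sizes, esc):
                    m = mult[sz]
                    w_esc *= math.comb(m, e) * pe ** e * (1 - pe) ** (m - e)
                    escaped += [sz] * e
                    stay += [sz] * (m - e)
                if w_esc == 0.0:
                    continue
                if len(stay) >= 2:
                    blocks = tuple(escaped + [sum(stay)])
                else:
                    blocks = tuple(escaped + stay)
                et += pk * w_part * w_esc * _post_sweep_sfs(blocks, n)
    tot = et.sum()
    if tot <= 0.0:
        raise ParameterError("degenerate tree: total branch length is zero")
    return et / tot


def expected_iton_lengths_gf(n: int, alpha: float, Ta: float) -> np.ndarray:
    """E[t_i] from the full GF (first derivatives); cross-check path, n <= 6."""
    model = StarlikeModel(alpha)
    gf = sweep_iton_gf(n, model)
    tv = list(range(1, n))
    C = gf.taylor(tv, [0.0] * (n - 1), [1] * (n - 1), Ta=Ta, model=model)
    out = np.empty(n - 1)
    for i in range(1, n):
        idx = tuple(1 if j == i else 0 for j in range(1, n))
        out[i - 1] = -C[idx]
    return out


# ---------------------------------------------------------------------------
# topology class probabilities, n = 4
# ---------------------------------------------------------------------------

def topology_probs_n4(alpha: float, Ta: float, model=None,
                      ta_correction: float = 0.0):
    """(Psym, Pasym, Pstar) for n=4 under the star-like approximation.

    Classes are defined by the root node: a symmetric {2,2} or asymmetric
    {3,1} bipartition, or a root without any bipartition (the simultaneous
    merger of all four lineages during the sweep),
    ``Pstar = exp(-6*Ta)*P_{0,4}``.  A trifurcating root (three lineages at
    the sweep, none escaping) is counted with the symmetric class, the
    convention under which the three closed forms sum to one.

    Only the star-like law admits these closed forms; for an empirical
    (marked-Yule) model a Monte-Carlo estimate via the hybrid simulator is
    returned with a warning.
    """
    if model is not None and getattr(model, "kind", None) != "star-like":
        import warnings

        warnings.warn("topology closed forms require the star-like model; "
                      "falling back to a Monte-Carlo estimate")
        from .simulate import topology_class_freqs_n4

        return topology_class_freqs_n4(model, Ta + ta_correction,
                                       reps=200_000, seed=0)
    if model is not None:
        alpha = model.alpha
    ta = Ta + ta_correction
    pe = escape_probability(alpha)
    p03 = (1 - pe) ** 3
    p04 = (1 - pe) ** 4
    p14 = 4 * pe * (1 - pe) ** 3
    e6 = math.exp(-6.0 * ta)
    # 2*exp(-6Ta)*(1-exp(3Ta)) = -2*P(three lineages survive to the sweep)
    m = 4.0 * (e6 - math.exp(-3.0 * ta))
    psym = (1.0 - m * p03 - e6 * (p04 + p14)) / 3.0
    pasym = (2.0 + m * p03 - e6 * (2 * p04 - p14)) / 3.0
    pstar = e6 * p04
    return psym, pasym, pstar


# ---------------------------------------------------------------------------
# marginal i-Ton branch-length distributions, n = 4
# ---------------------------------------------------------------------------

def iton_marginal_distribution(i: int, alpha: float, Ta: float, n: int = 4,
                               model=None, ta_correction: float = 0.0
                               ) -> PiecewiseExpDensity:
    """Marginal distribution of the total i-Ton branch length for n=4.

    Obtained by inverting the joint GF with respect to the i-Ton dummy
    variable after setting the others to zero.  The result combines a
    continuous piecewise-exponential part with atoms: at 0 (branch classes
    that may never exist) and at multiples of Ta set by the number of i-Ton
    branches extant when the sweep strikes.
    """
    if n != 4:
        raise ParameterError("marginal i-Ton distributions are provided for "
                             "n=4 (full joint GF)")
    if i not in (1, 2, 3):
        raise ParameterError("i must be in 1..3 for n=4")
    if model is None:
        model = StarlikeModel(alpha)
    ta = Ta + ta_correction
    gf = sweep_iton_gf(n, model)
    others = frozenset(j for j in range(1, n) if j != i)
    g = _marginalized(gf, others, n - 1)
    masses, comps = g.invert_single(i, ta, model=model)
    return PiecewiseExpDensity.from_components(masses, comps)


# ---------------------------------------------------------------------------
# blockwise SFS probabilities, n = 4
# ---------------------------------------------------------------------------

@dataclass
class BsfsTable:
    """Probability table over capped blockwise mutation configurations.

    ``probs[k1, k2, k3]`` with each index in ``0..kmax+1``; index ``kmax+1``
    is the ``>kmax`` bin.  Indices order i-Ton classes (singletons,
    doubletons, tripletons).
    """

    probs: np.ndarray
    kmax: int
    meta: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return float(self.probs[key])

    def sum(self) -> float:
        return float(self.probs.sum())

    @property
    def flat(self) -> np.ndarray:
        return self.probs.reshape(-1)

    @staticmethod
    def config_code(k: np.ndarray, kmax: int) -> np.ndarray:
        """Flat index of capped configurations; counts above kmax are binned."""
        kk = np.minimum(np.asarray(k), kmax + 1)
        base = kmax + 2
        return (kk[..., 0] * base + kk[..., 1]) * base + kk[..., 2]

    def labels(self):
        base = self.kmax + 2
        out = []
        for k1, k2, k3 in np.ndindex(base, base, base):
            out.append(tuple(f">{self.kmax}" if k == self.kmax + 1 else k
                             for k in (k1, k2, k3)))
        return out

    def to_tsv(self, path):
        with open(path, "w") as fh:
            fh.write("# " + json.dumps(self.meta) + "\n")
            fh.write("k1\tk2\tk3\tprob\n")
            for lab, p in zip(self.labels(), self.flat):
                fh.write(f"{lab[0]}\t{lab[1]}\t{lab[2]}\t{p:.12g}\n")

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump({"meta": self.meta, "kmax": self.kmax,
                       "probs": {" ".join(map(str, lab)): p for lab, p in
                                 zip(self.labels(), self.flat)}}, fh,
                      indent=1)


def _derivative_tables(gf, model, Ta: float, half_theta: float, kmax: int,
                       nclasses: int = 3) -> dict:
    """Taylor tables of the GF for every marginalization pattern.

    ``D[S][k]`` holds the Taylor coefficients at the point where the
    variables not in S sit at theta/2 and those in S at zero (marginalizing
    their mutation counts).
    """
    D = {}
    allv = frozenset(range(1, nclasses + 1))
    for rs in range(nclasses + 1):
        for S in map(frozenset, combinations(sorted(allv), rs)):
            tv = sorted(allv - S)
            g = _marginalized(gf, S, nclasses)
            if tv:
                D[S] = g.taylor(tv, [half_theta] * len(tv),
                                [kmax] * len(tv), Ta=Ta, model=model)
            else:
                D[S] = np.array(g.evaluate({}, Ta=Ta, model=model))
    return D


def _capped_table(D: dict, half_theta: float, kmax: int) -> np.ndarray:
    """Assemble the capped probability table from the derivative tables.

    Uncapped entries follow directly from the mixed Taylor coefficients;
    ``>kmax`` bins are computed by inclusion-exclusion over partially
    marginalized evaluations (complementation), so the table sums to one
    by construction.
    """
    base = kmax + 2
    out = np.zeros((base,) * 3)
    allv = (1, 2, 3)
    for cfg in np.ndindex(base, base, base):
        S = frozenset(v for v, k in zip(allv, cfg) if k == kmax + 1)
        U = [v for v in allv if v not in S]
        kU = {v: k for v, k in zip(allv, cfg) if v not in S}
        total = 0.0
        for rt in range(len(S) + 1):
            for T in map(frozenset, combinations(sorted(S), rt)):
                marg = S - T
                tbl = D[marg]
                tvars = sorted(frozenset(allv) - marg)
                sub = 0.0
                free = sorted(T)
                for kT in np.ndindex(*([kmax + 1] * len(free))):
                    kfull = {**kU, **dict(zip(free, kT))}
                    idx = tuple(kfull[v] for v in tvars)
                    c = float(tbl[idx]) if tvars else float(tbl)
                    ksum = sum(kfull.values())
                    sub += (half_theta ** ksum * (-1.0) ** ksum * c)
                total += (-1.0) ** rt * sub
        out[cfg] = total
    return out


def bsfs_probabilities(alpha: float, Ta: float, mut: MutationModel,
                       model=None, ta_correction: float = 0.0) -> BsfsTable:
    """Analytic bSFS probabilities for subsamples of four lineages.

    ``P[k] = prod_i ((theta/2)^{k_i}/k_i!) * (-1)^{sum k} *
    d^k phi / d omega^k`` evaluated at ``omega_i = theta/2``; counts above
    ``kmax`` are binned by complementation.  With ``kmax = 2`` the table
    has 64 entries.
    """
    if model is None:
        model = StarlikeModel(alpha)
    ta = Ta + ta_correction
    gf = sweep_iton_gf(4, model)
    D = _derivative_tables(gf, model, ta, mut.theta / 2.0, mut.kmax)
    probs = _capped_table(D, mut.theta / 2.0, mut.kmax)
    meta = {"alpha": getattr(model, "alpha", alpha), "Ta": Ta,
            "theta": mut.theta, "kmax": mut.kmax,
            "model": getattr(model, "kind", "star-like"),
            "ta_correction": ta_correction}
    return BsfsTable(probs=probs, kmax=mut.kmax, meta=meta)


def neutral_bsfs_probabilities(mut: MutationModel, n: int = 4) -> BsfsTable:
    """bSFS probabilities under the neutral coalescent (no sweep)."""
    gf = neutral_iton_gf(n)
    D = _derivative_tables(gf, None, 0.0, mut.theta / 2.0, mut.kmax,
                           nclasses=n - 1)
    probs = _capped_table(D, mut.theta / 2.0, mut.kmax)
    return BsfsTable(probs=probs, kmax=mut.kmax,
                     meta={"model": "neutral", "theta": mut.theta,
                           "kmax": mut.kmax})
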