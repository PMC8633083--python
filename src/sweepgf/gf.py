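"""Generating-function engine for the branch-length distribution of genealogies.

The joint Laplace transform (generating function, GF) of genealogical branch
lengths is built by recursion over coalescent histories.  Every expression
handled here is a finite sum of *path terms*, each of the form

    c * w(pkey) * Ta^p * exp(-Ta*(b + sum_v e_v omega_v))
      * prod_j 1/(lam_j + [delta] + sum_v c_jv omega_v)^{p_j}

where the ``omega_v`` are dummy variables, one per branch class, ``delta`` is
the rate of the competing exponential process standing in for the sweep, and
``Ta`` is the (discrete) time since fixation obtained by inverse Laplace
transform with respect to ``delta``.  ``w(pkey)`` is an optional
partition-probability weight resolved at evaluation time by a
:class:`PartitionModel`, which keeps the algebraic structure of the GF
independent of the sweep strength.

Terms are products of simple rational and exponential factors, so
differentiation, per-variable limits, substitution, variable merging, inverse
Laplace transforms and Taylor expansion are all exact term-wise operations.

Branch-class variables are

* a ``frozenset`` of sample labels for a fully labeled branch, e.g.
  ``frozenset({'a','b'})``;
* an ``int`` i for the i-Ton class (branches with i descendants) after
  collapsing;
* a ``str`` name for special merged variables (e.g. the tmrca variable).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GFError",
    "GFExpr",
    "PartitionModel",
    "neutral_gf",
    "gf_with_sweep",
    "MAX_FULL_GF_N",
]

#: Full joint GF construction is capped here: the number of coalescent
#: histories grows super-exponentially with sample size.  Larger samples are
#: served by the marginal-moments path in :mod:`sweepgf.observables`.
MAX_FULL_GF_N = 6


class GFError(ValueError):
    """Invalid input or operation on a generating function."""


# ---------------------------------------------------------------------------
# variables and linear forms
# ---------------------------------------------------------------------------

def _vkey(v: Hashable):
    """Stable sort key across the three variable kinds."""
    if isinstance(v, frozenset):
        return (0, tuple(sorted(v)))
    if isinstance(v, (int, np.integer)):
        return (1, (int(v),))
    return (2, (str(v),))


def _lin(lam: float, coeffs: Mapping[Hashable, int]):
    """Canonical linear form ``lam + sum coeffs[v]*v`` as a hashable tuple."""
    items = tuple(sorted(((v, int(c)) for v, c in coeffs.items() if c != 0),
                         key=lambda it: _vkey(it[0])))
    return (float(lam), items)


def _lin_sub(lin, var, value):
    lam, items = lin
    out = []
    for v, c in items:
        if v == var:
            lam += c * value
        else:
            out.append((v, c))
    return (lam, tuple(out))


def _lin_map(lin, mapping):
    lam, items = lin
    acc: dict = {}
    for v, c in items:
        w = mapping.get(v, v)
        acc[w] = acc.get(w, 0) + c
    return _lin(lam, acc)


def _lin_time(lin, newvar):
    """Replace the whole omega load with a single unit-coefficient variable."""
    lam, items = lin
    if not items:
        return lin
    return (lam, ((newvar, 1),))


def _lin_eval(lin, point):
    lam, items = lin
    return lam + sum(c * point[v] for v, c in items)


def _lin_sub_diff(a, b):
    """Linear form a - b."""
    lama, ita = a
    lamb, itb = b
    acc: dict = {}
    for v, c in ita:
        acc[v] = acc.get(v, 0) + c
    for v, c in itb:
        acc[v] = acc.get(v, 0) - c
    return _lin(lama - lamb, acc)


# ---------------------------------------------------------------------------
# terms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Term:
    coeff: float
    pkey: tuple | None          # partition-probability weight key, or None
    dnum: int                   # numerator power of delta (0 or 1)
    dfs: tuple                  # delta-bearing waiting factors: ((lam, items), ...)
    facs: tuple                 # delta-free factors: ((lam, items, power), ...)
    expb: float | None          # b of exp(-Ta*(b + sum e_v omega_v)); None = no exp
    expit: tuple                # ((var, coeff), ...) of the exponential
    tap: int                    # power of Ta as a prefactor

    def _key(self):
        return (self.pkey, self.dnum, tuple(sorted(self.dfs)),
                tuple(sorted(self.facs)), self.expb, self.expit, self.tap)


def _merge(terms: Iterable[_Term]) -> tuple:
    acc: dict = {}
    for t in terms:
        k = t._key()
        if k in acc:
            acc[k] = replace(acc[k], coeff=acc[k].coeff + t.coeff)
        else:
            acc[k] = t
    return tuple(t for t in acc.values() if t.coeff != 0.0)


def _mul_fac(t: _Term, lin, power=1) -> _Term:
    lam, items = lin
    if not items:
        # constant denominator folds into the coefficient
        if lam == 0.0:
            raise GFError("zero constant denominator")
        return replace(t, coeff=t.coeff / lam ** power)
    facs = dict()
    for flam, fit, p in t.facs:
        facs[(flam, fit)] = facs.get((flam, fit), 0) + p
    facs[(lam, items)] = facs.get((lam, items), 0) + power
    newfacs = tuple(sorted((fl, fi, p) for (fl, fi), p in facs.items()))
    return replace(t, facs=newfacs)


# ---------------------------------------------------------------------------
# partition models (protocol; implementations live in sweepgf.partition)
# ---------------------------------------------------------------------------

class PartitionModel:
    """Instantaneous-sweep partition law applied to the extant lineages.

    Subclasses enumerate, for a set of lineages present when the sweep
    occurs, the possible partitions of those lineages together with a weight
    key; the numeric probability attached to each key is supplied by
    :meth:`weight` so that the same GF structure can be re-weighted (e.g. for
    different recombination distances).
    """

    def structures(self, lineages: frozenset):
        """Yield ``(pkey, partition)`` pairs; partition is a tuple of label-sets."""
        raise NotImplementedError

    def weight(self, pkey) -> float:
        raise NotImplementedError

    def signature(self):
        """Hashable identity of the *structure* (not the weights)."""
        raise NotImplementedError

    def validate(self, max_n: int, tol: float = 1e-9) -> None:
        """Check partition probabilities sum to one for every subset size."""
        for k in range(2, max_n + 1):
            labels = frozenset(frozenset({i}) for i in range(k))
            tot = sum(self.weight(pk) for pk, _ in self.structures(labels))
            if abs(tot - 1.0) > tol:
                raise GFError(
                    f"partition probabilities for n={k} sum to {tot!r}, not 1")


# ---------------------------------------------------------------------------
# GF expression
# ---------------------------------------------------------------------------

class GFExpr:
    """A generating function as a canonical sum of path terms."""

    def __init__(self, terms: Sequence[_Term], nsample: int, has_delta: bool):
        self.terms = tuple(terms)
        self.nsample = nsample
        self.has_delta = has_delta

    def __len__(self):
        return len(self.terms)

    # -- structure queries -------------------------------------------------
    def variables(self) -> set:
        out = set()
        for t in self.terms:
            for _, items in t.dfs:
                out.update(v for v, _ in items)
            for _, items, _ in t.facs:
                out.update(v for v, _ in items)
            out.update(v for v, _ in t.expit)
        return out

    # -- evaluation --------------------------------------------------------
    def evaluate(self, point: Mapping[Hashable, float], Ta: float | None = None,
                 delta: float | None = None, model: PartitionModel | None = None
                 ) -> float:
        """Evaluate at a numeric point; every variable must be assigned.

        ``delta`` is required iff the expression is still parameterized by
        the competing-exponential rate; ``Ta`` iff it has been inverted.
        """
        total = 0.0
        for t in self.terms:
            v = t.coeff
            if t.pkey is not None:
                if model is None:
                    raise GFError("expression carries partition weights; "
                                  "a partition model is required")
                v *= model.weight(t.pkey)
            if t.dfs or t.dnum:
                if delta is None:
                    raise GFError("expression contains delta; pass delta=")
                v *= delta ** t.dnum
                for lam, items in t.dfs:
                    v /= (lam + delta + sum(c * point[x] for x, c in items))
            for lam, items, p in t.facs:
                v /= (lam + sum(c * point[x] for x, c in items)) ** p
            if t.expb is not None or t.tap:
                if Ta is None:
                    raise GFError("expression contains Ta; pass Ta=")
                if t.tap:
                    v *= Ta ** t.tap
                if t.expb is not None:
                    v *= math.exp(-Ta * (t.expb +
                                         sum(c * point[x] for x, c in t.expit)))
            total += v
        return total

    # -- substitution and limits --------------------------------------------
    def subs(self, var, value: float) -> "GFExpr":
        """Substitute a numeric value for one variable (limit toward it)."""
        out = []
        for t in self.terms:
            dfs = tuple(_lin_sub(l, var, value) for l in t.dfs)
            coeff = t.coeff
            facs = []
            for lam, items, p in t.facs:
                lam2, it2 = _lin_sub((lam, items), var, value)
                if it2:
                    facs.append((lam2, it2, p))
                else:
                    if lam2 == 0.0:
                        raise GFError("substitution produced a pole")
                    coeff /= lam2 ** p
            expb, expit = t.expb, t.expit
            if expb is not None:
                expb, expit = _lin_sub((expb, expit), var, value)
            out.append(replace(t, coeff=coeff, dfs=dfs, facs=tuple(sorted(facs)),
                               expb=expb, expit=expit))
        return GFExpr(_merge(out), self.nsample, self.has_delta)

    def limit_zero(self, var) -> "GFExpr":
        return self.subs(var, 0.0)

    def limit_inf(self, var) -> "GFExpr":
        """Limit var -> infinity: every term containing the variable vanishes.

        Each rational factor is linear in the variable so the term decays like
        a negative power; an exponential factor containing the variable decays
        for Ta > 0 (the value at Ta = 0 is taken as the right limit).
        """
        keep = []
        for t in self.terms:
            present = any(v == var for _, items in t.dfs for v, _ in items) or \
                any(v == var for _, items, _ in t.facs for v, _ in items) or \
                any(v == var for v, _ in t.expit)
            if not present:
                keep.append(t)
        return GFExpr(keep, self.nsample, self.has_delta)

    def limit_delta_zero(self) -> "GFExpr":
        """delta -> 0: the sweep never happens; recovers the neutral GF."""
        if not self.has_delta:
            raise GFError("expression has no delta")
        out = []
        for t in self.terms:
            if t.dnum:
                continue
            s = replace(t, dfs=())
            for lin in t.dfs:
                s = _mul_fac(s, lin)
            out.append(s)
        return GFExpr(_merge(out), self.nsample, False)

    # -- variable rewiring ---------------------------------------------------
    def merge_vars(self, mapping: Mapping) -> "GFExpr":
        """Merge/rename variables; coefficients of merged variables add."""
        out = []
        for t in self.terms:
            dfs = tuple(_lin_map(l, mapping) for l in t.dfs)
            facs = tuple(sorted((*_lin_map((lam, items), mapping), p)
                                for lam, items, p in t.facs))
            expb, expit = t.expb, t.expit
            if expb is not None:
                expb, expit = _lin_map((expb, expit), mapping)
            out.append(replace(t, dfs=dfs, facs=facs, expb=expb, expit=expit))
        return GFExpr(_merge(out), self.nsample, self.has_delta)

    def collapse_to_iton(self) -> "GFExpr":
        """Merge labeled branch variables by descendant count (i-Ton classes)."""
        mapping = {}
        for v in self.variables():
            if isinstance(v, frozenset):
                if len(v) >= self.nsample:
                    raise GFError("root branch variable should not occur")
                mapping[v] = len(v)
        return self.merge_vars(mapping)

    def collapse_time(self, newvar="omega") -> "GFExpr":
        """Rewire the GF to transform total elapsed time (e.g. tmrca).

        In every factor the per-branch omega load is replaced by a single
        unit-coefficient variable, so the transform variable multiplies the
        duration of each inter-event interval rather than branch lengths.
        """
        out = []
        for t in self.terms:
            dfs = tuple(_lin_time(l, newvar) for l in t.dfs)
            facdict: dict = {}
            for lam, items, p in t.facs:
                lam2, it2 = _lin_time((lam, items), newvar)
                facdict[(lam2, it2)] = facdict.get((lam2, it2), 0) + p
            facs = tuple(sorted((lam, it, p) for (lam, it), p in facdict.items()))
            expb, expit = t.expb, t.expit
            if expb is not None:
                expb, expit = _lin_time((expb, expit), newvar)
            out.append(replace(t, dfs=dfs, facs=facs, expb=expb, expit=expit))
        return GFExpr(_merge(out), self.nsample, self.has_delta)

    # -- calculus ------------------------------------------------------------
    def diff(self, var) -> "GFExpr":
        """Exact partial derivative with respect to one dummy variable."""
        if self.has_delta:
            raise GFError("invert delta before differentiating")
        out = []
        for t in self.terms:
            for i, (lam, items, p) in enumerate(t.facs):
                c = dict(items).get(var, 0)
                if not c:
                    continue
                facs = list(t.facs)
                facs[i] = (lam, items, p + 1)
                out.append(replace(t, coeff=-t.coeff * p * c,
                                   facs=tuple(sorted(facs))))
            if t.expb is not None:
                c = dict(t.expit).get(var, 0)
                if c:
                    out.append(replace(t, coeff=-t.coeff * c, tap=t.tap + 1))
        return GFExpr(_merge(out), self.nsample, False)

    # -- inverse Laplace transform in one branch variable ---------------------
    def invert_single(self, var, Ta: float, model: PartitionModel | None = None):
        """Inverse Laplace transform with respect to one remaining variable.

        Every other variable must already have been substituted and delta
        inverted, so each term reads
        ``w * exp(-Ta*c*var) * prod_j 1/(lam_j + c_j*var)^{p_j}``.
        The transform of such a term is a (possibly signed) mixture of
        shifted Erlang-type components plus point masses: terms constant in
        ``var`` map to an atom at ``t = Ta*c`` and rational parts map, via
        partial fractions, to ``(t-shift)^k exp(-rate*(t-shift))`` pieces.
        Components with negative rates arise from partial-fraction
        coefficients of the delta inversion and cancel beyond the last
        breakpoint; they are legitimate on interior intervals.

        Returns ``(masses, comps)`` with ``masses`` a dict
        ``{location: mass}`` and ``comps`` a list of ``(shift, coef, k,
        rate)`` meaning ``coef*(t-shift)^k*exp(-rate*(t-shift))`` supported
        on ``t >= shift``.
        """
        if self.has_delta:
            raise GFError("invert delta before inverting a branch variable")
        masses: dict = {}
        comps: list = []
        for t in self.terms:
            w = t.coeff
            if t.pkey is not None:
                if model is None:
                    raise GFError("partition model required")
                w *= model.weight(t.pkey)
            if t.tap:
                w *= Ta ** t.tap
            tau = 0.0
            if t.expb is not None:
                w *= math.exp(-Ta * t.expb)
                eit = dict(t.expit)
                if set(eit) - {var}:
                    raise GFError("unsubstituted variable in exponential")
                c = eit.get(var, 0)
                if c < 0:  # pragma: no cover
                    raise GFError("negative exponential coefficient")
                tau = Ta * c
            roots: dict = {}
            for lam, items, p in t.facs:
                it = dict(items)
                if set(it) - {var}:
                    raise GFError("unsubstituted variable in factor")
                c = it[var]
                w /= float(c) ** p
                d = round(lam / c, 12)
                roots[d] = roots.get(d, 0) + p
            if not roots:
                key = round(tau, 12)
                masses[key] = masses.get(key, 0.0) + w
                continue
            for d, coefs in _partial_fractions_1d(roots).items():
                for m, a in enumerate(coefs, start=1):
                    comps.append((tau, w * a / math.factorial(m - 1),
                                  m - 1, d))
        return masses, comps

    # -- inverse Laplace transform in delta -----------------------------------
    def invert_delta(self) -> "GFExpr":
        """Inverse Laplace transform of GF/delta: competing-rate -> discrete Ta.

        Each term is a product of simple rational factors with distinct poles
        in delta (waiting-time rates strictly decrease along a history), so
        partial fractions in delta followed by term-wise inversion yields a
        finite sum of exponentials in Ta.
        """
        if not self.has_delta:
            raise GFError("expression has no delta to invert")
        out = []
        for t in self.terms:
            if t.expb is not None:
                raise GFError("term already inverted")
            poles = list(t.dfs)  # pole at delta = -(lam + sum c omega)
            base = replace(t, dfs=(), dnum=0)
            if t.dnum == 0:
                # extra pole at delta = 0 from dividing the GF by delta
                s = base
                for lin in poles:
                    s = _mul_fac(s, lin)
                out.append(s)  # the Ta-independent part
                for j, pj in enumerate(poles):
                    s = replace(base, coeff=-base.coeff,
                                expb=pj[0], expit=pj[1])
                    s = _mul_fac(s, pj)
                    for i, pi in enumerate(poles):
                        if i != j:
                            s = _mul_fac(s, _lin_sub_diff(pi, pj))
                    out.append(s)
            elif t.dnum == 1:
                # numerator delta cancels the 1/delta; no pole at zero
                for j, pj in enumerate(poles):
                    s = replace(base, expb=pj[0], expit=pj[1])
                    for i, pi in enumerate(poles):
                        if i != j:
                            s = _mul_fac(s, _lin_sub_diff(pi, pj))
                    out.append(s)
            else:  # pragma: no cover
                raise GFError("unsupported delta numerator power")
        return GFExpr(_merge(out), self.nsample, False)

    # -- Taylor expansion (numeric workhorse) ---------------------------------
    def taylor(self, tvars: Sequence, point: Sequence[float],
               orders: Sequence[int], Ta: float | None = None,
               model: PartitionModel | None = None) -> np.ndarray:
        """Taylor coefficients around a numeric point, batched over terms.

        Returns the array ``C[k1,...,km]`` with
        ``f = sum_k C[k] prod (x_i - point_i)^{k_i}``; mixed partial
        derivatives follow as ``C[k] * prod k_i!``.  Any variable of the
        expression not listed in ``tvars`` must already have been
        substituted.
        """
        if self.has_delta:
            raise GFError("invert delta before Taylor expansion")
        shape = tuple(o + 1 for o in orders)
        nt = len(self.terms)
        if nt == 0:
            return np.zeros(shape)
        plan = self._taylor_plan(tuple(tvars), shape)
        return plan.run(self, np.asarray(point, dtype=float), Ta, model)

    def _taylor_plan(self, tvars: tuple, shape: tuple) -> "_TaylorPlan":
        key = (tvars, shape)
        cache = getattr(self, "_plan_cache", None)
        if cache is None:
            cache = {}
            self._plan_cache = cache
        if key not in cache:
            cache[key] = _TaylorPlan(self, tvars, shape)
        return cache[key]


def _partial_fractions_1d(roots: Mapping[float, int]) -> dict:
    """Partial fractions of ``prod_i (w + d_i)^{-m_i}`` with distinct d_i.

    Returns ``{d_j: [A_{j,1}, ..., A_{j,m_j}]}`` such that the product equals
    ``sum_j sum_m A_{j,m} / (w + d_j)^m``.  Repeated roots are handled through
    derivatives of the co-factor, computed with the logarithmic-derivative
    recursion (exact in closed form, no numerical differentiation).
    """
    ds = list(roots.items())
    out: dict = {}
    for j, (dj, mj) in enumerate(ds):
        others = [(di, mi) for i, (di, mi) in enumerate(ds) if i != j]
        # g(w) = prod_{i != j} (w + d_i)^{-m_i}, evaluated with derivatives
        # at w = -d_j;  g' = g*h with h = sum -m_i/(w + d_i).
        nder = mj - 1
        g = [0.0] * (nder + 1)
        g[0] = math.prod((di - dj) ** -mi for di, mi in others)
        if nder:
            h = [math.fsum(-mi * (-1.0) ** q * math.factorial(q)
                           / (di - dj) ** (q + 1) for di, mi in others)
                 for q in range(nder)]
            for r in range(nder):
                g[r + 1] = math.fsum(math.comb(r, q) * h[q] * g[r - q]
                                     for q in range(r + 1))
        coefs = [g[mj - m] / math.factorial(mj - m) for m in range(1, mj + 1)]
        out[dj] = coefs
    return out


@lru_cache(maxsize=32)
def _conv_pairs(shape):
    """Truncated-convolution index pairs, grouped by output multi-index."""
    midx = list(np.ndindex(*shape))
    pos = {k: i for i, k in enumerate(midx)}
    groups = []
    for k in midx:
        ia, ib = [], []
        for a in np.ndindex(*(ki + 1 for ki in k)):
            b = tuple(ki - ai for ki, ai in zip(k, a))
            ia.append(pos[tuple(a)])
            ib.append(pos[b])
        groups.append((np.array(ia), np.array(ib)))
    return tuple(groups)


def _batch_conv(A, B, groups):
    """Row-wise truncated convolution of series batches A, B: (T, flat)."""
    out = np.empty_like(A)
    for t, (ia, ib) in enumerate(groups):
        out[:, t] = np.einsum("ij,ij->i", A[:, ia], B[:, ib])
    return out


class _TaylorPlan:
    """Precompiled layout of a GF's terms for fast repeated Taylor expansion.

    The GF structure (factors, exponentials, weight keys) is fixed; only the
    expansion point, Ta and the partition weights change between calls, so
    everything index-like is computed once and the per-call work is a handful
    of vectorized array operations.
    """

    def __init__(self, gf: "GFExpr", tvars: tuple, shape: tuple):
        self.shape = shape
        self.flat = int(np.prod(shape))
        nv = len(tvars)
        vidx = {v: i for i, v in enumerate(tvars)}
        self.karr = np.array(list(np.ndindex(*shape)))          # (flat, nv')
        if self.karr.shape[1] != nv:  # pragma: no cover
            raise GFError("orders/tvars length mismatch")
        self.absk = self.karr.sum(axis=1)
        fact = np.array([math.factorial(i) for i in range(20)], dtype=float)
        self.multinom = fact[self.absk] / fact[self.karr].prod(axis=1)
        self.factprod = fact[self.karr].prod(axis=1)
        self.fact = fact
        self.groups = _conv_pairs(shape)

        nt = len(gf.terms)
        self.nt = nt
        self.coeff = np.array([t.coeff for t in gf.terms])
        self.tap = np.array([t.tap for t in gf.terms])
        self.pkeys = [t.pkey for t in gf.terms]

        flam, fpow, fcmat, ftid = [], [], [], []
        rounds: list[list[int]] = []
        for it, t in enumerate(gf.terms):
            for r, (lam, items, p) in enumerate(t.facs):
                cvec = np.zeros(nv)
                for v, c in items:
                    if v not in vidx:
                        raise GFError(f"unsubstituted variable {v!r}")
                    cvec[vidx[v]] = c
                while len(rounds) <= r:
                    rounds.append([])
                rounds[r].append(len(flam))
                flam.append(lam)
                fpow.append(p)
                fcmat.append(cvec)
                ftid.append(it)
        self.flam = np.array(flam)
        self.fpow = np.array(fpow, dtype=int)
        self.fcmat = np.array(fcmat) if fcmat else np.zeros((0, nv))
        self.ftid = np.array(ftid, dtype=int)
        self.rounds = [np.array(r, dtype=int) for r in rounds]

        eb, ecmat, etid = [], [], []
        for it, t in enumerate(gf.terms):
            if t.expb is not None:
                cvec = np.zeros(nv)
                for v, c in t.expit:
                    if v not in vidx:
                        raise GFError(f"unsubstituted variable {v!r}")
                    cvec[vidx[v]] = c
                eb.append(t.expb)
                ecmat.append(cvec)
                etid.append(it)
        self.eb = np.array(eb)
        self.ecmat = np.array(ecmat) if ecmat else np.zeros((0, nv))
        self.etid = np.array(etid, dtype=int)

    def run(self, gf: "GFExpr", pt: np.ndarray, Ta, model) -> np.ndarray:
        w = self.coeff.copy()
        if any(pk is not None for pk in self.pkeys):
            if model is None:
                raise GFError("partition model required")
            w *= np.array([1.0 if pk is None else model.weight(pk)
                           for pk in self.pkeys])
        if self.tap.any():
            if Ta is None:
                raise GFError("Ta required")
            w *= np.where(self.tap > 0, float(Ta) ** self.tap, 1.0)

        # all factor series at once: (F, flat)
        if len(self.flam):
            mu = self.flam + self.fcmat @ pt
            if np.any(mu == 0.0):
                raise GFError("Taylor expansion at a pole")
            p = self.fpow[:, None]
            m = self.absk[None, :]
            comb = self.fact[p - 1 + m] / (self.fact[p - 1] * self.fact[m])
            cpow = np.prod(self.fcmat[:, None, :] ** self.karr[None, :, :],
                           axis=2)
            S = ((-1.0) ** m * comb * self.multinom[None, :] * cpow
                 / mu[:, None] ** (p + m))
        else:
            S = np.zeros((0, self.flat))

        if len(self.eb):
            if Ta is None:
                raise GFError("Ta required")
            damp = np.exp(-Ta * (self.eb + self.ecmat @ pt))
            Se = (np.prod((-Ta * self.ecmat[:, None, :])
                          ** self.karr[None, :, :], axis=2)
                  / self.factprod[None, :]) * damp[:, None]

        rows = np.zeros((self.nt, self.flat))
        rows[:, 0] = w
        for rnd in self.rounds:
            tid = self.ftid[rnd]
            rows[tid] = _batch_conv(rows[tid], S[rnd], self.groups)
        if len(self.eb):
            rows[self.etid] = _batch_conv(rows[self.etid], Se, self.groups)
        return rows.sum(axis=0).reshape(self.shape)


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def _check_sample(sample: Iterable) -> frozenset:
    lineages = frozenset(frozenset(x) for x in sample)
    if not lineages or any(len(x) == 0 for x in lineages):
        raise GFError("sample must be a non-empty set of non-empty label sets")
    labels = [l for x in lineages for l in x]
    if len(labels) != len(set(labels)):
        raise GFError("lineage label sets must be disjoint")
    return lineages


def make_sample(n: int) -> frozenset:
    """Default sample of n uniquely labeled lineages {{a},{b},...}."""
    if n > MAX_FULL_GF_N:
        raise GFError(
            f"full GF construction is capped at n={MAX_FULL_GF_N}; use the "
            "marginal-moments path for larger samples")
    labels = "abcdefghij"[:n]
    return frozenset(frozenset({c}) for c in labels)


def _pairs(lineages):
    return itertools.combinations(sorted(lineages, key=_vkey), 2)


def neutral_gf(sample: Iterable) -> GFExpr:
    """Neutral-coalescent GF by recursion over pairwise coalescence events.

    Each term carries one factor ``1/(C(k,2) + sum omega)`` per epoch of the
    corresponding coalescent history; the recursion ends at a single lineage.
    """
    lineages = _check_sample(sample)
    n = sum(len(x) for x in lineages)
    if n > MAX_FULL_GF_N:
        raise GFError(
            f"full GF construction is capped at n={MAX_FULL_GF_N}")

    memo: dict = {}

    def rec(om: frozenset) -> tuple:
        if len(om) == 1:
            return (_Term(1.0, None, 0, (), (), None, (), 0),)
        if om in memo:
            return memo[om]
        k = len(om)
        lin = _lin(k * (k - 1) / 2.0, {x: 1 for x in om})
        out = []
        for a, b in _pairs(om):
            nxt = (om - {a, b}) | {a | b}
            for t in rec(nxt):
                out.append(_mul_fac(t, lin))
        res = _merge(out)
        memo[om] = res
        return res

    return GFExpr(rec(lineages), n, False)


def gf_with_sweep(sample: Iterable, model: PartitionModel) -> GFExpr:
    """GF with an embedded sweep treated as a competing exponential process.

    The sweep competes at rate delta with coalescence; when it wins, the
    extant lineages are partitioned instantaneously according to ``model``
    and the history continues neutrally (the sweep occurs at most once, so
    the continuation carries no delta).
    """
    lineages = _check_sample(sample)
    n = sum(len(x) for x in lineages)
    if n > MAX_FULL_GF_N:
        raise GFError(f"full GF construction is capped at n={MAX_FULL_GF_N}")
    model.validate(len(lineages))

    nmemo: dict = {}

    def neutral_terms(om: frozenset) -> tuple:
        if len(om) == 1:
            return (_Term(1.0, None, 0, (), (), None, (), 0),)
        if om in nmemo:
            return nmemo[om]
        k = len(om)
        lin = _lin(k * (k - 1) / 2.0, {x: 1 for x in om})
        out = []
        for a, b in _pairs(om):
            nxt = (om - {a, b}) | {a | b}
            for t in neutral_terms(nxt):
                out.append(_mul_fac(t, lin))
        res = _merge(out)
        nmemo[om] = res
        return res

    smemo: dict = {}

    def sweep_terms(om: frozenset) -> tuple:
        if len(om) == 1:
            return (_Term(1.0, None, 0, (), (), None, (), 0),)
        if om in smemo:
            return smemo[om]
        k = len(om)
        lin = _lin(k * (k - 1) / 2.0, {x: 1 for x in om})
        out = []
        for a, b in _pairs(om):
            nxt = (om - {a, b}) | {a | b}
            for t in sweep_terms(nxt):
                out.append(replace(t, dfs=t.dfs + (lin,)))
        for pkey, part in model.structures(om):
            for t in neutral_terms(frozenset(part)):
                if t.pkey is not None:  # pragma: no cover
                    raise GFError("nested partition weights")
                out.append(replace(t, pkey=pkey, dnum=1, dfs=t.dfs + (lin,)))
        res = _merge(out)
        smemo[om] = res
        return res

    return GFExpr(sweep_terms(lineages), n, True)
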