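"""Instantaneous-sweep partition models and selection-parameter algebra.

A hard selective sweep of a codominant beneficial mutation (heterozygous
advantage ``s``, diploid population size ``Ne``) is approximated as an
instantaneous event on the coalescent time scale that partitions the lineages
extant when it occurs.  At a neutral site ``d`` bases from the selected site
the strength of the hitchhiking effect is summarized by

    alpha = (r*d/s) * ln(2*Ne*s),

the expected number of recombination events between the two sites along one
lineage during the sweep; equivalently ``alpha = r*d*t_fix/2`` with sweep
duration ``t_fix = 2*ln(2*Ne*s)/s`` generations.

Two partition laws are provided:

* **star-like** — each lineage escapes the sweep independently with
  probability ``Pe = 1 - exp(-alpha)``; all non-escapers merge at once.
* **marked Yule** — the beneficial-allele genealogy is a pure-birth tree
  with splitting rate ``2*Ne*s`` stopped at ``ceil(4*Ne*s)`` lineages and
  marked by recombination at rate ``2*Ne*r*d``; sampled lineages fall into
  late recombinant singletons (L), early-recombinant families (escaping
  after coalescing, E) and a nonrecombinant family (N).  The partition law
  is estimated by Monte Carlo and plugged into the GF exactly as the
  star-like probabilities are.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .gf import GFError, PartitionModel, _vkey

__all__ = [
    "ParameterError",
    "SweepParams",
    "alpha",
    "escape_probability",
    "starlike_partition_probs",
    "fixation_time_coalescent",
    "StarlikeModel",
    "EmpiricalPartitionModel",
    "yule_partition_sample",
]


class ParameterError(ValueError):
    """Parameter outside the model's domain."""


@dataclass(frozen=True)
class SweepParams:
    """Hard-sweep parameters.

    Attributes
    ----------
    Ne : diploid population size (individuals).
    s : heterozygous selection coefficient per generation; requires
        ``2*Ne*s > 1`` for the sweep duration to be defined.
    r : per-base per-generation recombination rate.
    Ta : time since fixation of the beneficial allele, in units of 2*Ne
        generations.
    """

    Ne: float
    s: float
    r: float
    Ta: float = 0.0

    def __post_init__(self):
        if self.Ne < 1:
            raise ParameterError("Ne must be >= 1")
        if not self.s > 0:
            raise ParameterError("s must be positive")
        if 2 * self.Ne * self.s <= 1:
            raise ParameterError("2*Ne*s must exceed 1 (else the sweep "
                                 "duration is undefined)")
        if self.r < 0:
            raise ParameterError("r must be non-negative")
        if self.Ta < 0:
            raise ParameterError("Ta must be non-negative")

    @property
    def t_fix(self) -> float:
        """Expected sweep duration 2*ln(2*Ne*s)/s, in generations."""
        return 2.0 * math.log(2 * self.Ne * self.s) / self.s

    @property
    def t_fix_coal(self) -> float:
        """Sweep duration in coalescent units of 2*Ne generations."""
        return self.t_fix / (2.0 * self.Ne)

    def alpha_at(self, d: float) -> float:
        """Scaled recombination distance of a site d bases away."""
        return alpha(self.r, d, self.s, self.Ne)


def alpha(r: float, d: float, s: float, Ne: float) -> float:
    """Scaled recombination distance alpha = (r*d/s)*ln(2*Ne*s)."""
    if 2 * Ne * s <= 1:
        raise ParameterError("2*Ne*s must exceed 1")
    if d < 0:
        raise ParameterError("distance must be non-negative")
    if r < 0:
        raise ParameterError("recombination rate must be non-negative")
    return (r * d / s) * math.log(2 * Ne * s)


def escape_probability(a: float) -> float:
    """Probability 1 - exp(-alpha) that a lineage recombines out of the sweep."""
    if a < 0:
        raise ParameterError("alpha must be non-negative")
    return -math.expm1(-a) if math.isfinite(a) else 1.0


def starlike_partition_probs(n: int, a: float) -> dict:
    """P_{m,n}: probability that m of n lineages escape the sweep.

    Lineages escape independently, so the counts are binomial in the escape
    probability ``Pe = 1 - exp(-alpha)``.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    pe = escape_probability(a)
    return {m: math.comb(n, m) * pe ** m * (1 - pe) ** (n - m)
            for m in range(n + 1)}


def fixation_time_coalescent(params: SweepParams) -> float:
    """Sweep duration t_fix/(2*Ne) = ln(2*Ne*s)/(s*Ne), coalescent units."""
    return params.t_fix_coal


# ---------------------------------------------------------------------------
# star-like partition model
# ---------------------------------------------------------------------------

class StarlikeModel(PartitionModel):
    """Independent-escape, single multiple-merger partition of the lineages.

    Each extant lineage escapes with probability ``Pe``; the non-escapers
    coalesce instantaneously into one lineage.  Weight keys record only
    (number escaping, subset size), so a GF built with one instance can be
    re-weighted by any other (the structure does not depend on alpha).
    """

    kind = "star-like"

    def __init__(self, alpha: float):
        if alpha < 0:
            raise ParameterError("alpha must be non-negative")
        self.alpha = alpha
        self.pe = escape_probability(alpha)

    def structures(self, lineages: frozenset):
        k = len(lineages)
        items = sorted(lineages, key=_vkey)
        for m in range(k + 1):
            for esc in itertools.combinations(items, m):
                rest = lineages.difference(esc)
                if len(rest) >= 2:
                    part = tuple(esc) + (frozenset().union(*rest),)
                else:
                    part = tuple(items)
                yield ("m", m, k), part

    def weight(self, pkey) -> float:
        _, m, k = pkey
        # per labeled escape subset (no binomial coefficient: subsets are
        # enumerated individually and merge in the GF's canonical form)
        return self.pe ** m * (1.0 - self.pe) ** (k - m)

    def signature(self):
        return ("star-like",)


# ---------------------------------------------------------------------------
# marked-Yule partition model
# ---------------------------------------------------------------------------

def _set_partitions(items):
    """All set partitions of a list of hashables."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] + [first]] + part[i + 1:]
        yield part + [[first]]


def _n_labeled_partitions(k: int, shape: tuple) -> int:
    """Number of set partitions of k elements with the given block sizes."""
    mult = Counter(shape)
    out = math.factorial(k)
    for size, m in mult.items():
        out //= math.factorial(size) ** m * math.factorial(m)
    return out


@dataclass
class EmpiricalPartitionModel(PartitionModel):
    """Exchangeable partition law given by empirical block-shape frequencies.

    ``shape_probs[k]`` maps a sorted block-size tuple (e.g. ``(2, 1, 1)``)
    to its probability for k extant lineages; each labeled partition with a
    given shape is equally likely.  Standard errors and the frequency of
    replicates with more than one early-recombinant family (not representable
    by the three-family partition) are kept as diagnostics.
    """

    shape_probs: dict
    shape_se: dict = field(default_factory=dict)
    extra_family_freq: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)
    kind: str = "yule"

    def structures(self, lineages: frozenset):
        k = len(lineages)
        probs = self.shape_probs.get(k)
        if probs is None:
            raise GFError(f"no partition probabilities for subset size {k}")
        for part in _set_partitions(sorted(lineages, key=_vkey)):
            shape = tuple(sorted((len(b) for b in part), reverse=True))
            if shape in probs:
                merged = tuple(frozenset().union(*b) for b in part)
                yield ("shape", k, shape), merged

    def weight(self, pkey) -> float:
        _, k, shape = pkey
        return self.shape_probs[k][shape] / _n_labeled_partitions(k, shape)

    def signature(self):
        return ("yule",) + tuple(
            (k, tuple(sorted(v))) for k, v in sorted(self.shape_probs.items()))


def _sample_yule_shapes(nsub: int, founders: int, split_rate: float,
                        mark_rate: float, reps: int, rng: np.random.Generator):
    """Monte-Carlo sample partition shapes from the marked-Yule process.

    The pure-birth tree is traversed pastward from its ``founders`` tips:
    while j ancestral lines remain the next (forward-time) split lies
    ``Exp(j*split_rate)`` back, and a uniformly chosen pair merges.  Only the
    spanning tree of the ``nsub`` sampled tips matters, so merges are thinned
    to sampled pairs with probability C(c,2)/C(j,2); recombination marks are
    Bernoulli per spanning-tree edge with probability ``1-exp(-mark_rate*
    duration)``.  Tracing each sampled tip pastward, the first marked edge on
    its path determines its family: a marked pendant edge makes a late
    singleton (L), a marked internal edge releases an early-recombinant
    family (E), and unmarked tips descend from the founder (N).
    """
    c = np.full(reps, nsub)
    t = np.zeros(reps)
    evt_t = np.zeros((reps, max(nsub - 1, 1)))
    nev = np.zeros(reps, dtype=int)
    for j in range(founders, 1, -1):
        t = t + rng.exponential(1.0 / (j * split_rate), size=reps)
        p = c * (c - 1) / (j * (j - 1))
        hit = rng.random(reps) < p
        if hit.any():
            idx = np.nonzero(hit)[0]
            evt_t[idx, nev[idx]] = t[idx]
            nev[idx] += 1
            c[idx] -= 1
        if not (c > 1).any():
            break

    shapes: Counter = Counter()
    extra = 0
    for rep in range(reps):
        # lines: (alive sampled-leaf count set, edge start time)
        lines = [([i], 0.0) for i in range(nsub)]
        n_l = 0
        e_families: list[int] = []
        for e in range(nev[rep]):
            te = evt_t[rep, e]
            i1 = int(rng.integers(len(lines)))
            i2 = int(rng.integers(len(lines) - 1))
            if i2 >= i1:
                i2 += 1
            merged_alive: list[int] = []
            for idx in sorted((i1, i2), reverse=True):
                leaves, start = lines.pop(idx)
                dur = te - start
                marked = (mark_rate > 0 and leaves
                          and rng.random() < -math.expm1(-mark_rate * dur))
                if marked:
                    if len(leaves) == 1:
                        n_l += 1
                    else:
                        e_families.append(len(leaves))
                else:
                    merged_alive.extend(leaves)
            lines.append((merged_alive, te))
        # the final line reaches the founder: its alive leaves are the
        # nonrecombinant family (marks on the final segment leave the
        # partition unchanged: the family escapes as a single unit)
        n_block = len(lines[0][0]) if lines else 0
        sizes = [1] * n_l + e_families + ([n_block] if n_block else [])
        shapes[tuple(sorted(sizes, reverse=True))] += 1
        if len(e_families) >= 2:
            extra += 1
    return shapes, extra


def yule_partition_sample(n: int, params: SweepParams, d: float,
                          reps: int, seed) -> EmpiricalPartitionModel:
    """Estimate the marked-Yule partition law for subsets of 2..n lineages.

    Runs the marked pure-birth simulation independently for every subset
    size (the GF needs partition probabilities whenever the sweep finds
    2..n lineages extant) and returns an empirical model with Monte-Carlo
    standard errors.
    """
    if reps < 1:
        raise ParameterError("reps must be >= 1")
    founders = math.ceil(4 * params.Ne * params.s)
    if founders < n:
        raise ParameterError(
            f"insufficient founders: ceil(4*Ne*s)={founders} < n={n}")
    split_rate = 2 * params.Ne * params.s
    mark_rate = 2 * params.Ne * params.r * d
    rng = np.random.default_rng(seed)
    shape_probs: dict = {}
    shape_se: dict = {}
    extra_freq: dict = {}
    for k in range(2, n + 1):
        shapes, extra = _sample_yule_shapes(k, founders, split_rate,
                                            mark_rate, reps, rng)
        shape_probs[k] = {sh: cnt / reps for sh, cnt in shapes.items()}
        shape_se[k] = {sh: math.sqrt(p * (1 - p) / reps)
                       for sh, p in shape_probs[k].items()}
        extra_freq[k] = extra / reps
    return EmpiricalPartitionModel(
        shape_probs=shape_probs, shape_se=shape_se,
        extra_family_freq=extra_freq,
        meta={"n": n, "Ne": params.Ne, "s": params.s, "r": params.r,
              "d": d, "alpha": params.alpha_at(d), "reps": reps})
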