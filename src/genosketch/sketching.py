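"""Fixed-size sketches of k-mer multisets and distance estimation.

Four sketch families are provided, all driven by the same seedable
64-bit token hashing so that sketches of different genomes are
register-wise comparable:

* ``probminhash3a`` — weighted MinHash over normalized k-mer frequencies.
  Each register holds the token minimizing an Exp(w(token)) draw; the
  probability that two genomes share a register equals the probability
  Jaccard index J_p.  Implemented with the order-statistics acceleration:
  per token the m register values are generated in ascending order
  (exponential spacings + truncated Fisher-Yates permutation) and the
  scan stops as soon as the value exceeds the current register maximum.
* ``superminhash`` — unweighted; per element, register j receives
  j + U_j assigned through a random permutation, register equality has
  probability J with lower variance than classic m-hash MinHash.
* ``oph_optimal`` / ``oph_faster`` — one-permutation hashing: a single
  hash per element binned into m slots keeping the bin minimum, with
  empty bins filled by optimal (random re-hash probing) or faster
  (fixed-direction rotation with bin-level re-randomization)
  densification.
* ``setsketch`` — geometric base-b registers K_i = max over elements of
  1 + floor(log_b(a/E)), clamped to [0, q+1]; mergeable by element-wise
  max and interpolating between MinHash (b -> 1) and HyperLogLog (b = 2).
  Jaccard is estimated either from register equality with a b-dependent
  correction (LSH) or by joint maximum likelihood over register pairs
  (JMLE, the default: more accurate when J < 0.01).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum

import numba as nb
import numpy as np
from scipy.optimize import minimize, minimize_scalar

from ._hashing import GOLDEN, mix64, seed_stream, to_unit
from .genome_io import Alphabet
from .kmer import KmerMultiset, weight_arrays


class SketchAlgo(str, Enum):
    PROBMINHASH3A = "probminhash3a"
    SUPERMINHASH = "superminhash"
    OPH_OPTIMAL = "oph_optimal"
    OPH_FASTER = "oph_faster"
    SETSKETCH = "setsketch"


class Estimator(str, Enum):
    REGISTER_MATCH = "register_match"
    SETSKETCH_LSH = "setsketch_lsh"
    SETSKETCH_JMLE = "setsketch_jmle"


# stream salts keep the algorithms' randomness independent
_SALT = {
    SketchAlgo.PROBMINHASH3A: 0x50524F42,
    SketchAlgo.SUPERMINHASH: 0x53555045,
    SketchAlgo.OPH_OPTIMAL: 0x4F504821,
    SketchAlgo.OPH_FASTER: 0x4F504821,
    SketchAlgo.SETSKETCH: 0x53455453,
}
_DENSIFY_SALT = 0x44454E53


@dataclass(frozen=True)
class SketchParams:
    """Everything needed to reproduce a sketch bit-for-bit.

    Defaults follow standard practice for bacterial genomes at the
    nucleotide level: m = 12000 registers, k = 16.  Amino-acid searches
    use k = 7 (whole proteome) or k = 5 (universal genes); fungal
    nucleotide searches use m = 48000, k = 21.
    """

    algo: SketchAlgo = SketchAlgo.PROBMINHASH3A
    m: int = 12000
    k: int = 16
    alphabet: Alphabet = Alphabet.NUCLEOTIDE
    seed: int = 0
    setsketch_b: float = 1.001
    setsketch_a: float = 20.0
    setsketch_q: int = 2 ** 16 - 2

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("sketch size m must be >= 1")
        if self.setsketch_b <= 1.0 or self.setsketch_a <= 0.0 or self.setsketch_q < 1:
            raise ValueError("setsketch requires b > 1, a > 0, q >= 1")
        object.__setattr__(self, "algo", SketchAlgo(self.algo))
        object.__setattr__(self, "alphabet", Alphabet(self.alphabet))

    def compatible_with(self, other: "SketchParams") -> bool:
        return (self.algo == other.algo and self.m == other.m and self.k == other.k
                and self.alphabet == other.alphabet and self.seed == other.seed
                and (self.algo is not SketchAlgo.SETSKETCH
                     or (self.setsketch_b == other.setsketch_b
                         and self.setsketch_a == other.setsketch_a
                         and self.setsketch_q == other.setsketch_q)))


@dataclass
class SketchVector:
    """m registers summarizing one genome under one algorithm."""

    params: SketchParams
    registers: np.ndarray
    genome_id: str = ""

    @property
    def m(self) -> int:
        return self.params.m


class IncomparableSketches(ValueError):
    """Raised when sketches from different parameter sets are compared."""


# ---------------------------------------------------------------------------
# numba kernels


@nb.njit(cache=True)
def _probminhash_kernel(tokens, weights, m, seed):
    reg_val = np.full(m, np.inf)
    reg_tok = np.zeros(m, np.uint64)
    perm = np.empty(m, np.int64)
    tag = np.full(m, -1, np.int64)
    bound = np.inf
    filled = 0
    updates = 0
    seedmix = seed
    seedmix = (seedmix ^ (seedmix >> 30)) * nb.uint64(0xBF58476D1CE4E5B9)
    seedmix = (seedmix ^ (seedmix >> 27)) * nb.uint64(0x94D049BB133111EB)
    seedmix = seedmix ^ (seedmix >> 31)
    for e in range(tokens.shape[0]):
        w = weights[e]
        state = tokens[e] ^ seedmix
        state = (state ^ (state >> 30)) * nb.uint64(0xBF58476D1CE4E5B9)
        state = (state ^ (state >> 27)) * nb.uint64(0x94D049BB133111EB)
        state = state ^ (state >> 31)
        x = 0.0
        for kk in range(m):
            state = state + nb.uint64(0x9E3779B97F4A7C15)
            h = state
            h = (h ^ (h >> 30)) * nb.uint64(0xBF58476D1CE4E5B9)
            h = (h ^ (h >> 27)) * nb.uint64(0x94D049BB133111EB)
            h = h ^ (h >> 31)
            u1 = (nb.float64(h >> 11) + 0.5) * (1.0 / 9007199254740992.0)
            x += -math.log(u1) / (w * (m - kk))
            if x >= bound:
                break
            state = state + nb.uint64(0x9E3779B97F4A7C15)
            h = state
            h = (h ^ (h >> 30)) * nb.uint64(0xBF58476D1CE4E5B9)
            h = (h ^ (h >> 27)) * nb.uint64(0x94D049BB133111EB)
            h = h ^ (h >> 31)
            u2 = (nb.float64(h >> 11) + 0.5) * (1.0 / 9007199254740992.0)
            r = kk + int(u2 * (m - kk))
            if r >= m:
                r = m - 1
            ar = perm[r] if tag[r] == e else r
            ak = perm[kk] if tag[kk] == e else kk
            perm[r] = ak
            tag[r] = e
            perm[kk] = ar
            tag[kk] = e
            j = ar
            if x < reg_val[j] or (x == reg_val[j] and tokens[e] < reg_tok[j]):
                if reg_val[j] == np.inf:
                    filled += 1
                reg_val[j] = x
                reg_tok[j] = tokens[e]
                updates += 1
                if filled == m and (bound == np.inf or updates >= m):
                    bm = 0.0
                    for i in range(m):
                        if reg_val[i] > bm:
                            bm = reg_val[i]
                    bound = bm
                    updates = 0
    return reg_tok, reg_val


@nb.njit(cache=True)
def _superminhash_kernel(tokens, m, seed):
    reg = np.full(m, np.inf)
    perm = np.empty(m, np.int64)
    tag = np.full(m, -1, np.int64)
    bound = np.inf
    filled = 0
    updates = 0
    seedmix = seed
    seedmix = (seedmix ^ (seedmix >> 30)) * nb.uint64(0xBF58476D1CE4E5B9)
    seedmix = (seedmix ^ (seedmix >> 27)) * nb.uint64(0x94D049BB133111EB)
    seedmix = seedmix ^ (seedmix >> 31)
    for e in range(tokens.shape[0]):
        state = tokens[e] ^ seedmix
        state = (state ^ (state >> 30)) * nb.uint64(0xBF58476D1CE4E5B9)
        state = (state ^ (state >> 27)) * nb.uint64(0x94D049BB133111EB)
        state = state ^ (state >> 31)
        for jj in range(m):
            if nb.float64(jj) >= bound:
                break
            state = state + nb.uint64(0x9E3779B97F4A7C15)
            h = state
            h = (h ^ (h >> 30)) * nb.uint64(0xBF58476D1CE4E5B9)
            h = (h ^ (h >> 27)) * nb.uint64(0x94D049BB133111EB)
            h = h ^ (h >> 31)
            u = (nb.float64(h >> 11) + 0.5) * (1.0 / 9007199254740992.0)
            state = state + nb.uint64(0x9E3779B97F4A7C15)
            h = state
            h = (h ^ (h >> 30)) * nb.uint64(0xBF58476D1CE4E5B9)
            h = (h ^ (h >> 27)) * nb.uint64(0x94D049BB133111EB)
            h = h ^ (h >> 31)
            u2 = (nb.float64(h >> 11) + 0.5) * (1.0 / 9007199254740992.0)
            r = jj + int(u2 * (m - jj))
            if r >= m:
                r = m - 1
            ar = perm[r] if tag[r] == e else r
            ajj = perm[jj] if tag[jj] == e else jj
            perm[r] = ajj
            tag[r] = e
            perm[jj] = ar
            tag[jj] = e
            slot = ar
            v = u + jj
            if v < reg[slot]:
                if reg[slot] == np.inf:
                    filled += 1
                reg[slot] = v
                updates += 1
                if filled == m and (bound == np.inf or updates >= m):
                    bm = 0.0
                    for i in range(m):
                        if reg[i] > bm:
                            bm = reg[i]
                    bound = bm
                    updates = 0
    return reg


@nb.njit(cache=True)
def _setsketch_kernel(streams, m, lo_thresh, log_b, a, q):
    # streams: per-element seeded states; register r improves only if the
    # element's uniform exceeds lo_thresh[r] = exp(-a * b**(-r)), which
    # avoids a log for the overwhelming majority of draws.
    regs = np.zeros(m, np.int64)
    for e in range(streams.shape[0]):
        state = streams[e]
        for i in range(m):
            state = state + nb.uint64(0x9E3779B97F4A7C15)
            h = state
            h = (h ^ (h >> 30)) * nb.uint64(0xBF58476D1CE4E5B9)
            h = (h ^ (h >> 27)) * nb.uint64(0x94D049BB133111EB)
            h = h ^ (h >> 31)
            u = (nb.float64(h >> 11) + 0.5) * (1.0 / 9007199254740992.0)
            if u <= lo_thresh[regs[i]]:
                continue
            ex = -math.log(u)
            kv = 1 + int(math.floor(math.log(a / ex) / log_b))
            if kv > q + 1:
                kv = q + 1
            if kv > regs[i]:
                regs[i] = kv
    return regs


# ---------------------------------------------------------------------------
# sketch constructors


def _require_nonempty(ms: KmerMultiset) -> None:
    if not ms:
        raise ValueError("cannot sketch an empty k-mer multiset")


def _check_ms(ms: KmerMultiset, params: SketchParams) -> None:
    _require_nonempty(ms)
    if ms.k != params.k or ms.alphabet != params.alphabet:
        raise ValueError("multiset k/alphabet do not match sketch parameters")


def sketch_probminhash3a(ms: KmerMultiset, params: SketchParams) -> SketchVector:
    _check_ms(ms, params)
    tokens, weights = weight_arrays(ms)
    seed = np.uint64((params.seed & 0xFFFFFFFFFFFFFFFF) ^ _SALT[SketchAlgo.PROBMINHASH3A])
    reg_tok, _ = _probminhash_kernel(tokens, weights, params.m, seed)
    return SketchVector(params=params, registers=reg_tok)


def sketch_superminhash(ms: KmerMultiset, params: SketchParams) -> SketchVector:
    _check_ms(ms, params)
    seed = np.uint64((params.seed & 0xFFFFFFFFFFFFFFFF) ^ _SALT[SketchAlgo.SUPERMINHASH])
    reg = _superminhash_kernel(ms.tokens, params.m, seed)
    return SketchVector(params=params, registers=reg)


def sketch_oph_densified(ms: KmerMultiset, params: SketchParams,
                         variant: str | None = None) -> SketchVector:
    """One-permutation hashing with densification (single hash pass)."""
    _check_ms(ms, params)
    algo = params.algo if variant is None else (
        SketchAlgo.OPH_OPTIMAL if variant == "optimal" else SketchAlgo.OPH_FASTER)
    m = params.m
    h = seed_stream(ms.tokens, params.seed, _SALT[algo])
    bins = (to_unit(h) * m).astype(np.int64)
    np.clip(bins, 0, m - 1, out=bins)
    vals = np.full(m, np.iinfo(np.uint64).max, dtype=np.uint64)
    np.minimum.at(vals, bins, h)
    occupied = np.zeros(m, dtype=bool)
    occupied[bins] = True
    regs = vals.copy()
    empty = np.flatnonzero(~occupied)
    if empty.size == m:
        raise ValueError("empty support")
    if algo is SketchAlgo.OPH_OPTIMAL:
        dseed = np.uint64((params.seed & 0xFFFFFFFFFFFFFFFF) ^ _DENSIFY_SALT)
        with np.errstate(over="ignore"):
            for i in empty:
                t = np.uint64(0)
                base = mix64(np.uint64(i) * GOLDEN ^ dseed)
                while True:
                    j = int(mix64(base + t) % np.uint64(m))
                    if occupied[j]:
                        regs[i] = vals[j]
                        break
                    t += np.uint64(1)
    else:  # faster: fixed-direction rotation + bin-level re-randomization
        for i in empty:
            j = (i + 1) % m
            while not occupied[j]:
                j = (j + 1) % m
            regs[i] = mix64(vals[j] ^ mix64(np.uint64(i) + GOLDEN))
    return SketchVector(params=replace(params, algo=algo), registers=regs)


def sketch_setsketch(ms: KmerMultiset, params: SketchParams) -> SketchVector:
    _check_ms(ms, params)
    a, b, q = params.setsketch_a, params.setsketch_b, params.setsketch_q
    streams = seed_stream(ms.tokens, params.seed, _SALT[SketchAlgo.SETSKETCH])
    lo = np.exp(-a * np.float_power(b, -np.arange(q + 2, dtype=np.float64)))
    regs = _setsketch_kernel(streams, params.m, lo, math.log(b), a, q)
    return SketchVector(params=params, registers=regs)


_SKETCHERS = {
    SketchAlgo.PROBMINHASH3A: sketch_probminhash3a,
    SketchAlgo.SUPERMINHASH: sketch_superminhash,
    SketchAlgo.OPH_OPTIMAL: sketch_oph_densified,
    SketchAlgo.OPH_FASTER: sketch_oph_densified,
    SketchAlgo.SETSKETCH: sketch_setsketch,
}


def sketch(ms: KmerMultiset, params: SketchParams, genome_id: str = "") -> SketchVector:
    """Sketch a multiset with the algorithm named in ``params``."""
    sv = _SKETCHERS[params.algo](ms, params)
    sv.genome_id = genome_id
    return sv


# ---------------------------------------------------------------------------
# distance estimation


def default_estimator(algo: SketchAlgo) -> Estimator:
    return (Estimator.SETSKETCH_JMLE if algo is SketchAlgo.SETSKETCH
            else Estimator.REGISTER_MATCH)


def estimate_distance(sa: SketchVector, sb: SketchVector,
                      estimator: Estimator | str | None = None) -> float:
    """Estimated 1 − J_p (probminhash) or 1 − J (all others), in [0, 1]."""
    if not sa.params.compatible_with(sb.params):
        raise IncomparableSketches(
            "sketches built with different algo/m/k/alphabet/seed cannot be compared")
    algo = sa.params.algo
    estimator = Estimator(estimator) if estimator is not None else default_estimator(algo)
    if estimator is Estimator.REGISTER_MATCH:
        if algo is SketchAlgo.SETSKETCH:
            raise ValueError("register_match does not apply to setsketch registers")
        return 1.0 - float(np.mean(sa.registers == sb.registers))
    if algo is not SketchAlgo.SETSKETCH:
        raise ValueError(f"{estimator.value} applies only to setsketch sketches")
    if estimator is Estimator.SETSKETCH_LSH:
        j = setsketch_lsh_jaccard(sa, sb)
    else:
        j = setsketch_jmle_jaccard(sa, sb)
    return float(min(1.0, max(0.0, 1.0 - j)))


# ---------------------------------------------------------------------------
# setsketch estimators


def _ss_cdf_exponent(k: np.ndarray, b: float, q: int) -> np.ndarray:
    """g(k) with P(K <= k) = exp(-n*a*g(k)): b^-k, clamped so g(>=q+1)=0."""
    k = np.asarray(k, dtype=np.float64)
    g = np.float_power(b, -np.minimum(k, q))
    g = np.where(k >= q + 1, 0.0, g)
    g = np.where(k < 0, np.inf, g)
    return g


def setsketch_cardinality(sv: SketchVector) -> float:
    """Maximum-likelihood estimate of the support size from one sketch."""
    p = sv.params
    a, b, q = p.setsketch_a, p.setsketch_b, p.setsketch_q
    ks, cnt = np.unique(sv.registers, return_counts=True)
    gk = _ss_cdf_exponent(ks, b, q)
    gkm1 = _ss_cdf_exponent(ks - 1, b, q)

    def nll(ln_n: float) -> float:
        n = math.exp(ln_n)
        upper = np.exp(-n * a * gk)
        lower = np.where(np.isinf(gkm1), 0.0, np.exp(-n * a * np.where(np.isinf(gkm1), 0.0, gkm1)))
        pmf = np.clip(upper - lower, 1e-300, None)
        return -float((cnt * np.log(pmf)).sum())

    res = minimize_scalar(nll, bounds=(-5.0, 60.0), method="bounded",
                          options={"xatol": 1e-10})
    return math.exp(res.x)


def _ss_marginal_pmf(n: float, params: SketchParams, ks: np.ndarray) -> np.ndarray:
    a, b, q = params.setsketch_a, params.setsketch_b, params.setsketch_q
    gk = _ss_cdf_exponent(ks, b, q)
    gkm1 = _ss_cdf_exponent(ks - 1, b, q)
    upper = np.exp(-n * a * gk)
    lower = np.where(np.isinf(gkm1), 0.0, np.exp(-n * a * np.where(np.isinf(gkm1), 0.0, gkm1)))
    return np.clip(upper - lower, 0.0, None)


def setsketch_lsh_jaccard(sa: SketchVector, sb: SketchVector) -> float:
    """Register-equality estimate of J with the b-dependent correction.

    The fraction of equal registers is J plus the probability that two
    *different* dominating elements land in the same geometric bin; that
    accidental-collision probability is computed from the two sketches'
    estimated cardinalities and subtracted.
    """
    p = sa.params
    d0 = float(np.mean(sa.registers == sb.registers))
    na = setsketch_cardinality(sa)
    nb_ = setsketch_cardinality(sb)
    lo = max(0, int(min(sa.registers.min(), sb.registers.min())) - 64)
    hi = min(p.setsketch_q + 1, int(max(sa.registers.max(), sb.registers.max())) + 64)
    ks = np.arange(lo, hi + 1)
    eps = float((_ss_marginal_pmf(na, p, ks) * _ss_marginal_pmf(nb_, p, ks)).sum())
    if eps >= 1.0:
        return d0
    return min(1.0, max(0.0, (d0 - eps) / (1.0 - eps)))


def setsketch_jmle_jaccard(sa: SketchVector, sb: SketchVector) -> float:
    """Joint maximum-likelihood J from paired registers.

    The pair (K_A, K_B) decomposes through shared/exclusive supports with
    sizes (nS, nx, ny):  P(K_A<=x, K_B<=y) = exp(-a(nS g(min) + nx g(x) +
    ny g(y))); the pmf follows by finite differences and (nS, nx, ny) are
    fit by L-BFGS on log scale.  Returns nS / (nS + nx + ny).
    """
    p = sa.params
    a, b, q = p.setsketch_a, p.setsketch_b, p.setsketch_q
    if np.array_equal(sa.registers, sb.registers):
        # MLE limit: exclusive parts empty, J = 1
        return 1.0
    pair = sa.registers.astype(np.int64) * (q + 2) + sb.registers.astype(np.int64)
    up, cnt = np.unique(pair, return_counts=True)
    x = up // (q + 2)
    y = up % (q + 2)

    def g(k):
        return _ss_cdf_exponent(k, b, q)

    # the four finite-difference corners of the joint CDF, as (gm, gx, gy)
    # exponent triples with signs (+, -, -, +); inf exponents mean CDF = 0
    corners = [
        (1.0, g(np.minimum(x, y)), g(x), g(y)),
        (-1.0, g(np.minimum(x - 1, y)), g(x - 1), g(y)),
        (-1.0, g(np.minimum(x, y - 1)), g(x), g(y - 1)),
        (1.0, g(np.minimum(x - 1, y - 1)), g(x - 1), g(y - 1)),
    ]
    corners = [(s_, np.where(np.isinf(gm), np.inf, gm),
                np.where(np.isinf(gxx), np.inf, gxx),
                np.where(np.isinf(gyy), np.inf, gyy))
               for s_, gm, gxx, gyy in corners]

    def nll_grad(theta):
        ns, nx_, ny_ = theta
        pmf = np.zeros(len(x))
        dns = np.zeros(len(x))
        dnx = np.zeros(len(x))
        dny = np.zeros(len(x))
        for s_, gm, gxx, gyy in corners:
            dead = np.isinf(gm) | np.isinf(gxx) | np.isinf(gyy)
            gm0 = np.where(dead, 0.0, gm)
            gx0 = np.where(dead, 0.0, gxx)
            gy0 = np.where(dead, 0.0, gyy)
            f = np.where(dead, 0.0, np.exp(-a * (ns * gm0 + nx_ * gx0 + ny_ * gy0)))
            pmf += s_ * f
            dns += s_ * f * (-a * gm0)
            dnx += s_ * f * (-a * gx0)
            dny += s_ * f * (-a * gy0)
        pmf = np.clip(pmf, 1e-300, None)
        val = -float((cnt * np.log(pmf)).sum())
        w = cnt / pmf
        return val, -np.array([float((w * dns).sum()), float((w * dnx).sum()),
                               float((w * dny).sum())])

    na = setsketch_cardinality(sa)
    nb_ = setsketch_cardinality(sb)
    merged = SketchVector(params=p, registers=np.maximum(sa.registers, sb.registers))
    nu = max(setsketch_cardinality(merged), max(na, nb_))
    ns_ie = max(na + nb_ - nu, 1e-6)
    bounds = [(1e-9, None)] * 3
    best = None
    for ns0 in {ns_ie, max(0.01 * min(na, nb_), 1.0), 0.5 * min(na, nb_)}:
        x0 = np.array([ns0, max(na - ns0, 1e-6), max(nb_ - ns0, 1e-6)])
        res = minimize(nll_grad, x0, jac=True, method="L-BFGS-B",
                       bounds=bounds, options={"maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
    ns, nx_, ny_ = best.x
    return float(ns / (ns + nx_ + ny_))


def merge_setsketch(sa: SketchVector, sb: SketchVector) -> SketchVector:
    """Sketch of the union: element-wise register max (mergeability)."""
    if not sa.params.compatible_with(sb.params):
        raise IncomparableSketches("cannot merge sketches with different parameters")
    if sa.params.algo is not SketchAlgo.SETSKETCH:
        raise ValueError("merge by register max is defined for setsketch only")
    return SketchVector(params=sa.params, registers=np.maximum(sa.registers, sb.registers))
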