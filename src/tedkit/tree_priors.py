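"""Log-density evaluation for dated-tree priors.

Implements the uniform tree prior, the birth-death (BD) prior and the
fossilized birth-death (FBD) prior with complete, random or diversified
extant-tip sampling, a skyline (piecewise-constant-rate) FBD, and the
hyperpriors on the diversification parameters.

Parameterization
----------------
The diversification process is parameterized as in the tip-dating literature:

* net diversification  d = lambda - mu        (events / lineage / Myr)
* turnover             r = mu / lambda        in [0, 1)
* fossil sampling      f = psi / (mu + psi)   in [0, 1)

where lambda is the birth rate, mu the death rate and psi the fossil
recovery rate (fossilization times the probability of subsequent discovery).
Extant tips are sampled with probability rho at the present.

Conditioning convention
-----------------------
All BD/FBD densities condition on the root age (scored separately by
:class:`RootAgePrior`) and on both root children leaving at least one sampled
extant descendant.  Fossils are terminal tips with fixed ages; sampled
ancestors are not modelled.

Diversified sampling treats the n extant exemplars as spanning every split
older than the cutoff x_cut (the youngest sampled split): below x_cut the
process carries no data, so rho-sampling is replaced by the probability that
each sampled lineage crossing x_cut survives to the present and each
unsampled side lineage leaves no sampled descendant.  This is implemented by
inserting an interval boundary at x_cut with psi = 0 below it, reusing the
skyline machinery.  log(0) regions return -inf rather than raising, so MCMC
can reject.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from tedkit.timetree import TimeTree, youngest_split_age

__all__ = [
    "FBDParams",
    "SkylineFBDParams",
    "RootAgePrior",
    "HyperPriors",
    "HYPERPRIOR_PRESETS",
    "convert_drf",
    "convert_lmp",
    "bd_p0",
    "bd_p1",
    "bd_log_density",
    "fbd_log_density",
    "uniform_tree_log_density",
    "skyline_fbd_log_density",
    "hyperprior_log_density",
]

NEG_INF = float("-inf")

SamplingMode = Literal["complete", "random", "diversified"]


def convert_drf(d: float, r: float, f: float) -> tuple[float, float, float]:
    """(d, r, f) -> (lambda, mu, psi).

    Inverts the defining identities d = lambda - mu, r = mu/lambda,
    f = psi/(mu + psi).
    """
    if not d > 0:
        raise ValueError("net diversification d must be > 0")
    if not (0 <= r < 1):
        raise ValueError("turnover r must be in [0, 1)")
    if not (0 <= f < 1):
        raise ValueError("fossil sampling probability f must be in [0, 1)")
    lam = d / (1.0 - r)
    mu = lam * r
    psi = f * mu / (1.0 - f)
    return lam, mu, psi


def convert_lmp(lam: float, mu: float, psi: float) -> tuple[float, float, float]:
    """(lambda, mu, psi) -> (d, r, f); inverse of :func:`convert_drf`."""
    if not lam > 0:
        raise ValueError("birth rate must be > 0")
    d = lam - mu
    r = mu / lam
    f = psi / (mu + psi) if (mu + psi) > 0 else 0.0
    return d, r, f


@dataclass(frozen=True)
class FBDParams:
    """Diversification-process parameters in (d, r, f) form.

    ``rho`` is the extant sampling fraction, used by the random sampling
    mode; complete sampling forces rho = 1 and diversified sampling replaces
    rho-sampling below the cutoff altogether.
    """

    d: float
    r: float = 0.0
    f: float = 0.0
    rho: float = 1.0
    sampling_mode: SamplingMode = "complete"

    def __post_init__(self):
        convert_drf(self.d, self.r, self.f)  # validates ranges
        if not (0 < self.rho <= 1):
            raise ValueError("rho must be in (0, 1]")
        if self.sampling_mode not in ("complete", "random", "diversified"):
            raise ValueError(f"unknown sampling mode {self.sampling_mode!r}")

    @property
    def lam(self) -> float:
        return convert_drf(self.d, self.r, self.f)[0]

    @property
    def mu(self) -> float:
        return convert_drf(self.d, self.r, self.f)[1]

    @property
    def psi(self) -> float:
        return convert_drf(self.d, self.r, self.f)[2]

    @property
    def effective_rho(self) -> float:
        return 1.0 if self.sampling_mode == "complete" else self.rho


@dataclass(frozen=True)
class SkylineFBDParams:
    """Piecewise-constant FBD parameters.

    ``boundaries`` are interval limits in Ma, strictly decreasing (e.g. the
    default (70, 55) gives three intervals: older than 70, 70-55, younger
    than 55).  ``intervals`` lists one :class:`FBDParams` per interval from
    oldest to youngest; sampling mode and rho are taken from the youngest
    interval and must be shared.
    """

    boundaries: tuple[float, ...] = (70.0, 55.0)
    intervals: tuple[FBDParams, ...] = ()

    def __post_init__(self):
        bs = tuple(float(b) for b in self.boundaries)
        if any(b2 >= b1 for b1, b2 in zip(bs, bs[1:])):
            raise ValueError("boundaries must be strictly decreasing")
        if len(self.intervals) != len(bs) + 1:
            raise ValueError("need exactly len(boundaries)+1 parameter sets")
        rhos = {p.rho for p in self.intervals}
        modes = {p.sampling_mode for p in self.intervals}
        if len(rhos) > 1 or len(modes) > 1:
            raise ValueError("rho and sampling_mode must be shared")
        object.__setattr__(self, "boundaries", bs)

    @property
    def sampling_mode(self) -> SamplingMode:
        return self.intervals[0].sampling_mode

    @property
    def rho(self) -> float:
        return self.intervals[0].rho


@dataclass(frozen=True)
class RootAgePrior:
    """Offset-exponential prior on the root age.

    rate = 1/(mean - offset).  The effective lower bound is the larger of
    the offset and the oldest fossil age (hard reject below it); the density
    above the bound is the untruncated offset-exponential, so truncation
    contributes only a constant that cancels in MCMC.
    """

    mean: float = 164.0
    offset: float = 64.0

    def __post_init__(self):
        if not self.mean > self.offset > 0:
            raise ValueError("need mean > offset > 0")

    @property
    def rate(self) -> float:
        return 1.0 / (self.mean - self.offset)

    def effective_minimum(self, oldest_fossil_age: float = 0.0) -> float:
        return max(self.offset, oldest_fossil_age)

    def log_density(self, age: float, oldest_fossil_age: float = 0.0) -> float:
        if age < self.effective_minimum(oldest_fossil_age):
            return NEG_INF
        return math.log(self.rate) - self.rate * (age - self.offset)

    def sample(self, rng: np.random.Generator,
               oldest_fossil_age: float = 0.0) -> float:
        lo = self.effective_minimum(oldest_fossil_age)
        # inverse-CDF draw from the exponential truncated to [lo, inf)
        return lo + rng.exponential(1.0 / self.rate)


# ---------------------------------------------------------------------------
# hyperpriors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HyperPriors:
    """Priors on (d, r, f).

    ``d_prior`` is either ("exp", rate) or ("fixed", value); ``r_prior`` and
    ``f_prior`` are Beta(a, b) pairs with support taken as the open interval
    (0, 1).
    """

    d_prior: tuple[str, float] = ("exp", 10.0)
    r_prior: tuple[float, float] = (1.0, 1.0)
    f_prior: tuple[float, float] = (1.0, 1.0)
    name: str = "custom"

    @property
    def d_fixed(self) -> float | None:
        return self.d_prior[1] if self.d_prior[0] == "fixed" else None

    def sample(self, rng: np.random.Generator) -> tuple[float, float, float]:
        if self.d_prior[0] == "fixed":
            d = self.d_prior[1]
        else:
            d = rng.exponential(1.0 / self.d_prior[1])
        r = rng.beta(*self.r_prior)
        f = rng.beta(*self.f_prior)
        return d, r, f


HYPERPRIOR_PRESETS: dict[str, HyperPriors] = {
    # vague: Exp(10) on d (expectation 0.1), flat Beta(1,1) on r and f
    "vague": HyperPriors(("exp", 10.0), (1.0, 1.0), (1.0, 1.0), "vague"),
    # rare extinction: Beta(1,100) pulls turnover towards 0
    "low_extinction": HyperPriors(("exp", 10.0), (1.0, 100.0), (1.0, 1.0),
                                  "low_extinction"),
    # high fossil recovery: Beta(100,1) pulls f towards 1
    "high_fossil_sampling": HyperPriors(("exp", 10.0), (1.0, 1.0),
                                        (100.0, 1.0), "high_fossil_sampling"),
    "low_ext_high_fs": HyperPriors(("exp", 10.0), (1.0, 100.0), (100.0, 1.0),
                                   "low_ext_high_fs"),
    # rapid diversification: d fixed at 0.1, flat r and f
    "rapid_diversification": HyperPriors(("fixed", 0.1), (1.0, 1.0),
                                         (1.0, 1.0), "rapid_diversification"),
}


def hyperprior_log_density(p: FBDParams, h: HyperPriors) -> float:
    """Sum of log prior densities of d, r and f.

    A fixed d contributes 0 (and pins the value: mismatch is -inf).
    Out-of-support values return -inf.
    """
    total = 0.0
    if h.d_prior[0] == "fixed":
        if not math.isclose(p.d, h.d_prior[1], rel_tol=1e-12, abs_tol=1e-12):
            return NEG_INF
    else:
        rate = h.d_prior[1]
        if p.d <= 0:
            return NEG_INF
        total += math.log(rate) - rate * p.d
    for value, (a, b) in ((p.r, h.r_prior), (p.f, h.f_prior)):
        if not (0 < value < 1):
            # endpoint 0 is allowed when the Beta density is finite there
            if value == 0.0 and a == 1.0:
                total += stats.beta.logpdf(1e-300, a, b)
                continue
            return NEG_INF
        total += stats.beta.logpdf(value, a, b)
    return total


# ---------------------------------------------------------------------------
# BD closed forms
# ---------------------------------------------------------------------------

def bd_p0(t, lam: float, mu: float, rho: float = 1.0):
    """P(no sampled extant descendant) for a lineage at age t (rho-sampled BD)."""
    t = np.asarray(t, dtype=float)
    net = lam - mu
    denom = rho * lam + (lam * (1 - rho) - mu) * np.exp(-net * t)
    return 1.0 - rho * net / denom


def bd_p1(t, lam: float, mu: float, rho: float = 1.0):
    """Density-like probability of exactly one sampled extant descendant with
    no reconstructed split, for a lineage at age t."""
    t = np.asarray(t, dtype=float)
    net = lam - mu
    denom = rho * lam + (lam * (1 - rho) - mu) * np.exp(-net * t)
    return rho * net**2 * np.exp(-net * t) / denom**2


# ---------------------------------------------------------------------------
# piecewise-constant FBD engine
# ---------------------------------------------------------------------------

class _PiecewiseFBD:
    """p0 and log q for a piecewise-constant (lambda, mu, psi) process.

    ``edges`` are ascending interval lower edges starting at 0; interval i
    spans [edges[i], edges[i+1]).  ``p0_init`` is the value of p0 at age 0
    (1 - rho for rho-sampling at the present).  Within each interval the
    standard constant-rate solution applies, with the integration constant
    c2 chosen so that p0 and q are continuous across boundaries.
    """

    def __init__(self, edges: Sequence[float], lams: Sequence[float],
                 mus: Sequence[float], psis: Sequence[float], p0_init: float):
        self.edges = [float(e) for e in edges]
        assert self.edges[0] == 0.0
        self.lams = list(map(float, lams))
        self.mus = list(map(float, mus))
        self.psis = list(map(float, psis))
        self.c1: list[float] = []
        self.c2: list[float] = []
        self.logq_base: list[float] = []  # accumulated log q at interval lower edge
        p0 = float(p0_init)
        logq = 0.0
        for i, (lam, mu, psi) in enumerate(zip(self.lams, self.mus, self.psis)):
            c1 = math.sqrt((lam - mu - psi) ** 2 + 4 * lam * psi)
            if c1 <= 0:
                raise ValueError("degenerate process: c1 = 0 (lambda=mu, psi=0)")
            c2 = (lam + mu + psi - 2 * lam * p0) / c1
            self.c1.append(c1)
            self.c2.append(c2)
            self.logq_base.append(logq)
            if i + 1 < len(self.edges):
                width = self.edges[i + 1] - self.edges[i]
                p0 = self._p0_interval(i, width)
                logq += self._logq_interval(i, width)

    def _interval_of(self, t: float) -> int:
        i = len(self.edges) - 1
        while i > 0 and t < self.edges[i]:
            i -= 1
        return i

    def _p0_interval(self, i: int, dt: float) -> float:
        lam, mu, psi = self.lams[i], self.mus[i], self.psis[i]
        c1, c2 = self.c1[i], self.c2[i]
        e = math.exp(-c1 * dt)
        frac = (e * (1 - c2) - (1 + c2)) / (e * (1 - c2) + (1 + c2))
        return (lam + mu + psi + c1 * frac) / (2 * lam)

    def _logq_interval(self, i: int, dt: float) -> float:
        c1, c2 = self.c1[i], self.c2[i]
        # log[4 e^{-c1 dt} / (e^{-c1 dt}(1-c2) + (1+c2))^2]; equals 0 at dt=0
        e = math.exp(-c1 * dt)
        denom = e * (1 - c2) + (1 + c2)
        if denom <= 0:
            return NEG_INF
        return math.log(4.0) - c1 * dt - 2.0 * math.log(denom)

    def p0(self, t: float) -> float:
        i = self._interval_of(t)
        return self._p0_interval(i, t - self.edges[i])

    def log_q(self, t: float) -> float:
        i = self._interval_of(t)
        return self.logq_base[i] + self._logq_interval(i, t - self.edges[i])

    def lam_at(self, t: float) -> float:
        return self.lams[self._interval_of(t)]

    def psi_at(self, t: float) -> float:
        return self.psis[self._interval_of(t)]


def _tree_arrays(tree: TimeTree):
    internal = tree.internal_nodes()
    root_age = tree.root.age
    nonroot_internal_ages = [n.age for n in internal if n is not tree.root]
    fossil_ages = [t.age for t in tree.fossil_tips()]
    n_extant = len(tree.extant_tips())
    return root_age, nonroot_internal_ages, fossil_ages, n_extant


def _process_log_density(tree: TimeTree, edges: list[float],
                         lams: list[float], mus: list[float],
                         psis: list[float], rho: float,
                         mode: SamplingMode,
                         root_prior: RootAgePrior) -> float:
    """Shared BD/FBD/skyline density on the q-function form."""
    root_age, node_ages, fossil_ages, n_extant = _tree_arrays(tree)
    oldest_fossil = max(fossil_ages) if fossil_ages else 0.0
    log_root = root_prior.log_density(root_age, oldest_fossil)
    if log_root == NEG_INF:
        return NEG_INF
    # support restriction matching the conditioning: each root child must
    # subtend at least one sampled extant tip
    for child in tree.root.children:
        sub = TimeTree(child, validate=False)
        if not any(not t.is_fossil for t in sub.tips()):
            return NEG_INF

    if mode == "diversified":
        x_cut = youngest_split_age(tree)
        if any(y <= x_cut for y in fossil_ages):
            return NEG_INF  # fossil younger than the sampling cutoff
        # below x_cut: same birth/death rates, no fossil recovery, and
        # "sampling" means survival to the present (rho = 1 at age 0)
        pts = sorted({0.0, x_cut, *(e for e in edges if e > 0.0)})
        full_edges, full_l, full_m, full_p = [], [], [], []
        for lo in pts:
            idx = _interval_index(edges, lo)
            full_edges.append(lo)
            full_l.append(lams[idx])
            full_m.append(mus[idx])
            full_p.append(0.0 if lo < x_cut else psis[idx])
        engine = _PiecewiseFBD(full_edges, full_l, full_m, full_p, p0_init=0.0)
        surv = _PiecewiseFBD(full_edges, full_l, full_m,
                             [0.0] * len(full_l), p0_init=0.0)
        tip_term = n_extant * (
            _log(1.0 - engine.p0(x_cut)) - engine.log_q(x_cut))
    else:
        eff_rho = 1.0 if mode == "complete" else rho
        engine = _PiecewiseFBD(edges, lams, mus, psis, p0_init=1.0 - eff_rho)
        surv = _PiecewiseFBD(edges, lams, mus, [0.0] * len(lams),
                             p0_init=1.0 - eff_rho)
        tip_term = n_extant * math.log(eff_rho)

    total = log_root + tip_term
    for x in node_ages:
        total += _log(engine.lam_at(x)) + engine.log_q(x)
    total += 2.0 * engine.log_q(root_age)
    for y in fossil_ages:
        psi_y = engine.psi_at(y)
        if psi_y <= 0:
            return NEG_INF
        total += math.log(psi_y) + _log(engine.p0(y)) - engine.log_q(y)
    # condition on both root children leaving >= 1 sampled extant descendant
    total -= 2.0 * _log(1.0 - surv.p0(root_age))
    return total


def _log(x: float) -> float:
    return math.log(x) if x > 0 else NEG_INF


def _first_ge(edges: list[float], x: float) -> int:
    for i, e in enumerate(edges):
        if e >= x:
            return i
    return len(edges)


def _interval_index(edges: list[float], x: float) -> int:
    i = len(edges) - 1
    while i > 0 and x < edges[i]:
        i -= 1
    return i


def _check_binary_no_polytomy(tree: TimeTree):
    for node in tree.internal_nodes():
        if len(node.children) != 2:
            raise ValueError("tree must be strictly binary")


def bd_log_density(tree: TimeTree, p: FBDParams,
                   root_prior: RootAgePrior) -> float:
    """Log prior density of a dated extant-only tree under the rho-sampled
    birth-death process, conditioned on the root age (scored by
    ``root_prior``) and on both root children surviving to the sample."""
    _check_binary_no_polytomy(tree)
    if tree.fossil_tips():
        raise ValueError("BD prior applies to extant-only trees; "
                         "use fbd_log_density for trees with fossil tips")
    lam, mu, _ = convert_drf(p.d, p.r, 0.0)
    if p.sampling_mode == "diversified":
        return _process_log_density(tree, [0.0], [lam], [mu], [0.0], p.rho,
                                    "diversified", root_prior)
    rho = p.effective_rho
    root_age, node_ages, _, n_extant = _tree_arrays(tree)
    log_root = root_prior.log_density(root_age, 0.0)
    if log_root == NEG_INF:
        return NEG_INF
    total = log_root + n_extant * math.log(rho)
    for x in node_ages:
        total += _log(lam * bd_p1(x, lam, mu, rho) / rho)
    total += 2.0 * _log(bd_p1(root_age, lam, mu, rho) / rho)
    total -= 2.0 * _log(1.0 - bd_p0(root_age, lam, mu, rho))
    return total


def fbd_log_density(tree: TimeTree, p: FBDParams,
                    root_prior: RootAgePrior) -> float:
    """Log density of a dated tree (fossils as terminal tips) under the
    fossilized birth-death process; reduces to :func:`bd_log_density` when
    psi = 0 and the tree has no fossils."""
    _check_binary_no_polytomy(tree)
    lam, mu, psi = convert_drf(p.d, p.r, p.f)
    if psi == 0.0 and tree.fossil_tips():
        return NEG_INF
    return _process_log_density(tree, [0.0], [lam], [mu], [psi], p.rho,
                                p.sampling_mode, root_prior)


def skyline_fbd_log_density(tree: TimeTree, p: SkylineFBDParams,
                            root_prior: RootAgePrior) -> float:
    """Piecewise-constant-rate FBD density; p0 and q are propagated across
    interval boundaries by continuity."""
    _check_binary_no_polytomy(tree)
    # boundaries given old -> young; engine wants ascending lower edges
    edges = [0.0] + sorted(p.boundaries)
    params = list(reversed(p.intervals))  # youngest first
    lams, mus, psis = [], [], []
    for q in params:
        lam, mu, psi = convert_drf(q.d, q.r, q.f)
        lams.append(lam); mus.append(mu); psis.append(psi)
    if any(ps == 0.0 for ps in psis) and tree.fossil_tips():
        fossil_ages = [t.age for t in tree.fossil_tips()]
        for y in fossil_ages:
            if psis[_interval_index(edges, y)] == 0.0:
                return NEG_INF
    return _process_log_density(tree, edges, lams, mus, psis, p.rho,
                                p.sampling_mode, root_prior)


# ---------------------------------------------------------------------------
# uniform tree prior
# ---------------------------------------------------------------------------

class _PiecewisePoly:
    """Piecewise polynomial on [0, 1] used for exact feasible-volume
    integration of the uniform tree prior; pieces[(lo, hi)] -> coefficient
    array (ascending powers).  Value is 0 below the first knot."""

    def __init__(self, knots: list[float], coefs: list[np.ndarray]):
        self.knots = knots  # ascending, length m+1, pieces between knots
        self.coefs = coefs  # length m

    @classmethod
    def indicator_above(cls, a: float) -> "_PiecewisePoly":
        return cls([a, 1.0], [np.array([1.0])])

    def __call__(self, x: float) -> float:
        if x < self.knots[0]:
            return 0.0
        return float(np.polynomial.polynomial.polyval(x, self._coef_at(x)))

    def multiply(self, other: "_PiecewisePoly") -> "_PiecewisePoly":
        knots = sorted(set(self.knots) | set(other.knots))
        lo0 = max(self.knots[0], other.knots[0])
        knots = [k for k in knots if k >= lo0]
        if knots[0] > lo0:
            knots.insert(0, lo0)
        coefs = []
        for lo, hi in zip(knots, knots[1:]):
            mid = 0.5 * (lo + hi)
            c1 = self._coef_at(mid)
            c2 = other._coef_at(mid)
            coefs.append(np.polynomial.polynomial.polymul(c1, c2))
        return _PiecewisePoly(knots, coefs)

    def _coef_at(self, x: float) -> np.ndarray:
        for (lo, hi), c in zip(zip(self.knots, self.knots[1:]), self.coefs):
            if lo <= x < hi:
                return c
        return self.coefs[-1]

    def integrate(self) -> "_PiecewisePoly":
        """Return F(x) = integral from the first knot to x."""
        acc = 0.0
        coefs = []
        for (lo, hi), c in zip(zip(self.knots, self.knots[1:]), self.coefs):
            C = np.polynomial.polynomial.polyint(c)
            lo_val = float(np.polynomial.polynomial.polyval(lo, C))
            # piece value: acc + int_lo^x = acc - C(lo) + C(x)
            piece = C.copy()
            piece[0] += acc - lo_val
            coefs.append(piece)
            acc = acc - lo_val + float(np.polynomial.polynomial.polyval(hi, C))
        return _PiecewisePoly(list(self.knots), coefs)


def _feasible_volume_scaled(tree: TimeTree) -> float:
    """Volume of the feasible internal-age polytope with ages scaled by the
    root age, root fixed at 1.  Exact piecewise-polynomial integration."""
    T = tree.root.age

    def F(node) -> _PiecewisePoly:
        # F(node)(s) = volume of node's subtree configurations given parent
        # age s (scaled); for a tip this is the indicator s > tip age.
        if node.is_tip:
            return _PiecewisePoly.indicator_above(min(node.age / T, 1.0))
        g = F(node.children[0]).multiply(F(node.children[1]))
        return g.integrate()

    g_root = F(tree.root.children[0]).multiply(F(tree.root.children[1]))
    return g_root(1.0)


def uniform_tree_log_density(tree: TimeTree,
                             root_prior: RootAgePrior) -> float:
    """Uniform dated-tree prior: the root age is scored by ``root_prior``;
    conditional on root age, topology and tip ages, the free internal node
    ages are uniform over the feasible age polytope.  The normalizing volume
    is computed exactly by recursive piecewise-polynomial integration."""
    _check_binary_no_polytomy(tree)
    root_age, node_ages, fossil_ages, _ = _tree_arrays(tree)
    oldest_fossil = max(fossil_ages) if fossil_ages else 0.0
    log_root = root_prior.log_density(root_age, oldest_fossil)
    if log_root == NEG_INF:
        return NEG_INF
    # feasibility
    for node in tree.internal_nodes():
        for child in node.children:
            if node.age <= child.age:
                return NEG_INF
    n_free = len(node_ages)
    if n_free == 0:
        return log_root
    vol_scaled = _feasible_volume_scaled(tree)
    if vol_scaled <= 0:
        return NEG_INF
    return log_root - math.log(vol_scaled) - n_free * math.log(root_age)
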