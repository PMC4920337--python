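"""Morphological and molecular character likelihoods on dated trees.

Morphology uses the Mk model (k-state symmetric rates, one k per character)
with discrete-gamma rate variation and the "Mkv" ascertainment correction for
matrices containing only variable characters.  Molecular partitions use
GTR + Gamma(4) + invariable sites with fixed exchangeabilities.  Branch
lengths enter as *effective lengths* (expected changes per character), so the
same machinery serves strict and relaxed clocks; per-partition rate
multipliers with a weighted-Dirichlet prior scale them.

Missing states ('?') and gaps contribute partial likelihood 1 for every
state.  Underflow is handled by per-node rescaling of partial likelihoods.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from tedkit.timetree import TimeTree, Node

__all__ = [
    "MorphMatrix",
    "MolAlignment",
    "GTRPartitionParams",
    "SiteModelParams",
    "PartitionRates",
    "discretize_gamma",
    "mk_transition_probs",
    "gtr_rate_matrix",
    "pruning_loglik",
    "mkv_correction",
    "partition_rate_log_prior",
    "filter_characters",
]

logger = logging.getLogger(__name__)

MISSING = -1
DNA_STATES = "ACGT"
NEG_INF = float("-inf")


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class MorphMatrix:
    """Discrete morphological matrix.

    ``states`` is an (n_taxa, n_chars) int array with -1 for missing;
    ``k`` holds the per-character state count (>= 2).  ``variable_only``
    declares that constant characters were removed before analysis, which
    triggers the Mkv ascertainment correction in the likelihood.
    """

    taxa: list[str]
    states: np.ndarray
    k: np.ndarray
    variable_only: bool = True

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.int8)
        self.k = np.asarray(self.k, dtype=np.int64)
        if self.states.shape != (len(self.taxa), len(self.k)):
            raise ValueError("states shape must be (n_taxa, n_chars)")
        if np.any(self.k < 2):
            raise ValueError("per-character state count must be >= 2")
        for j in range(self.n_chars):
            col = self.states[:, j]
            obs = col[col >= 0]
            if np.any(obs >= self.k[j]):
                raise ValueError(f"character {j}: state out of range")
            if self.variable_only and obs.size and np.all(obs == obs[0]):
                raise ValueError(
                    f"character {j} is constant but variable_only is set")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_chars(self) -> int:
        return len(self.k)

    def subset_taxa(self, keep: Sequence[str]) -> "MorphMatrix":
        idx = [self.taxa.index(t) for t in keep]
        return MorphMatrix(list(keep), self.states[idx], self.k.copy(),
                           variable_only=False)


@dataclass
class MolAlignment:
    """Partitioned nucleotide alignment.

    ``sites`` is (n_taxa, n_sites) int with A,C,G,T = 0..3 and -1 for
    gap/missing; ``partition_map`` assigns each site to one partition index;
    ``partition_names`` names them (e.g. codon positions and UTR).
    """

    taxa: list[str]
    sites: np.ndarray
    partition_map: np.ndarray
    partition_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.sites = np.asarray(self.sites, dtype=np.int8)
        self.partition_map = np.asarray(self.partition_map, dtype=np.int64)
        if self.sites.shape != (len(self.taxa), self.partition_map.size):
            raise ValueError("sites shape must be (n_taxa, n_sites)")
        nparts = int(self.partition_map.max()) + 1 if self.partition_map.size else 0
        if not self.partition_names:
            self.partition_names = [f"part{i+1}" for i in range(nparts)]
        if len(self.partition_names) < nparts:
            raise ValueError("partition_names shorter than partition count")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return self.sites.shape[1]

    @property
    def n_partitions(self) -> int:
        return len(self.partition_names)

    def subset_taxa(self, keep: Sequence[str]) -> "MolAlignment":
        idx = [self.taxa.index(t) for t in keep]
        return MolAlignment(list(keep), self.sites[idx],
                            self.partition_map.copy(),
                            list(self.partition_names))


@dataclass
class GTRPartitionParams:
    """GTR + Gamma + I parameters for one molecular partition.

    ``exch`` are the six exchangeabilities in the order AC, AG, AT, CG, CT,
    GT; ``freqs`` the stationary base frequencies (sum 1).
    """

    exch: np.ndarray = field(
        default_factory=lambda: np.ones(6))
    freqs: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))
    alpha: float = 1.0
    ncat: int = 4
    pinv: float = 0.0

    def __post_init__(self):
        self.exch = np.asarray(self.exch, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.exch.size != 6 or np.any(self.exch <= 0):
            raise ValueError("need 6 positive exchangeabilities")
        if self.freqs.size != 4 or abs(self.freqs.sum() - 1) > 1e-9:
            raise ValueError("frequencies must sum to 1")
        if not self.alpha > 0:
            raise ValueError("alpha must be > 0")
        if not (0 <= self.pinv < 1):
            raise ValueError("pinv must be in [0, 1)")


@dataclass
class SiteModelParams:
    """Site-model parameters: one shared morphological gamma shape plus one
    GTR parameter set per molecular partition.  Morphology has no invariable
    class (its ascertainment correction conditions on variability)."""

    morph_alpha: float = 1.0
    morph_ncat: int = 4
    gtr: list[GTRPartitionParams] = field(default_factory=list)

    def __post_init__(self):
        if not self.morph_alpha > 0:
            raise ValueError("morph_alpha must be > 0")


@dataclass
class PartitionRates:
    """Per-partition rate multipliers m_i with weights w_i proportional to
    partition character counts, constrained so the average rate across
    characters is 1: sum(w_i * m_i) = 1 with sum(w_i) = 1."""

    multipliers: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        self.multipliers = np.asarray(self.multipliers, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.multipliers.shape != self.weights.shape:
            raise ValueError("multipliers and weights must align")
        if np.any(self.multipliers <= 0):
            raise ValueError("multipliers must be > 0")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        if abs(float(self.weights @ self.multipliers) - 1.0) > 1e-9:
            raise ValueError("weighted mean of multipliers must be 1")

    @classmethod
    def flat(cls, counts: Sequence[int]) -> "PartitionRates":
        w = np.asarray(counts, dtype=float)
        w = w / w.sum()
        return cls(np.ones_like(w), w)


# ---------------------------------------------------------------------------
# rate machinery
# ---------------------------------------------------------------------------

_GAMMA_CACHE: dict[tuple[float, int], np.ndarray] = {}


def discretize_gamma(alpha: float, ncat: int) -> np.ndarray:
    """Mean-of-quantile-bin discrete gamma category rates (mean exactly 1).

    The mean-1 gamma is cut at its ncat-quantiles; each category rate is the
    conditional mean within its bin, computed from the closed-form identity
    E[X; X in (a,b)] = F_{alpha+1}(b) - F_{alpha+1}(a) for X ~ Gamma(alpha,
    1/alpha), then renormalized so the rates average exactly 1.
    """
    if not alpha > 0:
        raise ValueError("alpha must be > 0")
    if ncat < 1:
        raise ValueError("ncat must be >= 1")
    if ncat == 1:
        return np.ones(1)
    key = (float(alpha), int(ncat))
    hit = _GAMMA_CACHE.get(key)
    if hit is not None:
        return hit
    qs = np.arange(1, ncat) / ncat
    bounds = stats.gamma.ppf(qs, a=alpha, scale=1.0 / alpha)
    bounds = np.concatenate([[0.0], bounds, [np.inf]])
    upper_cdf = stats.gamma.cdf(bounds[1:], a=alpha + 1, scale=1.0 / alpha)
    lower_cdf = stats.gamma.cdf(bounds[:-1], a=alpha + 1, scale=1.0 / alpha)
    rates = ncat * (upper_cdf - lower_cdf)
    rates = rates / rates.mean()
    if len(_GAMMA_CACHE) > 512:
        _GAMMA_CACHE.clear()
    _GAMMA_CACHE[key] = rates
    return rates


def mk_transition_probs(k: int, t: np.ndarray) -> np.ndarray:
    """Mk transition probabilities for effective lengths ``t``.

    Returns array of shape t.shape + (k, k).  The Mk rate matrix has equal
    off-diagonal rates normalized to one expected change per unit length.
    """
    t = np.asarray(t, dtype=float)
    e = np.exp(-k * t / (k - 1))
    p_same = 1.0 / k + (k - 1) / k * e
    p_diff = 1.0 / k - 1.0 / k * e
    out = np.empty(t.shape + (k, k))
    out[...] = p_diff[..., None, None]
    idx = np.arange(k)
    out[..., idx, idx] = p_same[..., None]
    return out


def gtr_rate_matrix(params: GTRPartitionParams) -> np.ndarray:
    """GTR rate matrix normalized to one expected substitution per unit
    length at stationarity."""
    s = params.exch
    pi = params.freqs
    Q = np.zeros((4, 4))
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    for rate, (i, j) in zip(s, pairs):
        Q[i, j] = rate * pi[j]
        Q[j, i] = rate * pi[i]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -(pi * np.diag(Q)).sum()
    return Q / scale


class _GTRTransition:
    """Eigendecomposition-backed transition probabilities for a reversible
    rate matrix (cached per parameter set)."""

    def __init__(self, params: GTRPartitionParams):
        Q = gtr_rate_matrix(params)
        pi = params.freqs
        sq = np.sqrt(pi)
        S = Q * sq[:, None] / sq[None, :]  # symmetric similarity transform
        w, U = np.linalg.eigh((S + S.T) / 2.0)
        self.w = w
        self.left = U / sq[None, :].T  # rows scaled: diag(1/sq) @ U
        self.right = U.T * sq[None, :]  # U.T @ diag(sq)

    def probs(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        expwt = np.exp(np.multiply.outer(t, self.w))  # t.shape + (4,)
        P = np.einsum("ik,...k,kj->...ij", self.left, expwt, self.right)
        return np.clip(P, 0.0, None)


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------

def _postorder_with_index(tree: TimeTree):
    nodes = list(tree.postorder())
    index = {id(n): i for i, n in enumerate(nodes)}
    return nodes, index


def _branch_length_of(eff_lengths, node: Node) -> float:
    from tedkit.clocks import BranchEffects
    if isinstance(eff_lengths, BranchEffects):
        return eff_lengths.length_of(node)
    return float(eff_lengths[id(node)])


class _TreeContext:
    """Postorder node list and per-branch effective lengths, shared by all
    character blocks within one likelihood evaluation."""

    def __init__(self, tree: TimeTree, eff_lengths):
        self.nodes, self.index = _postorder_with_index(tree)
        self.root_index = self.index[id(tree.root)]
        lengths = np.zeros(len(self.nodes))
        for i, n in enumerate(self.nodes):
            if n.parent is not None:
                lengths[i] = _branch_length_of(eff_lengths, n)
        if np.any(lengths < 0):
            raise ValueError("negative effective branch length")
        self.lengths = lengths


def _prune_exec(ctx: _TreeContext, tip_rows: dict[str, int],
                patterns: np.ndarray, k: int, P_all: np.ndarray,
                freqs: np.ndarray) -> np.ndarray:
    """Per-pattern, gamma-mixed log-likelihoods.

    ``patterns``: (n_taxa, n_pat) int with -1 missing; ``P_all``:
    (n_nodes, ncat, k, k) transition matrices for the branch above each
    node.  Returns per-pattern log-likelihoods mixed over categories.
    """
    nodes = ctx.nodes
    n_pat = patterns.shape[1]
    ncat = P_all.shape[1]
    partial = [None] * len(nodes)
    logscale = np.zeros((ncat, n_pat))
    for ni, node in enumerate(nodes):
        if node.is_tip:
            if node.label not in tip_rows:
                raise ValueError(f"taxon {node.label!r} missing from data")
            continue  # tip partials are folded into the parent via a gather
        acc = None
        for child in node.children:
            ci = ctx.index[id(child)]
            if child.is_tip:
                obs = patterns[tip_rows[child.label]]
                # P[:, :, obs] gathers the conditional likelihood of the
                # observed state; missing data contribute 1 for all states
                down = P_all[ci][:, :, np.clip(obs, 0, k - 1)] \
                    .transpose(0, 2, 1)
                miss = obs < 0
                if miss.any():
                    down = down.copy()
                    down[:, miss, :] = 1.0
            else:
                down = np.einsum("cij,cpj->cpi", P_all[ci], partial[ci])
            acc = down if acc is None else acc * down
        mx = acc.max(axis=2)
        safe = np.where(mx > 0, mx, 1.0)
        partial[ni] = acc / safe[:, :, None]
        with np.errstate(divide="ignore"):
            logscale += np.where(mx > 0, np.log(safe), NEG_INF)
    site_lik = partial[ctx.root_index] @ freqs  # (ncat, n_pat)
    with np.errstate(divide="ignore"):
        log_cat = np.log(site_lik) + logscale
    m = log_cat.max(axis=0)
    mixed = np.where(
        np.isfinite(m),
        m + np.log(np.mean(np.exp(log_cat - m[None, :]), axis=0)),
        NEG_INF,
    )
    return mixed


def _prune_block(tree: TimeTree, taxa: list[str], patterns: np.ndarray,
                 k: int, trans_fn, cat_rates: np.ndarray,
                 freqs: np.ndarray, eff_lengths, multiplier: float):
    """Uncompiled pruning path (used by the public functions)."""
    ctx = _TreeContext(tree, eff_lengths)
    t = np.outer(ctx.lengths * multiplier, cat_rates)  # (n_nodes, ncat)
    P_all = trans_fn(t)
    tip_rows = {t_: i for i, t_ in enumerate(taxa)}
    return _prune_exec(ctx, tip_rows, patterns, k, P_all, freqs)


# ---------------------------------------------------------------------------
# compiled data blocks (pattern compression + cached eigendecompositions)
# ---------------------------------------------------------------------------

@dataclass
class CompiledBlock:
    """One pattern-compressed character block ready for repeated pruning.

    For morphology (``kind='mk'``) the last ``k`` pattern columns are the
    constant patterns used by the Mkv ascertainment correction.  For DNA
    (``kind='gtr'``) the eigendecomposition and the invariant-class pattern
    log-likelihoods are precomputed (frequencies are fixed during MCMC).
    """

    kind: str
    k: int
    taxa: list[str]
    patterns: np.ndarray
    counts: np.ndarray
    n_chars: int
    freqs: np.ndarray
    gtr: "_GTRTransition | None" = None
    inv_log: np.ndarray | None = None

    @property
    def tip_rows(self) -> dict[str, int]:
        if not hasattr(self, "_tip_rows"):
            object.__setattr__(self, "_tip_rows",
                               {t: i for i, t in enumerate(self.taxa)})
        return self._tip_rows


def compile_morph(data: MorphMatrix) -> list[CompiledBlock]:
    """Group characters by state count and compress to unique patterns,
    appending the k constant patterns for the Mkv correction."""
    blocks = []
    for kval in np.unique(data.k):
        k = int(kval)
        cols = np.where(data.k == kval)[0]
        pats, counts = np.unique(data.states[:, cols], axis=1,
                                 return_counts=True)
        const = np.tile(np.arange(k, dtype=np.int8), (data.n_taxa, 1))
        pats = np.concatenate([pats, const], axis=1)
        blocks.append(CompiledBlock(
            kind="mk", k=k, taxa=list(data.taxa), patterns=pats,
            counts=counts, n_chars=int(cols.size),
            freqs=np.full(k, 1.0 / k)))
    return blocks


def compile_mol(data: MolAlignment,
                gtr_params: Sequence[GTRPartitionParams]) -> list[CompiledBlock]:
    """Compress each partition to unique site patterns and precompute the
    transition-matrix eigendecomposition and invariant-class terms."""
    blocks = []
    for pi in range(data.n_partitions):
        cols = np.where(data.partition_map == pi)[0]
        if cols.size == 0:
            continue
        pats, counts = np.unique(data.sites[:, cols], axis=1,
                                 return_counts=True)
        params = gtr_params[pi]
        blocks.append(CompiledBlock(
            kind="gtr", k=4, taxa=list(data.taxa), patterns=pats,
            counts=counts, n_chars=int(cols.size), freqs=params.freqs,
            gtr=_GTRTransition(params),
            inv_log=_invariant_class_loglik(pats, params.freqs)))
    return blocks


def compiled_morph_loglik(tree: TimeTree, eff_lengths,
                          blocks: Sequence[CompiledBlock], alpha: float,
                          ncat: int, multiplier: float = 1.0,
                          variable_only: bool = True) -> float:
    """Mk log-likelihood over compiled k-group blocks, with the Mkv
    ascertainment correction applied per group when ``variable_only``."""
    ctx = _TreeContext(tree, eff_lengths)
    cat = discretize_gamma(alpha, ncat)
    t = np.outer(ctx.lengths * multiplier, cat)
    total = 0.0
    for block in blocks:
        P_all = mk_transition_probs(block.k, t)
        logL = _prune_exec(ctx, block.tip_rows, block.patterns, block.k,
                           P_all, block.freqs)
        data_log, const_log = logL[: -block.k], logL[-block.k:]
        total += float(data_log @ block.counts)
        if variable_only:
            p_const = float(np.exp(const_log).sum())
            if p_const >= 1.0 - 1e-14:
                return NEG_INF
            total -= block.n_chars * math.log1p(-p_const)
    return total


def compiled_mol_loglik(tree: TimeTree, eff_lengths,
                        blocks: Sequence[CompiledBlock],
                        gtr_params: Sequence[GTRPartitionParams],
                        multipliers: np.ndarray | None = None) -> float:
    """GTR + Gamma + I log-likelihood over compiled partition blocks."""
    ctx = _TreeContext(tree, eff_lengths)
    if multipliers is None:
        multipliers = np.ones(len(blocks))
    total = 0.0
    for block, params, mult in zip(blocks, gtr_params, multipliers):
        cat = discretize_gamma(params.alpha, params.ncat)
        t = np.outer(ctx.lengths * float(mult), cat)
        P_all = block.gtr.probs(t)
        logL = _prune_exec(ctx, block.tip_rows, block.patterns, 4, P_all,
                           block.freqs)
        if params.pinv > 0:
            logL = np.logaddexp(np.log1p(-params.pinv) + logL,
                                np.log(params.pinv) + block.inv_log)
        total += float(logL @ block.counts)
    return total


def _morph_pattern_groups(data: MorphMatrix):
    """Group characters by state count; compress to unique patterns."""
    groups = {}
    for kval in np.unique(data.k):
        cols = np.where(data.k == kval)[0]
        block = data.states[:, cols]
        pats, counts = np.unique(block, axis=1, return_counts=True)
        groups[int(kval)] = (pats, counts)
    return groups


def pruning_loglik(tree: TimeTree, eff_lengths, data,
                   model: SiteModelParams,
                   rates: PartitionRates | None = None) -> float:
    """Felsenstein-pruning log-likelihood of a character matrix.

    For a :class:`MorphMatrix`, characters are grouped by state count k and
    scored under Mk + discrete gamma (the Mkv correction is a separate term;
    see :func:`mkv_correction`).  For a :class:`MolAlignment`, each partition
    is scored under its GTR + Gamma + I model with its rate multiplier from
    ``rates`` (morphology is multiplier index 0 by convention when rates span
    both data types; pass the relevant :class:`PartitionRates` slice).
    """
    if isinstance(data, MorphMatrix):
        mult = 1.0 if rates is None else float(rates.multipliers[0])
        cat = discretize_gamma(model.morph_alpha, model.morph_ncat)
        total = 0.0
        for k, (pats, counts) in _morph_pattern_groups(data).items():
            freqs = np.full(k, 1.0 / k)
            logL = _prune_block(tree, data.taxa, pats, k,
                                lambda t, k=k: mk_transition_probs(k, t),
                                cat, freqs, eff_lengths, mult)
            total += float(logL @ counts)
        return total

    if isinstance(data, MolAlignment):
        total = 0.0
        for pi in range(data.n_partitions):
            params = model.gtr[pi]
            mult = 1.0 if rates is None else float(rates.multipliers[pi])
            cols = np.where(data.partition_map == pi)[0]
            if cols.size == 0:
                continue
            block = data.sites[:, cols]
            pats, counts = np.unique(block, axis=1, return_counts=True)
            cat = discretize_gamma(params.alpha, params.ncat)
            gtr = _GTRTransition(params)
            logL = _prune_block(tree, data.taxa, pats, 4, gtr.probs,
                                cat, params.freqs, eff_lengths, mult)
            if params.pinv > 0:
                log_inv = _invariant_class_loglik(pats, params.freqs)
                a = np.log1p(-params.pinv) + logL
                b = np.log(params.pinv) + log_inv
                logL = np.logaddexp(a, b)
            total += float(logL @ counts)
        return total

    raise TypeError(f"unsupported data type {type(data).__name__}")


def _invariant_class_loglik(pats: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Log-likelihood of each pattern under the invariable-sites class."""
    n_pat = pats.shape[1]
    out = np.full(n_pat, NEG_INF)
    for p in range(n_pat):
        col = pats[:, p]
        obs = col[col >= 0]
        if obs.size == 0:
            out[p] = 0.0
        elif np.all(obs == obs[0]):
            out[p] = math.log(freqs[obs[0]])
    return out


def mkv_correction(tree: TimeTree, eff_lengths, model: SiteModelParams,
                   k: int, n_chars: int,
                   rate_multiplier: float = 1.0) -> float:
    """Ascertainment ("coding bias") correction for variable-only matrices.

    Returns -n_chars * log(1 - P(constant)) for the k-state Mk model on this
    tree, where P(constant) = sum_j P(all tips observed in state j), with
    the gamma mixture applied inside the sum.  Subtracting nothing, the
    corrected likelihood is pruning + this term (the term itself is
    positive).  All-zero effective lengths make variability impossible and
    yield -inf.
    """
    cat = discretize_gamma(model.morph_alpha, model.morph_ncat)
    taxa = [t.label for t in tree.tips()]
    n_taxa = len(taxa)
    freqs = np.full(k, 1.0 / k)
    # constant patterns: one per state
    pats = np.tile(np.arange(k, dtype=np.int8), (n_taxa, 1))
    logL = _prune_block(tree, taxa, pats, k,
                        lambda t: mk_transition_probs(k, t),
                        cat, freqs, eff_lengths, rate_multiplier)
    p_const = float(np.exp(logL).sum())
    if p_const >= 1.0 - 1e-14:
        logger.warning("Mkv correction degenerate: P(constant) ~ 1 "
                       "(all effective lengths ~ 0)")
        return NEG_INF
    return -n_chars * math.log1p(-p_const)


def morph_log_likelihood(tree: TimeTree, eff_lengths, data: MorphMatrix,
                         model: SiteModelParams,
                         rates: PartitionRates | None = None) -> float:
    """Mk log-likelihood with the Mkv correction applied per k-group when
    the matrix is variable-only."""
    total = pruning_loglik(tree, eff_lengths, data, model, rates)
    if data.variable_only:
        mult = 1.0 if rates is None else float(rates.multipliers[0])
        for kval in np.unique(data.k):
            n_k = int((data.k == kval).sum())
            corr = mkv_correction(tree, eff_lengths, model, int(kval), n_k,
                                  mult)
            if corr == NEG_INF:
                return NEG_INF
            total += corr
    return total


# ---------------------------------------------------------------------------
# partition-rate prior
# ---------------------------------------------------------------------------

def partition_rate_log_prior(rates: PartitionRates,
                             concentration: float | np.ndarray = 1.0) -> float:
    """Log density of the weighted (scaled) Dirichlet prior on the rate
    multipliers: x_i = w_i * m_i ~ Dirichlet(concentration)."""
    m, w = rates.multipliers, rates.weights
    if abs(float(w @ m) - 1.0) > 1e-9:
        raise ValueError("multipliers violate the weighted-mean-1 constraint")
    if m.size == 1:
        return 0.0
    alpha = np.broadcast_to(np.asarray(concentration, dtype=float),
                            m.shape).copy()
    x = w * m
    return float(stats.dirichlet.logpdf(x / x.sum(), alpha)
                 + np.sum(np.log(w[:-1])))


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def filter_characters(data: MorphMatrix, drop_taxa: Sequence[str] = (),
                      remove_constant: bool = True) -> MorphMatrix:
    """Drop listed taxa, then remove characters constant (or missing-only)
    across the remaining taxa.  Removal counts are logged."""
    keep = [t for t in data.taxa if t not in set(drop_taxa)]
    n_dropped_taxa = data.n_taxa - len(keep)
    idx = [data.taxa.index(t) for t in keep]
    states = data.states[idx]
    keep_cols = []
    for j in range(data.n_chars):
        col = states[:, j]
        obs = col[col >= 0]
        constant = obs.size == 0 or bool(np.all(obs == obs[0]))
        if not (remove_constant and constant):
            keep_cols.append(j)
    n_removed = data.n_chars - len(keep_cols)
    logger.info("filter_characters: dropped %d taxa, removed %d constant "
                "or missing-only characters", n_dropped_taxa, n_removed)
    return MorphMatrix(keep, states[:, keep_cols], data.k[keep_cols],
                       variable_only=data.variable_only or remove_constant)
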