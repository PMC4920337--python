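"""Metropolis-coupled MCMC over dated trees and model parameters.

The sampler targets the joint posterior of (tree topology, node ages, fossil
attachments, diversification parameters, clock parameters, branch effects,
site-model parameters, partition rates) under the tree priors of
:mod:`tedkit.tree_priors` and the likelihoods of :mod:`tedkit.char_models`.
A ``prior_only`` switch forces the character log-likelihood to 0, which
yields the induced prior on node ages: fossil ages, topology constraints and
hyperpriors still act.

Design notes
------------
* The log posterior is held as named components with dirty-flag recomputation
  so parameter moves only re-evaluate what they touch; a periodic full
  recomputation asserts cache consistency to 1e-6.
* Tree moves (node-age slide, root slide, narrow exchange, fossil-subtree
  SPR) mutate the tree in place and return undo closures, so branch effects
  keyed by node identity survive topology changes.
* Chains are tempered as beta_i = 1/(1 + delta * i); only the cold chain is
  recorded.  All randomness flows from one seeded generator per run, with
  the run index perturbing the seed deterministically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from tedkit.timetree import (
    TimeTree, Node, CladeConstraint, FossilTable,
    ghost_excess, youngest_split_age, satisfies_constraint,
)
from tedkit import tree_priors as tp
from tedkit.tree_priors import (
    FBDParams, SkylineFBDParams, RootAgePrior, HyperPriors,
    HYPERPRIOR_PRESETS,
)
from tedkit import char_models as cm
from tedkit.char_models import (
    MorphMatrix, MolAlignment, SiteModelParams, GTRPartitionParams,
    PartitionRates,
)
from tedkit.clocks import (
    ClockParams, BranchEffects, effective_lengths_strict,
    igr_log_prior, sample_igr_lengths, clock_hyper_log_prior,
)

__all__ = [
    "ModelSpec",
    "McmcConfig",
    "ChainState",
    "McmcRun",
    "run_mc3",
    "sample_induced_prior",
    "propose_fossil_attachment",
    "convergence_diagnostics",
]

NEG_INF = float("-inf")


# ---------------------------------------------------------------------------
# specification
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Complete model specification for one analysis."""

    tree_prior: Literal["uniform", "bd", "fbd", "skyline"] = "fbd"
    hyper: HyperPriors = field(
        default_factory=lambda: HYPERPRIOR_PRESETS["vague"])
    root_prior: RootAgePrior = field(default_factory=RootAgePrior)
    sampling_mode: Literal["complete", "random", "diversified"] = "diversified"
    rho: float = 1.0
    skyline_boundaries: tuple[float, ...] = (70.0, 55.0)
    clock_mode: Literal["strict", "igr"] = "igr"
    clock_linkage: Literal["linked", "unlinked"] = "linked"
    constraints: tuple[CladeConstraint, ...] = ()
    fix_root_age: float | None = None
    alpha_prior_rate: float = 1.0  # Exp prior on gamma shapes

    @classmethod
    def preset(cls, name: str, **kwargs) -> "ModelSpec":
        return cls(hyper=HYPERPRIOR_PRESETS[name], **kwargs)


@dataclass
class McmcConfig:
    """Run-length and chain-coupling settings."""

    n_generations: int = 100_000
    n_runs: int = 4
    n_chains: int = 4
    heat_delta: float = 0.1
    sample_every: int = 500
    burnin_frac: float = 0.25
    seed: int = 0
    prior_only: bool = False
    fixed_topology: bool = False
    use_morph: bool = True
    use_mol: bool = True
    swap_every: int = 10
    check_every: int = 1000

    def __post_init__(self):
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if not (0 <= self.burnin_frac < 1):
            raise ValueError("burnin_frac must be in [0, 1)")


# ---------------------------------------------------------------------------
# chain state
# ---------------------------------------------------------------------------

_COMPONENTS = (
    "tree_prior", "hyper", "constraints",
    "clock_prior", "igr_prior", "partrate_prior", "sitemodel_prior",
    "lik_morph", "lik_mol",
)


class ChainState:
    """Mutable state of one chain plus cached log-posterior components."""

    def __init__(self, spec: ModelSpec, data, config: McmcConfig,
                 tree: TimeTree, rng: np.random.Generator):
        self.spec = spec
        self.config = config
        self.tree = tree
        self.rng = rng
        self.morph: MorphMatrix | None = data.morph if config.use_morph else None
        self.mol: MolAlignment | None = data.mol if config.use_mol else None

        n_int = len(spec.skyline_boundaries) + 1 if spec.tree_prior == "skyline" else 1
        d0 = spec.hyper.d_fixed if spec.hyper.d_fixed is not None else 0.1
        self.drf = [[d0, 0.5, 0.5 if self._uses_psi() else 0.0]
                    for _ in range(n_int)]

        self.clock_rate = {"morph": math.exp(-6.0), "mol": math.exp(-6.0)}
        self.clock_nu = {"morph": 0.1, "mol": 0.1}
        self.effects: dict[str, BranchEffects | None] = {"morph": None, "mol": None}
        if spec.clock_mode == "igr":
            for key in self._clock_keys():
                self.effects[key] = effective_lengths_strict(
                    tree, self.clock_rate[key])

        # site model: sampled shapes/pinv, empirical frequencies
        gtr = []
        if self.mol is not None:
            for pi in range(self.mol.n_partitions):
                cols = self.mol.sites[:, self.mol.partition_map == pi]
                obs = cols[cols >= 0]
                freqs = np.bincount(obs, minlength=4).astype(float) + 1.0
                gtr.append(GTRPartitionParams(freqs=freqs / freqs.sum(),
                                              alpha=1.0, pinv=0.1))
        self.site_model = SiteModelParams(morph_alpha=1.0, gtr=gtr)
        self._morph_blocks = (cm.compile_morph(self.morph)
                              if self.morph is not None
                              and not config.prior_only else None)
        self._mol_blocks = (cm.compile_mol(self.mol, gtr)
                            if self.mol is not None
                            and not config.prior_only else None)

        counts = []
        if self.morph is not None:
            counts.append(self.morph.n_chars)
        if self.mol is not None:
            counts.extend(int((self.mol.partition_map == pi).sum())
                          for pi in range(self.mol.n_partitions))
        self.part_rates = PartitionRates.flat(counts) if counts else None

        self.components: dict[str, float] = {}
        self.recompute(set(_COMPONENTS))

    # -- clock plumbing ----------------------------------------------------
    def _clock_keys(self) -> list[str]:
        if self.spec.clock_linkage == "linked":
            return ["mol"]  # one shared clock, stored under "mol"
        keys = []
        if self.morph is not None:
            keys.append("morph")
        if self.mol is not None:
            keys.append("mol")
        return keys or ["mol"]

    def _clock_key_for(self, block: str) -> str:
        return "mol" if self.spec.clock_linkage == "linked" else block

    def _uses_psi(self) -> bool:
        return self.spec.tree_prior in ("fbd", "skyline")

    def effective_lengths(self, block: str):
        """Branch length source for a data block ('morph' | 'mol')."""
        key = self._clock_key_for(block)
        if self.spec.clock_mode == "strict" or self.effects[key] is None:
            c = self.clock_rate[key]
            return {id(n): c * (n.parent.age - n.age)
                    for n in self.tree.preorder() if n.parent is not None}
        return self.effects[key]

    # -- components --------------------------------------------------------
    def _fbd_params(self, i: int = 0) -> FBDParams:
        d, r, f = self.drf[i]
        return FBDParams(d, r, f, rho=self.spec.rho,
                         sampling_mode=self.spec.sampling_mode)

    def _component_tree_prior(self) -> float:
        spec = self.spec
        if spec.fix_root_age is not None:
            root_prior = _DegenerateRootPrior(spec.fix_root_age)
        else:
            root_prior = spec.root_prior
        if spec.tree_prior == "uniform":
            return tp.uniform_tree_log_density(self.tree, root_prior)
        if spec.tree_prior == "bd":
            return tp.bd_log_density(self.tree, self._fbd_params(), root_prior)
        if spec.tree_prior == "fbd":
            return tp.fbd_log_density(self.tree, self._fbd_params(), root_prior)
        params = SkylineFBDParams(
            spec.skyline_boundaries,
            tuple(self._fbd_params(i) for i in range(len(self.drf))))
        return tp.skyline_fbd_log_density(self.tree, params, root_prior)

    def _component_hyper(self) -> float:
        if self.spec.tree_prior == "uniform":
            return 0.0
        total = 0.0
        for i in range(len(self.drf)):
            total += tp.hyperprior_log_density(self._fbd_params(i),
                                               self.spec.hyper)
            if total == NEG_INF:
                return NEG_INF
        return total

    def _component_constraints(self) -> float:
        for c in self.spec.constraints:
            if not satisfies_constraint(self.tree, c):
                return NEG_INF
        return 0.0

    def _component_clock_prior(self) -> float:
        total = 0.0
        for key in self._clock_keys():
            nu = self.clock_nu[key] if self.spec.clock_mode == "igr" else 0.0
            total += clock_hyper_log_prior(self.clock_rate[key], nu)
        return total

    def _component_igr_prior(self) -> float:
        if self.spec.clock_mode != "igr":
            return 0.0
        total = 0.0
        for key in self._clock_keys():
            total += igr_log_prior(self.effects[key], self.tree,
                                   self.clock_rate[key], self.clock_nu[key])
            if total == NEG_INF:
                return NEG_INF
        return total

    def _component_partrate_prior(self) -> float:
        if self.part_rates is None or self.part_rates.multipliers.size == 1:
            return 0.0
        return cm.partition_rate_log_prior(self.part_rates)

    def _component_sitemodel_prior(self) -> float:
        rate = self.spec.alpha_prior_rate
        total = math.log(rate) - rate * self.site_model.morph_alpha
        for g in self.site_model.gtr:
            total += math.log(rate) - rate * g.alpha  # Exp prior on shape
            # pinv ~ Uniform(0,1): contributes 0
        return total

    def _component_lik_morph(self) -> float:
        if self.morph is None or self.config.prior_only:
            return 0.0
        mult = (float(self.part_rates.multipliers[0])
                if self.part_rates is not None and self.mol is not None else 1.0)
        eff = self.effective_lengths("morph")
        return cm.compiled_morph_loglik(
            self.tree, eff, self._morph_blocks,
            self.site_model.morph_alpha, self.site_model.morph_ncat,
            multiplier=mult, variable_only=self.morph.variable_only)

    def _component_lik_mol(self) -> float:
        if self.mol is None or self.config.prior_only:
            return 0.0
        offset = 1 if self.morph is not None else 0
        mults = (self.part_rates.multipliers[offset:]
                 if self.part_rates is not None
                 else np.ones(self.mol.n_partitions))
        eff = self.effective_lengths("mol")
        return cm.compiled_mol_loglik(self.tree, eff, self._mol_blocks,
                                      self.site_model.gtr, mults)

    def recompute(self, dirty: set[str]) -> None:
        for name in dirty:
            self.components[name] = getattr(self, f"_component_{name}")()

    def log_posterior(self) -> float:
        total = 0.0
        for v in self.components.values():
            if v == NEG_INF:
                return NEG_INF
            total += v
        return total

    def log_likelihood(self) -> float:
        return self.components["lik_morph"] + self.components["lik_mol"]

    def full_recompute_check(self, tol: float = 1e-6) -> None:
        cached = dict(self.components)
        self.recompute(set(_COMPONENTS))
        for name, old in cached.items():
            new = self.components[name]
            if old == NEG_INF and new == NEG_INF:
                continue
            if abs(old - new) > tol * max(1.0, abs(new)):
                raise RuntimeError(
                    f"cache drift in {name}: {old} vs {new}")


class _DegenerateRootPrior:
    """Root prior for a fixed root age: accepts only (a neighbourhood of)
    the fixed value; used when the root age is clamped."""

    def __init__(self, age: float):
        self.age = age

    def log_density(self, age: float, oldest_fossil_age: float = 0.0) -> float:
        return 0.0 if abs(age - self.age) < 1e-9 else NEG_INF

    def effective_minimum(self, oldest_fossil_age: float = 0.0) -> float:
        return self.age


def _unconstrained_rates(mults: np.ndarray) -> PartitionRates:
    """PartitionRates carrier that skips the weighted-mean-1 check (the
    constraint is enforced on the full vector spanning both data types)."""
    obj = PartitionRates.__new__(PartitionRates)
    obj.multipliers = np.asarray(mults, dtype=float)
    obj.weights = np.full(obj.multipliers.size, 1.0 / obj.multipliers.size)
    return obj


# ---------------------------------------------------------------------------
# moves
# ---------------------------------------------------------------------------

TREE_DIRTY = {"tree_prior", "constraints", "igr_prior", "lik_morph", "lik_mol"}


def _scale_adjacent_effects(state: ChainState, node: Node, old_age: float):
    """After moving ``node``'s age, rescale the effects of its adjacent
    branches so branch *rates* are preserved; returns (log Jacobian, undo).

    Without this, the IGR prior at small nu pins every age to its branch
    effects and age moves crawl."""
    if state.spec.clock_mode != "igr":
        return 0.0, lambda: None
    log_j = 0.0
    saved: list[tuple[dict, int, float]] = []
    adjacent = list(node.children)
    if node.parent is not None:
        adjacent.append(node)

    def duration(n: Node, age_of_moved: float) -> float:
        if n is node:
            return n.parent.age - age_of_moved
        return age_of_moved - n.age

    for key in state._clock_keys():
        eff = state.effects[key]
        if eff is None:
            continue
        for n in adjacent:
            t_old = duration(n, old_age)
            t_new = duration(n, node.age)
            if t_old <= 0 or t_new <= 0:
                continue
            v = eff.lengths[id(n)]
            saved.append((eff.lengths, id(n), v))
            eff.lengths[id(n)] = v * t_new / t_old
            log_j += math.log(t_new / t_old)

    def undo():
        for lengths, nid, v in saved:
            lengths[nid] = v

    return log_j, undo


def _move_node_age(state: ChainState) -> tuple[float, set[str], Callable] | None:
    rng = state.rng
    nodes = [n for n in state.tree.internal_nodes() if n is not state.tree.root]
    if not nodes:
        return None
    node = nodes[rng.integers(len(nodes))]
    lo = max(c.age for c in node.children)
    hi = node.parent.age
    if hi <= lo:
        return None
    old = node.age
    node.age = float(rng.uniform(lo, hi))
    log_j, undo_eff = 0.0, lambda: None
    if rng.random() < 0.5:  # rate-preserving variant
        log_j, undo_eff = _scale_adjacent_effects(state, node, old)

    def undo():
        undo_eff()
        node.age = old

    return log_j, TREE_DIRTY, undo


def _move_root_age(state: ChainState) -> tuple[float, set[str], Callable] | None:
    if state.spec.fix_root_age is not None:
        return None
    rng = state.rng
    root = state.tree.root
    old = root.age
    base = max(c.age for c in root.children)
    fossil_ages = [t.age for t in state.tree.fossil_tips()]
    lo = max(base, state.spec.root_prior.effective_minimum(
        max(fossil_ages) if fossil_ages else 0.0))
    if rng.random() < 0.5:
        # independence draw from the root prior truncated to (lo, inf);
        # the exponential tail gives Hastings exp(rate * (new - old))
        rate = state.spec.root_prior.rate
        new = lo + float(rng.exponential(1.0 / rate))
        root.age = new
        log_h = rate * (new - old)
    else:
        # multiplicative move on the offset above the older child, which is
        # symmetric in log space (a state-dependent slide window would
        # violate detailed balance)
        u = float(rng.uniform(-0.5, 0.5))
        root.age = base + (old - base) * math.exp(u)
        log_h = u
    log_j, undo_eff = 0.0, lambda: None
    if rng.random() < 0.5:
        log_j, undo_eff = _scale_adjacent_effects(state, root, old)

    def undo():
        undo_eff()
        root.age = old

    return log_h + log_j, TREE_DIRTY, undo


def _move_tree_scale(state: ChainState) -> tuple[float, set[str], Callable] | None:
    """Ghost-lineage stretch: scale every internal age relative to the age
    of its oldest sampled descendant (its "anchor"), tips fixed.

    age' = anchor + xi * (age - anchor) dilates or compresses exactly the
    lineage durations unobserved in the fossil record, the direction deep
    root attraction lives in, while fossil-age constraints stay satisfied by
    construction.  Under the strict clock the clock rate is divided by xi
    (rate-time compensation); under the IGR clock the branch effects are
    rescaled by each branch's duration ratio so branch rates are preserved.
    """
    if state.spec.fix_root_age is not None:
        return None
    rng = state.rng
    xi = math.exp(float(rng.uniform(-0.35, 0.35)))
    tree = state.tree
    anchor: dict[int, float] = {}
    for n in tree.postorder():
        if n.is_tip:
            anchor[id(n)] = n.age
        else:
            anchor[id(n)] = max(anchor[id(c)] for c in n.children)
    internals = tree.internal_nodes()
    old_ages = [n.age for n in internals]
    old_durations = {id(n): n.parent.age - n.age
                     for n in tree.preorder() if n.parent is not None}
    for n in internals:
        n.age = anchor[id(n)] + xi * (n.age - anchor[id(n)])
    # upscaling can invert short branches whose endpoints have different
    # anchors; reject those proposals
    for n in tree.preorder():
        if n.parent is not None and n.parent.age <= n.age:
            for m, a in zip(internals, old_ages):
                m.age = a
            return None
    log_h = len(internals) * math.log(xi)

    saved_eff: list[tuple[dict, int, float]] = []
    keys = state._clock_keys()
    old_rates = {k: state.clock_rate[k] for k in keys}
    if state.spec.clock_mode == "strict":
        for k in keys:
            state.clock_rate[k] = old_rates[k] / xi
        log_h -= len(keys) * math.log(xi)
    else:
        for key in keys:
            eff = state.effects[key]
            if eff is None:
                continue
            for n in tree.preorder():
                if n.parent is None:
                    continue
                t_new = n.parent.age - n.age
                t_old = old_durations[id(n)]
                v = eff.lengths[id(n)]
                saved_eff.append((eff.lengths, id(n), v))
                eff.lengths[id(n)] = v * t_new / t_old
                log_h += math.log(t_new / t_old)

    def undo():
        for lengths, nid, v in saved_eff:
            lengths[nid] = v
        for k in keys:
            state.clock_rate[k] = old_rates[k]
        for m, a in zip(internals, old_ages):
            m.age = a

    return log_h, TREE_DIRTY | {"clock_prior"}, undo


def _move_clock_scale(state: ChainState) -> tuple[float, set[str], Callable] | None:
    """Jointly scale the clock rate and all branch effects of one clock.

    Under the IGR prior with small nu the conditional of c given the
    effects is razor thin; this move walks along the (c, v) ridge that the
    data, not the prior, constrain."""
    if state.spec.clock_mode != "igr":
        return None
    rng = state.rng
    keys = state._clock_keys()
    key = keys[rng.integers(len(keys))]
    eff = state.effects[key]
    if eff is None:
        return None
    xi = math.exp(float(rng.uniform(-0.08, 0.08)))
    old_c = state.clock_rate[key]
    old_lengths = dict(eff.lengths)
    state.clock_rate[key] = old_c * xi
    for nid in eff.lengths:
        eff.lengths[nid] *= xi

    def undo():
        state.clock_rate[key] = old_c
        eff.lengths = old_lengths

    n_branch = sum(1 for n in state.tree.preorder() if n.parent is not None)
    dirty = {"clock_prior", "igr_prior"}
    if state.spec.clock_linkage == "linked":
        dirty |= {"lik_morph", "lik_mol"}
    else:
        dirty |= {"lik_morph" if key == "morph" else "lik_mol"}
    return (1 + n_branch) * math.log(xi), dirty, undo


def _move_narrow_exchange(state: ChainState) -> tuple[float, set[str], Callable] | None:
    if state.config.fixed_topology:
        return None
    rng = state.rng
    cands = [n for n in state.tree.internal_nodes() if n is not state.tree.root]
    if not cands:
        return None
    v = cands[rng.integers(len(cands))]
    g = v.parent
    s = [c for c in g.children if c is not v][0]
    w = v.children[rng.integers(2)]
    if v.age <= s.age:
        return None  # s cannot move under v
    iv = v.children.index(w)
    ig = g.children.index(s)
    v.children[iv] = s
    s.parent = v
    g.children[ig] = w
    w.parent = g

    def undo():
        v.children[iv] = w
        w.parent = v
        g.children[ig] = s
        s.parent = g

    return 0.0, TREE_DIRTY, undo


def _fossil_only_subtrees(tree: TimeTree) -> list[Node]:
    """Roots of maximal all-fossil subtrees (possibly single fossil tips)."""
    all_fossil: dict[int, bool] = {}
    for n in tree.postorder():
        if n.is_tip:
            all_fossil[id(n)] = n.is_fossil
        else:
            all_fossil[id(n)] = all(all_fossil[id(c)] for c in n.children)
    out = []

    def walk(n: Node):
        if all_fossil[id(n)] and n.parent is not None:
            out.append(n)
            return
        for c in n.children:
            walk(c)

    walk(tree.root)
    return out


def _attachment_slots(tree: TimeTree, y: float, allow_root: bool):
    """Feasible attachment slots for a subtree whose root has age y."""
    slots = []
    for n in tree.preorder():
        if n.parent is None:
            continue
        lo = max(y, n.age)
        if n.parent.age > lo:
            slots.append(("branch", n, lo, n.parent.age))
    if allow_root:
        slots.append(("root", tree.root, max(y, tree.root.age), math.inf))
    return slots


def propose_fossil_attachment(state: ChainState,
                              rng: np.random.Generator | None = None
                              ) -> tuple[float, set[str], Callable] | None:
    """Detach a fossil-only subtree and reattach it to a uniformly chosen
    feasible slot at a uniformly chosen feasible age; returns (log Hastings
    ratio, dirty components, undo).  The above-root slot uses a shifted
    exponential age proposal with the root prior's rate."""
    rng = rng or state.rng
    tree = state.tree
    if state.config.fixed_topology:
        return None
    movers = _fossil_only_subtrees(tree)
    if not movers:
        return None
    x = movers[rng.integers(len(movers))]
    q = x.parent
    allow_root = state.spec.fix_root_age is None
    if q is tree.root and not allow_root:
        return None
    rate = state.spec.root_prior.rate
    old_durations = {id(n): n.parent.age - n.age
                     for n in tree.preorder() if n.parent is not None}

    # ---- detach ----
    ix = q.children.index(x)
    s = [c for c in q.children if c is not x][0]
    g = q.parent
    old_root = tree.root
    old_q_age = q.age
    if g is None:  # q was the root: s becomes the root
        s.parent = None
        tree.root = s
    else:
        ig = g.children.index(q)
        g.children[ig] = s
        s.parent = g

    # reverse-slot geometry, measured on the detached tree
    slots = _attachment_slots(tree, x.age, allow_root)
    n_slots = len(slots)
    if n_slots == 0:
        _restore_attach(tree, x, q, s, g, old_root, old_q_age)
        return None
    # log density of the reverse proposal (re-creating the old attachment)
    if g is None:
        log_rev = -math.log(n_slots) + (math.log(rate)
                                        - rate * (old_q_age - max(x.age, tree.root.age)))
    else:
        lo = max(x.age, s.age)
        log_rev = -math.log(n_slots) - math.log(g.age - lo)

    # ---- choose new slot ----
    kind, target, lo, hi = slots[rng.integers(n_slots)]
    if kind == "branch":
        a = float(rng.uniform(lo, hi))
        log_fwd = -math.log(n_slots) - math.log(hi - lo)
        p = target.parent
        it = p.children.index(target)
        q.age = a
        q.children = [x, target]
        x.parent = q
        target.parent = q
        q.parent = p
        p.children[it] = q
        new_root_flag = False
    else:
        a = lo + float(rng.exponential(1.0 / rate))
        log_fwd = -math.log(n_slots) + (math.log(rate) - rate * (a - lo))
        old_top = tree.root
        q.age = a
        q.children = [x, old_top]
        x.parent = q
        old_top.parent = q
        q.parent = None
        tree.root = q
        new_root_flag = True

    # branch-set changes (moves through the root slot create/destroy the
    # branch above the displaced root): under the IGR clock the per-branch
    # effects are parameters, so newly created branches draw their effect
    # from the prior and the Hastings ratio absorbs both proposal densities
    log_effects = 0.0
    if state.spec.clock_mode == "igr":
        new_durations = {id(n): n.parent.age - n.age
                         for n in tree.preorder() if n.parent is not None}
        created = set(new_durations) - set(old_durations)
        destroyed = set(old_durations) - set(new_durations)
        for key in state._clock_keys():
            eff = state.effects[key]
            if eff is None:
                continue
            c_key = state.clock_rate[key]
            nu = state.clock_nu[key]
            for nid in created:
                t_b = new_durations[nid]
                v = float(rng.gamma(shape=t_b / nu, scale=c_key * nu))
                eff.lengths[nid] = v
                log_effects -= _gamma_logpdf(v, t_b / nu, c_key * nu)
            for nid in destroyed:
                v = eff.lengths.get(nid)
                if v is not None:
                    log_effects += _gamma_logpdf(v, old_durations[nid] / nu,
                                                 c_key * nu)

    def undo():
        # detach from the new position
        if new_root_flag:
            top = [c for c in q.children if c is not x][0]
            top.parent = None
            tree.root = top
        else:
            p2 = q.parent
            other = [c for c in q.children if c is not x][0]
            i2 = p2.children.index(q)
            p2.children[i2] = other
            other.parent = p2
        _restore_attach(tree, x, q, s, g, old_root, old_q_age, ix)

    return log_rev - log_fwd + log_effects, TREE_DIRTY, undo


def _restore_attach(tree, x, q, s, g, old_root, old_q_age, ix=0):
    q.age = old_q_age
    q.children = [x, s] if ix == 0 else [s, x]
    x.parent = q
    s.parent = q
    if g is None:
        q.parent = None
        tree.root = q
    else:
        ig = g.children.index(s)
        g.children[ig] = q
        q.parent = g
        tree.root = old_root


def _move_drf(state: ChainState) -> tuple[float, set[str], Callable] | None:
    if state.spec.tree_prior == "uniform":
        return None
    rng = state.rng
    h = state.spec.hyper
    i = int(rng.integers(len(state.drf)))
    which = int(rng.integers(3))
    old = state.drf[i][which]
    if which == 0 and state.spec.hyper.d_fixed is not None:
        return None
    if which == 2 and not state._uses_psi():
        return None
    if rng.random() < 0.5:
        # independence draw from the hyperprior; the prior terms cancel in
        # the acceptance ratio, so this mixes well when data are weak
        if which == 0:
            new = float(rng.exponential(1.0 / h.d_prior[1]))
            log_h = (-h.d_prior[1] * old) - (-h.d_prior[1] * new)
        else:
            a, b = h.r_prior if which == 1 else h.f_prior
            new = float(np.clip(rng.beta(a, b), 1e-12, 1 - 1e-12))
            log_h = (stats.beta.logpdf(old, a, b)
                     - stats.beta.logpdf(new, a, b))
        state.drf[i][which] = new
    elif which == 0:  # d: multiplier move
        factor = math.exp(float(rng.uniform(-0.3, 0.3)))
        state.drf[i][0] = old * factor
        log_h = math.log(factor)
    else:  # r or f: reflected window on [0, 1)
        new = _reflect01(old + float(rng.uniform(-0.1, 0.1)))
        state.drf[i][which] = new
        log_h = 0.0

    def undo():
        state.drf[i][which] = old

    return log_h, {"tree_prior", "hyper"}, undo


def _reflect01(x: float) -> float:
    while not (0.0 <= x <= 1.0):
        if x < 0:
            x = -x
        if x > 1:
            x = 2.0 - x
    return min(max(x, 1e-12), 1.0 - 1e-12)


def _move_clock_rate(state: ChainState) -> tuple[float, set[str], Callable] | None:
    rng = state.rng
    keys = state._clock_keys()
    key = keys[rng.integers(len(keys))]
    old = state.clock_rate[key]
    if rng.random() < 0.5:
        # independence draw from the lognormal clock-rate prior
        new = float(np.exp(rng.normal(-6.0, 0.5)))
        log_h = (clock_hyper_log_prior(old, 0.0)
                 - clock_hyper_log_prior(new, 0.0))
        state.clock_rate[key] = new
    else:
        factor = math.exp(float(rng.uniform(-0.08, 0.08)))
        state.clock_rate[key] = old * factor
        log_h = math.log(factor)

    def undo():
        state.clock_rate[key] = old

    dirty = {"clock_prior", "igr_prior"}
    if state.spec.clock_mode == "strict":
        dirty |= {"lik_morph", "lik_mol"}
    return log_h, dirty, undo


def _move_clock_nu(state: ChainState) -> tuple[float, set[str], Callable] | None:
    if state.spec.clock_mode != "igr":
        return None
    rng = state.rng
    keys = state._clock_keys()
    key = keys[rng.integers(len(keys))]
    old = state.clock_nu[key]
    if rng.random() < 0.5:
        new = float(rng.exponential(0.1))  # independence draw, Exp(10)
        log_h = (-10.0 * old) - (-10.0 * new)
        state.clock_nu[key] = new
    else:
        factor = math.exp(float(rng.uniform(-0.3, 0.3)))
        state.clock_nu[key] = old * factor
        log_h = math.log(factor)

    def undo():
        state.clock_nu[key] = old

    return log_h, {"clock_prior", "igr_prior"}, undo


def _move_branch_effect(state: ChainState) -> tuple[float, set[str], Callable] | None:
    if state.spec.clock_mode != "igr":
        return None
    rng = state.rng
    keys = state._clock_keys()
    key = keys[rng.integers(len(keys))]
    eff = state.effects[key]
    branches = [n for n in state.tree.preorder() if n.parent is not None]
    node = branches[rng.integers(len(branches))]
    old = eff.length_of(node)
    if rng.random() < 0.5:  # multiplier
        factor = math.exp(float(rng.uniform(-0.5, 0.5)))
        eff.set_length(node, old * factor)
        log_h = math.log(factor)
    else:  # resample from the IGR prior (prior terms cancel in acceptance)
        t_b = node.parent.age - node.age
        nu = state.clock_nu[key]
        c = state.clock_rate[key]
        new = float(rng.gamma(shape=t_b / nu, scale=c * nu))
        if new <= 0:
            return None
        log_h = _gamma_logpdf(old, t_b / nu, c * nu) \
            - _gamma_logpdf(new, t_b / nu, c * nu)
        eff.set_length(node, new)

    def undo():
        eff.set_length(node, old)

    dirty = {"igr_prior", "lik_mol" if state._clock_key_for("mol") == key
             else "lik_morph"}
    if state.spec.clock_linkage == "linked":
        dirty = {"igr_prior", "lik_morph", "lik_mol"}
    elif key == "morph":
        dirty = {"igr_prior", "lik_morph"}
    else:
        dirty = {"igr_prior", "lik_mol"}
    return log_h, dirty, undo


def _gamma_logpdf(x: float, shape: float, scale: float) -> float:
    if x <= 0:
        return NEG_INF
    return (shape - 1) * math.log(x) - x / scale \
        - shape * math.log(scale) - math.lgamma(shape)


def _move_alpha(state: ChainState) -> tuple[float, set[str], Callable] | None:
    rng = state.rng
    choices = []
    if state.morph is not None:
        choices.append(("morph", None))
    for pi in range(len(state.site_model.gtr)):
        choices.append(("mol", pi))
    if not choices:
        return None
    kind, pi = choices[rng.integers(len(choices))]
    factor = math.exp(float(rng.uniform(-0.3, 0.3)))
    if kind == "morph":
        old = state.site_model.morph_alpha
        state.site_model.morph_alpha = old * factor

        def undo():
            state.site_model.morph_alpha = old

        return math.log(factor), {"sitemodel_prior", "lik_morph"}, undo
    g = state.site_model.gtr[pi]
    old = g.alpha
    g.alpha = old * factor

    def undo():
        g.alpha = old

    return math.log(factor), {"sitemodel_prior", "lik_mol"}, undo


def _move_pinv(state: ChainState) -> tuple[float, set[str], Callable] | None:
    if not state.site_model.gtr:
        return None
    rng = state.rng
    pi = int(rng.integers(len(state.site_model.gtr)))
    g = state.site_model.gtr[pi]
    old = g.pinv
    new = _reflect01(old + float(rng.uniform(-0.1, 0.1)))
    g.pinv = min(new, 1.0 - 1e-9)

    def undo():
        g.pinv = old

    return 0.0, {"lik_mol"}, undo


def _move_part_rates(state: ChainState) -> tuple[float, set[str], Callable] | None:
    pr = state.part_rates
    if pr is None or pr.multipliers.size < 2:
        return None
    rng = state.rng
    tau = 500.0
    x = pr.weights * pr.multipliers
    x = x / x.sum()
    alpha_fwd = np.maximum(tau * x, 1e-3)
    new_x = rng.dirichlet(alpha_fwd)
    if np.any(new_x <= 1e-10):
        return None
    alpha_rev = np.maximum(tau * new_x, 1e-3)
    log_h = (_dirichlet_logpdf(x, alpha_rev) - _dirichlet_logpdf(new_x, alpha_fwd))
    old_m = pr.multipliers.copy()
    pr.multipliers = new_x / pr.weights

    def undo():
        pr.multipliers = old_m

    return log_h, {"partrate_prior", "lik_morph", "lik_mol"}, undo


def _dirichlet_logpdf(x: np.ndarray, alpha: np.ndarray) -> float:
    from scipy.special import gammaln
    return float(np.sum((alpha - 1) * np.log(x))
                 + gammaln(alpha.sum()) - gammaln(alpha).sum())


# Each generation draws one structural move (tree or likelihood-touching
# parameters) and one cheap hyperparameter move (diversification and clock
# rates only re-evaluate closed-form priors), so the cheap coordinates are
# not starved of updates by the expensive ones.
_STRUCTURAL_MOVES: list[tuple[Callable, float]] = [
    (_move_node_age, 30.0),
    (_move_root_age, 8.0),
    (_move_tree_scale, 8.0),
    (_move_clock_scale, 8.0),
    (_move_narrow_exchange, 10.0),
    (propose_fossil_attachment, 10.0),
    (_move_branch_effect, 20.0),
    (_move_alpha, 3.0),
    (_move_pinv, 2.0),
    (_move_part_rates, 2.0),
]
_CHEAP_MOVES: list[tuple[Callable, float]] = [
    (_move_drf, 3.0),
    (_move_clock_rate, 2.0),
    (_move_clock_nu, 1.0),
]


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def _random_topology(labels: list[str], rng: np.random.Generator) -> Node:
    nodes = [Node(0.0, lab) for lab in labels]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[int(i)], nodes[int(j)]
        parent = Node()
        parent.add_child(a)
        parent.add_child(b)
        nodes = [n for n in nodes if n is not a and n is not b] + [parent]
    return nodes[0]


def _assign_ages(root: Node, root_age: float, rng: np.random.Generator) -> None:
    min_age: dict[int, float] = {}

    def compute_min(n: Node) -> float:
        if n.is_tip:
            min_age[id(n)] = n.age
        else:
            min_age[id(n)] = max(compute_min(c) for c in n.children)
        return min_age[id(n)]

    compute_min(root)
    root.age = root_age

    def assign(n: Node):
        for c in n.children:
            if not c.is_tip:
                lo = min_age[id(c)]
                c.age = float(rng.uniform(lo + 0.02 * (n.age - lo), n.age))
                assign(c)

    assign(root)


def initial_tree(spec: ModelSpec, data, config: McmcConfig,
                 rng: np.random.Generator, max_tries: int = 100) -> TimeTree:
    """Random feasible dated starting tree: random constrained extant
    topology, root age from the root prior, fossils attached sequentially
    at feasible positions."""
    if config.fixed_topology:
        if getattr(data, "tree", None) is None:
            raise ValueError("fixed_topology requires data.tree")
        return data.tree.copy()
    extant = _extant_labels(data)
    fossils: FossilTable = data.fossils or FossilTable({})
    for _ in range(max_tries):
        groups = []
        used: set[str] = set()
        for c in spec.constraints:
            groups.append(_random_topology(sorted(c.taxa), rng))
            used |= set(c.taxa)
        for lab in extant:
            if lab not in used:
                groups.append(Node(0.0, lab))
        root = groups[0]
        if len(groups) > 1:
            pool = list(groups)
            while len(pool) > 1:
                i, j = rng.choice(len(pool), size=2, replace=False)
                a, b = pool[int(i)], pool[int(j)]
                parent = Node()
                parent.add_child(a)
                parent.add_child(b)
                pool = [n for n in pool if n is not a and n is not b] + [parent]
            root = pool[0]
        if root.is_tip:
            raise ValueError("need at least 2 extant taxa")
        oldest = fossils.oldest_age
        if spec.fix_root_age is not None:
            root_age = spec.fix_root_age
        else:
            root_age = spec.root_prior.sample(rng, oldest)
        _assign_ages(root, root_age, rng)
        tree = TimeTree(root)
        ok = True
        for taxon, age in sorted(fossils.items()):
            slots = _attachment_slots(tree, age, allow_root=False)
            slots = [s for s in slots if s[3] > s[2]]
            if not slots:
                ok = False
                break
            kind, target, lo, hi = slots[rng.integers(len(slots))]
            a = float(rng.uniform(lo, hi))
            q = Node(a)
            p = target.parent
            it = p.children.index(target)
            q.add_child(Node(age, taxon, is_fossil=True))
            q.add_child(target)
            target.parent = q
            q.parent = p
            p.children[it] = q
        if not ok:
            continue
        tree = TimeTree(tree.root)  # revalidate
        if all(satisfies_constraint(tree, c) for c in spec.constraints):
            return tree
    raise RuntimeError("could not build a feasible starting tree")


def _extant_labels(data) -> list[str]:
    if getattr(data, "morph", None) is not None:
        taxa = list(data.morph.taxa)
    elif getattr(data, "mol", None) is not None:
        taxa = list(data.mol.taxa)
    elif getattr(data, "tree", None) is not None:
        taxa = data.tree.taxa()
    else:
        raise ValueError("no data to infer taxa from")
    fossil_names = set((data.fossils or FossilTable({})).ages) \
        if getattr(data, "fossils", None) is not None else set()
    return [t for t in taxa if t not in fossil_names]


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------

@dataclass
class McmcRun:
    """Samples and provenance for one independent run (cold chain only)."""

    trace: pd.DataFrame
    trees: list[TimeTree]
    swap_acceptance: float
    move_acceptance: dict[str, float]
    seed: int


@dataclass
class DataBundle:
    """Input container for :func:`run_mc3`."""

    morph: MorphMatrix | None = None
    mol: MolAlignment | None = None
    fossils: FossilTable | None = None
    tree: TimeTree | None = None


_STRUCT_P = np.array([w for _, w in _STRUCTURAL_MOVES])
_STRUCT_P = _STRUCT_P / _STRUCT_P.sum()
_CHEAP_P = np.array([w for _, w in _CHEAP_MOVES])
_CHEAP_P = _CHEAP_P / _CHEAP_P.sum()


def _try_move(state: ChainState, move, beta: float,
              rng: np.random.Generator, accept_counts, attempt_counts):
    name = move.__name__
    attempt_counts[name] = attempt_counts.get(name, 0) + 1
    old_components = dict(state.components)
    old_logpost = state.log_posterior()
    result = move(state)
    if result is None:
        return
    log_h, dirty, undo = result
    state.recompute(dirty)
    new_logpost = state.log_posterior()
    if new_logpost == NEG_INF:
        log_accept = NEG_INF
    else:
        log_accept = beta * (new_logpost - old_logpost) + log_h
    if math.log(rng.random() + 1e-300) < log_accept:
        accept_counts[name] = accept_counts.get(name, 0) + 1
    else:
        undo()
        state.components = old_components


def _one_chain_step(state: ChainState, beta: float, rng: np.random.Generator,
                    accept_counts, attempt_counts) -> None:
    idx = int(rng.choice(len(_STRUCTURAL_MOVES), p=_STRUCT_P))
    _try_move(state, _STRUCTURAL_MOVES[idx][0], beta, rng, accept_counts,
              attempt_counts)
    idx = int(rng.choice(len(_CHEAP_MOVES), p=_CHEAP_P))
    _try_move(state, _CHEAP_MOVES[idx][0], beta, rng, accept_counts,
              attempt_counts)


def _record(state: ChainState, gen: int, rows: list, trees: list[TimeTree]):
    row = {
        "gen": gen,
        "log_posterior": state.log_posterior(),
        "log_likelihood": state.log_likelihood(),
        "root_age": state.tree.root.age,
        "ghost_excess": ghost_excess(state.tree),
        "tree_length": state.tree.total_duration(),
    }
    if len(state.tree.extant_tips()) >= 2:
        row["youngest_split"] = youngest_split_age(state.tree)
    if state.spec.tree_prior != "uniform":
        for i, (d, r, f) in enumerate(state.drf):
            suff = f"_{i}" if len(state.drf) > 1 else ""
            row[f"d{suff}"] = d
            row[f"r{suff}"] = r
            if state._uses_psi():
                row[f"f{suff}"] = f
    for key in state._clock_keys():
        suff = "" if len(state._clock_keys()) == 1 else f"_{key}"
        row[f"clock_rate{suff}"] = state.clock_rate[key]
        if state.spec.clock_mode == "igr":
            row[f"nu{suff}"] = state.clock_nu[key]
    if state.morph is not None and not state.config.prior_only:
        row["morph_alpha"] = state.site_model.morph_alpha
    rows.append(row)
    trees.append(state.tree.copy())


def run_mc3(spec: ModelSpec, data: DataBundle,
            config: McmcConfig) -> list[McmcRun]:
    """Run ``config.n_runs`` independent Metropolis-coupled analyses.

    Each run uses ``config.n_chains`` incrementally heated chains
    (beta_i = 1/(1 + delta*i)); only the cold chain is recorded, every
    ``sample_every`` generations after a 25% burn-in (burn-in samples are
    recorded too and flagged by the ``burnin`` column so summaries can drop
    them).  Returns one :class:`McmcRun` per run.
    """
    runs = []
    for run_idx in range(config.n_runs):
        seed = (config.seed * 1_000_003 + 7919 * run_idx) % (2**31 - 1)
        rng = np.random.default_rng(seed)
        tree0 = initial_tree(spec, data, config, rng)
        chains = [ChainState(spec, data, config, tree0.copy()
                             if i else tree0, rng)
                  for i in range(config.n_chains)]
        betas = [1.0 / (1.0 + config.heat_delta * i)
                 for i in range(config.n_chains)]
        rows: list[dict] = []
        trees: list[TimeTree] = []
        accept: dict[str, int] = {}
        attempt: dict[str, int] = {}
        swap_acc = 0
        swap_try = 0
        for gen in range(1, config.n_generations + 1):
            for chain, beta in zip(chains, betas):
                _one_chain_step(chain, beta, rng, accept, attempt)
            if config.n_chains > 1 and gen % config.swap_every == 0:
                i = int(rng.integers(config.n_chains - 1))
                swap_try += 1
                li = chains[i].log_posterior()
                lj = chains[i + 1].log_posterior()
                if (lj > NEG_INF and li > NEG_INF):
                    log_acc = (betas[i] - betas[i + 1]) * (lj - li)
                    if math.log(rng.random() + 1e-300) < log_acc:
                        chains[i], chains[i + 1] = chains[i + 1], chains[i]
                        swap_acc += 1
            if gen % config.sample_every == 0:
                _record(chains[0], gen, rows, trees)
            if gen % config.check_every == 0:
                chains[0].full_recompute_check()
        trace = pd.DataFrame(rows)
        n_burn = int(math.ceil(config.burnin_frac * len(trace)))
        trace["burnin"] = np.arange(len(trace)) < n_burn
        runs.append(McmcRun(
            trace=trace, trees=trees,
            swap_acceptance=swap_acc / swap_try if swap_try else math.nan,
            move_acceptance={k: accept.get(k, 0) / v
                             for k, v in attempt.items()},
            seed=seed))
    return runs


def sample_induced_prior(spec: ModelSpec, data: DataBundle,
                         config: McmcConfig) -> list[McmcRun]:
    """Induced prior on dated trees: identical machinery with the character
    log-likelihood forced to 0.  Fossil ages, constraints and hyperpriors
    still act."""
    return run_mc3(spec, data, replace(config, prior_only=True))


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def convergence_diagnostics(runs: Sequence[McmcRun],
                            params: Sequence[str] | None = None,
                            psrf_threshold: float = 1.05) -> dict:
    """Per-parameter ESS and between-run PSRF (rank-normalized R-hat), plus
    the across-run standard deviation of clade sampling frequencies."""
    import warnings
    import arviz as az

    if len(runs) < 2:
        raise ValueError("need >= 2 runs for convergence diagnostics")
    lengths = {len(r.trace) for r in runs}
    if len(lengths) > 1:
        raise ValueError("runs must have equal length")
    traces = [r.trace[~r.trace["burnin"]] for r in runs]
    if params is None:
        skip = {"gen", "burnin"}
        params = [c for c in traces[0].columns
                  if c not in skip and np.issubdtype(traces[0][c].dtype,
                                                     np.number)]
    report: dict = {"ess": {}, "psrf": {}, "flags": []}
    if any(len(t) < 4 for t in traces):
        import logging
        logging.getLogger(__name__).warning(
            "too few post-burn-in samples for reliable diagnostics")
    for p in params:
        arr = np.stack([t[p].to_numpy() for t in traces])
        if np.allclose(arr, arr[0, 0]) or np.allclose(arr.std(axis=1), 0):
            report["ess"][p] = float(arr.shape[1] * arr.shape[0])
            report["psrf"][p] = 1.0
            continue
        if all(np.array_equal(arr[0], arr[i]) for i in range(arr.shape[0])):
            # byte-identical runs: no between-run variance by construction
            report["ess"][p] = float(arr.shape[1])
            report["psrf"][p] = 1.0
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            data = az.convert_to_dataset({p: arr})
            report["ess"][p] = float(az.ess(data)[p].values)
            report["psrf"][p] = float(az.rhat(data)[p].values)
        if report["psrf"][p] > psrf_threshold:
            report["flags"].append(f"PSRF({p}) = {report['psrf'][p]:.3f}")
    report["split_sd"] = _split_frequency_sd(runs)
    return report


def _split_frequency_sd(runs: Sequence[McmcRun]) -> float:
    from tedkit.timetree import prune_fossils

    freq_per_run = []
    all_splits: set[frozenset] = set()
    run_counts = []
    for r in runs:
        keep = [t for t, b in zip(r.trees, r.trace["burnin"]) if not b]
        counts: dict[frozenset, int] = {}
        for tree in keep:
            pruned = prune_fossils(tree) if tree.fossil_tips() else tree
            for node in pruned.internal_nodes():
                if node is pruned.root:
                    continue
                clade = frozenset(
                    t.label for t in TimeTree(node, validate=False).tips())
                counts[clade] = counts.get(clade, 0) + 1
        run_counts.append((counts, max(len(keep), 1)))
        all_splits |= set(counts)
    if not all_splits:
        return 0.0
    sds = []
    for split in all_splits:
        freqs = [c.get(split, 0) / n for c, n in run_counts]
        sds.append(float(np.std(freqs)))
    return float(np.mean(sds))
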