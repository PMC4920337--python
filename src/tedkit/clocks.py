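"""Clock models: map a dated tree to effective branch lengths.

The strict clock sets every branch's effective length (expected changes per
character) to c * t_b, with c the base clock rate in substitutions per site
per Myr and t_b the branch duration in Myr.  The independent gamma rates
(IGR, "white noise") relaxed clock draws each effective length independently
from Gamma(shape = t_b / nu, scale = c * nu), so E[v_b] = c * t_b and
Var[v_b] = c^2 * nu * t_b: the variance of the branch-average rate shrinks
as 1/t_b, the defining white-noise property.

The clock-rate hyperprior is lognormal(-6.0, 0.5) on the natural-log scale,
i.e. a central (median) rate of exp(-6) ~ 0.25% substitutions/site/Myr; the
variance-increase parameter nu has an Exp(10) prior.  Morphological and
molecular clocks may be linked (one set of effective lengths drives both
data types) or unlinked (independent (c, nu, lengths) per data type on the
shared dated tree).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import stats

from tedkit.timetree import TimeTree, Node

__all__ = [
    "ClockParams",
    "BranchEffects",
    "effective_lengths_strict",
    "igr_log_prior",
    "sample_igr_lengths",
    "clock_hyper_log_prior",
]

NEG_INF = float("-inf")


@dataclass
class ClockParams:
    """Base rate c, IGR variance-increase nu, clock mode and linkage."""

    rate: float = math.exp(-6.0)
    nu: float = 0.1
    mode: Literal["strict", "igr"] = "igr"
    linkage: Literal["linked", "unlinked"] = "linked"

    def __post_init__(self):
        if not self.rate > 0:
            raise ValueError("clock rate must be > 0")
        if self.nu < 0:
            raise ValueError("nu must be >= 0")
        if self.mode not in ("strict", "igr"):
            raise ValueError(f"unknown clock mode {self.mode!r}")
        if self.linkage not in ("linked", "unlinked"):
            raise ValueError(f"unknown linkage {self.linkage!r}")


class BranchEffects:
    """Per-branch effective lengths for a given tree.

    Branches are identified by their child node; lengths are expected
    changes per character.  ``mean_rate_of`` reports the implied
    branch-average rate v_b / t_b (per Myr).
    """

    def __init__(self, tree: TimeTree, lengths: dict[int, float]):
        self.tree = tree
        self.lengths = lengths

    @classmethod
    def from_values(cls, tree: TimeTree, values: dict[Node, float]
                    ) -> "BranchEffects":
        return cls(tree, {id(n): float(v) for n, v in values.items()})

    def length_of(self, node: Node) -> float:
        return self.lengths[id(node)]

    def set_length(self, node: Node, value: float) -> None:
        if value < 0:
            raise ValueError("effective length must be >= 0")
        self.lengths[id(node)] = float(value)

    def mean_rate_of(self, node: Node) -> float:
        t = node.parent.age - node.age
        return self.lengths[id(node)] / t if t > 0 else math.nan

    def branches(self):
        """Yield (child node, duration, effective length)."""
        for node in self.tree.preorder():
            if node.parent is not None:
                yield node, node.parent.age - node.age, self.lengths[id(node)]

    def total(self) -> float:
        return sum(v for _, _, v in self.branches())

    def copy(self) -> "BranchEffects":
        return BranchEffects(self.tree, dict(self.lengths))


def effective_lengths_strict(tree: TimeTree, c: float) -> BranchEffects:
    """Strict clock: v_b = c * t_b for every branch."""
    if not c > 0:
        raise ValueError("clock rate must be > 0")
    lengths = {}
    for node in tree.preorder():
        if node.parent is not None:
            lengths[id(node)] = c * (node.parent.age - node.age)
    return BranchEffects(tree, lengths)


def igr_log_prior(effects: BranchEffects, tree: TimeTree, c: float,
                  nu: float) -> float:
    """Log density of the branch effective lengths under the IGR clock:
    v_b ~ Gamma(shape = t_b / nu, scale = c * nu), independent across
    branches."""
    if not nu > 0:
        raise ValueError("igr_log_prior requires nu > 0; "
                         "nu = 0 is the strict clock")
    total = 0.0
    for node in tree.preorder():
        if node.parent is None:
            continue
        t_b = node.parent.age - node.age
        if t_b <= 0:
            return NEG_INF
        v = effects.length_of(node)
        shape = t_b / nu
        scale = c * nu
        if v <= 0:
            return NEG_INF  # zero-length branch effect rejected
        total += (shape - 1) * math.log(v) - v / scale \
            - shape * math.log(scale) - math.lgamma(shape)
    return total


def sample_igr_lengths(tree: TimeTree, c: float, nu: float,
                       rng: np.random.Generator | int) -> BranchEffects:
    """Draw effective lengths from the IGR clock; nu = 0 returns the strict
    lengths.  Deterministic for a fixed seed."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if nu == 0:
        return effective_lengths_strict(tree, c)
    lengths = {}
    for node in tree.preorder():
        if node.parent is None:
            continue
        t_b = node.parent.age - node.age
        lengths[id(node)] = float(rng.gamma(shape=t_b / nu, scale=c * nu))
    return BranchEffects(tree, lengths)


def clock_hyper_log_prior(c: float, nu: float, log_mean: float = -6.0,
                          log_sd: float = 0.5, nu_rate: float = 10.0) -> float:
    """Lognormal(log_mean, log_sd) log density for the clock rate plus
    Exp(nu_rate) log density for the IGR variance increase."""
    if c <= 0 or nu < 0:
        return NEG_INF
    logc = math.log(c)
    lp = (-0.5 * ((logc - log_mean) / log_sd) ** 2
          - math.log(log_sd * math.sqrt(2 * math.pi)) - logc)
    lp += math.log(nu_rate) - nu_rate * nu
    return lp
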