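"""High-level modelling interface: TotalEvidenceModel / TEDResults.

The pattern follows the statsmodels idiom: a model object is constructed
from data plus model options, ``fit()`` runs the Metropolis-coupled sampler
and returns a results object carrying traces, tree samples, summaries and
diagnostics.  ``sample_prior()`` returns the induced prior (the same
machinery with the character log-likelihood forced to zero), the standard
way to see how much dating information the tree prior, the fossil ages and
the constraints contribute before the characters are consulted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from tedkit.timetree import TimeTree, CladeConstraint, FossilTable
from tedkit.tree_priors import HyperPriors, HYPERPRIOR_PRESETS, RootAgePrior
from tedkit.char_models import MorphMatrix, MolAlignment
from tedkit.mcmc import (
    ModelSpec, McmcConfig, DataBundle, run_mc3, sample_induced_prior,
    convergence_diagnostics, McmcRun,
)
from tedkit.summarize import (
    TraceSummary, summarize_clade_ages, majority_consensus, hpd, kde,
    _config_hash,
)

__all__ = ["TotalEvidenceModel", "TEDResults"]


class TotalEvidenceModel:
    """Joint Bayesian model of dated phylogeny from characters + fossils.

    Parameters
    ----------
    morph, mol
        Morphological matrix and/or partitioned alignment (at least one,
        unless fitting prior-only with an initial tree).
    fossils
        Fossil tip ages (Ma); taxa not listed are extant at age 0.
    tree_prior
        One of "uniform", "bd", "fbd", "skyline".
    hyperprior
        A preset name ("vague", "low_extinction", "high_fossil_sampling",
        "low_ext_high_fs", "rapid_diversification") or a
        :class:`HyperPriors`.
    sampling_mode, rho
        Extant tip-sampling assumption: "complete", "random" (with
        probability ``rho``) or "diversified".
    clock, clock_linkage
        "strict" or "igr"; "linked" or "unlinked" morphological/molecular
        clocks.
    constraints
        Hard monophyly constraints on extant taxa (fossils always float).

    Examples
    --------
    >>> model = TotalEvidenceModel(morph=m, mol=a, fossils=ft,
    ...                            tree_prior="fbd",
    ...                            hyperprior="rapid_diversification",
    ...                            sampling_mode="diversified")
    >>> res = model.fit(n_generations=20000, seed=1)
    >>> print(res.summary())
    """

    def __init__(self, morph: MorphMatrix | None = None,
                 mol: MolAlignment | None = None,
                 fossils: FossilTable | None = None,
                 tree: TimeTree | None = None,
                 tree_prior: str = "fbd",
                 hyperprior: str | HyperPriors = "vague",
                 root_prior: RootAgePrior | None = None,
                 sampling_mode: str = "diversified",
                 rho: float = 1.0,
                 skyline_boundaries: tuple[float, ...] = (70.0, 55.0),
                 clock: str = "igr",
                 clock_linkage: str = "linked",
                 constraints: Sequence[CladeConstraint] = (),
                 fix_root_age: float | None = None):
        if morph is None and mol is None and tree is None:
            raise ValueError("need morph and/or mol data (or a tree for "
                             "prior-only work)")
        if isinstance(hyperprior, str):
            hyperprior = HYPERPRIOR_PRESETS[hyperprior]
        self.data = DataBundle(morph=morph, mol=mol,
                               fossils=fossils or FossilTable({}), tree=tree)
        self.spec = ModelSpec(
            tree_prior=tree_prior, hyper=hyperprior,
            root_prior=root_prior or RootAgePrior(),
            sampling_mode=sampling_mode, rho=rho,
            skyline_boundaries=skyline_boundaries,
            clock_mode=clock, clock_linkage=clock_linkage,
            constraints=tuple(constraints), fix_root_age=fix_root_age)

    @classmethod
    def from_dataset(cls, dataset, **kwargs) -> "TotalEvidenceModel":
        """Build from a :class:`tedkit.synthetic.SyntheticDataset`."""
        kwargs.setdefault("tree", dataset.tree)
        return cls(morph=dataset.morph, mol=dataset.mol,
                   fossils=dataset.fossils, **kwargs)

    def _config(self, n_generations, n_runs, n_chains, sample_every,
                seed, prior_only, fixed_topology, use_morph, use_mol,
                **extra) -> McmcConfig:
        return McmcConfig(
            n_generations=n_generations, n_runs=n_runs, n_chains=n_chains,
            sample_every=sample_every, seed=seed, prior_only=prior_only,
            fixed_topology=fixed_topology, use_morph=use_morph,
            use_mol=use_mol, **extra)

    def fit(self, n_generations: int = 100_000, n_runs: int = 2,
            n_chains: int = 2, sample_every: int = 50, seed: int = 0,
            fixed_topology: bool = False, use_morph: bool = True,
            use_mol: bool = True, **extra) -> "TEDResults":
        """Run the posterior sampler and return a results object."""
        config = self._config(n_generations, n_runs, n_chains, sample_every,
                              seed, False, fixed_topology, use_morph,
                              use_mol, **extra)
        runs = run_mc3(self.spec, self.data, config)
        return TEDResults(self, runs, config)

    def sample_prior(self, n_generations: int = 50_000, n_runs: int = 2,
                     n_chains: int = 1, sample_every: int = 50, seed: int = 0,
                     fixed_topology: bool = False, **extra) -> "TEDResults":
        """Sample the induced prior (character log-likelihood set to 0)."""
        config = self._config(n_generations, n_runs, n_chains, sample_every,
                              seed, True, fixed_topology, True, True, **extra)
        runs = sample_induced_prior(self.spec, self.data, config)
        return TEDResults(self, runs, config)


class TEDResults:
    """Posterior (or induced-prior) samples with summaries and diagnostics."""

    def __init__(self, model: TotalEvidenceModel, runs: list[McmcRun],
                 config: McmcConfig):
        self.model = model
        self.runs = runs
        self.config = config
        self.config_hash = _config_hash(model.spec, config)

    # -- sample access -----------------------------------------------------
    @property
    def trace(self) -> pd.DataFrame:
        """Pooled post-burn-in parameter trace across runs."""
        return pd.concat([r.trace[~r.trace["burnin"]] for r in self.runs],
                         ignore_index=True)

    @property
    def tree_samples(self) -> list[TimeTree]:
        return [t for r in self.runs
                for t, b in zip(r.trees, r.trace["burnin"]) if not b]

    @property
    def params(self) -> pd.Series:
        """Posterior medians of the scalar parameters."""
        tr = self.trace
        skip = {"gen", "burnin"}
        cols = [c for c in tr.columns if c not in skip
                and np.issubdtype(tr[c].dtype, np.number)]
        return tr[cols].median()

    def hpd(self, param: str, mass: float = 0.95) -> tuple[float, float]:
        return hpd(self.trace[param].to_numpy(), mass)

    # -- summaries ---------------------------------------------------------
    def summary(self) -> str:
        """Human-readable summary table (median, 95% HPD, ESS)."""
        ts = TraceSummary.from_trace(self.trace, config_hash=self.config_hash,
                                     seed=self.config.seed)
        mode = "induced prior" if self.config.prior_only else "posterior"
        spec = self.model.spec
        header = [
            "Total-evidence dating results",
            "=" * 64,
            f"tree prior:     {spec.tree_prior} "
            f"({spec.sampling_mode} sampling)",
            f"hyperpriors:    {spec.hyper.name}",
            f"clock:          {spec.clock_mode} ({spec.clock_linkage})",
            f"kind:           {mode}",
            f"runs x chains:  {self.config.n_runs} x {self.config.n_chains}, "
            f"{self.config.n_generations} generations",
            f"samples:        {len(self.trace)} (post burn-in, pooled)",
            f"provenance:     config {self.config_hash}, "
            f"seed {self.config.seed}",
            "-" * 64,
        ]
        with pd.option_context("display.float_format", "{:.4g}".format):
            body = ts.table.to_string()
        return "\n".join(header) + "\n" + body

    def summary_table(self) -> pd.DataFrame:
        return TraceSummary.from_trace(self.trace).table

    def clade_ages(self, clades: Mapping[str, Sequence[str]]):
        """Median + 95% HPD crown ages on fossil-pruned tree samples."""
        return summarize_clade_ages(self.tree_samples, clades,
                                    self.config_hash, self.config.seed)

    def consensus(self):
        return majority_consensus(self.tree_samples)

    def diagnostics(self, params: Sequence[str] | None = None) -> dict:
        return convergence_diagnostics(self.runs, params)

    # -- plotting ----------------------------------------------------------
    def plot_age_density(self, param: str = "root_age", adjust: float = 3.0,
                         ax=None, label: str | None = None):
        """KDE overlay of a posterior age distribution (returns the axes)."""
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x, y = kde(self.trace[param].to_numpy(), adjust)
        ax.plot(x, y, label=label or param)
        ax.set_xlabel("age (Ma)")
        ax.set_ylabel("density")
        if label:
            ax.legend()
        return ax

    def __repr__(self) -> str:
        mode = "prior" if self.config.prior_only else "posterior"
        return (f"<TEDResults {mode}, {len(self.runs)} runs, "
                f"{len(self.trace)} pooled samples>")
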