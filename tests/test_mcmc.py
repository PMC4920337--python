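"""Sampler correctness: prior-only vs direct simulation, fossil-attachment
proposals, cache consistency, convergence diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tedkit.timetree import TimeTree, FossilTable, CladeConstraint
from tedkit.tree_priors import (
    RootAgePrior, HyperPriors, FBDParams, fbd_log_density,
)
from tedkit.mcmc import (
    ModelSpec, McmcConfig, DataBundle, ChainState, run_mc3,
    sample_induced_prior, propose_fossil_attachment, convergence_diagnostics,
    _fossil_only_subtrees, _attachment_slots, initial_tree,
)


def interior_ages(run):
    out = []
    for t, b in zip(run.trees, run.trace["burnin"]):
        if b:
            continue
        ages = [n.age for n in t.internal_nodes() if n is not t.root]
        out.append(ages)
    return out


class TestPriorOnlyUniform:
    def test_interior_age_uniform(self):
        """Prior-only MCMC under the uniform tree prior with the root
        clamped at 10 must give Uniform(0, 10) interior node ages."""
        tree0 = TimeTree.from_newick("((A:4,B:4):6,C:10);")
        data = DataBundle(tree=tree0, fossils=FossilTable({}))
        spec = ModelSpec(tree_prior="uniform", fix_root_age=10.0,
                         root_prior=RootAgePrior(mean=20, offset=5),
                         clock_mode="strict", sampling_mode="complete")
        cfg = McmcConfig(n_generations=40_000, n_runs=1, n_chains=1,
                         sample_every=4, seed=42, prior_only=True)
        run = run_mc3(spec, data, cfg)[0]
        ages = np.array([a[0] for a in interior_ages(run)])
        assert len(ages) >= 7000
        ks = stats.kstest(ages, stats.uniform(0, 10).cdf)
        assert ks.pvalue > 0.01
        post = run.trace[~run.trace["burnin"]]
        assert np.allclose(post["root_age"], 10.0)


class TestPriorOnlyFreeRoot:
    @pytest.mark.parametrize("clock_mode", ["strict", "igr"])
    def test_root_marginal_is_offset_exponential(self, clock_mode):
        """Under the uniform tree prior the induced marginal of the root age
        is exactly the offset-exponential root prior (the conditional node
        ages integrate to one), a sharp whole-sampler check exercising the
        root, node-age and tree-stretch moves jointly."""
        import warnings
        import arviz as az

        tree0 = TimeTree.from_newick("(((A:4,B:4):3,C:7):3,D:10);")
        data = DataBundle(tree=tree0, fossils=FossilTable({}))
        rp = RootAgePrior(mean=20.0, offset=5.0)
        spec = ModelSpec(tree_prior="uniform", root_prior=rp,
                         clock_mode=clock_mode, sampling_mode="complete")
        cfg = McmcConfig(n_generations=50_000, n_runs=1, n_chains=1,
                         sample_every=6, seed=17, prior_only=True)
        run = run_mc3(spec, data, cfg)[0]
        roots = run.trace[~run.trace["burnin"]]["root_age"].to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ess = float(az.ess(roots[None, :]))
        thin = max(1, int(3 * len(roots) / max(ess, 1.0)))
        u = stats.expon(loc=5.0, scale=15.0).cdf(roots[::thin])
        assert stats.kstest(u, "uniform").pvalue > 0.01
        # mean within ~3 Monte-Carlo standard errors (sd of the target is 15)
        se = 15.0 / math.sqrt(max(ess, 1.0))
        assert roots.mean() == pytest.approx(20.0, abs=max(3 * se, 1.0))


class TestPriorOnlyFBD:
    def test_fossil_attachment_detailed_balance(self):
        """2 extant + 1 fossil, root fixed, (d, r, f) pinned: the sampled
        interior-node age distribution must match the FBD density that the
        forward simulator validated."""
        T, y = 8.0, 3.0
        tree0 = TimeTree.from_newick(f"((A:{y+1},F:1.0):{T-y-1},B:{T});",
                                     fossil_ages={"F": y})
        data = DataBundle(tree=tree0, fossils=FossilTable({"F": y}))
        hyper = HyperPriors(("fixed", 0.1), (5000.0, 5000.0),
                            (2000.0, 8000.0))
        spec = ModelSpec(tree_prior="fbd", hyper=hyper, fix_root_age=T,
                         sampling_mode="complete", clock_mode="strict",
                         root_prior=RootAgePrior(mean=20, offset=4))
        cfg = McmcConfig(n_generations=40_000, n_runs=1, n_chains=1,
                         sample_every=5, seed=7, prior_only=True)
        run = run_mc3(spec, data, cfg)[0]
        xs = np.array([a[0] for a in interior_ages(run)])
        params = FBDParams(0.1, 0.5, 0.2, rho=1.0, sampling_mode="complete")
        rp = RootAgePrior(mean=20, offset=4)

        def dens(x):
            nw = f"((A:{x:.6f},F:{x-y:.6f}):{T-x:.6f},B:{T:.6f});"
            t = TimeTree.from_newick(nw, fossil_ages={"F": y})
            return math.exp(fbd_log_density(t, params, rp))

        grid = np.linspace(y + 1e-4, T - 1e-4, 1000)
        d = np.array([dens(x) for x in grid])
        cdf = np.cumsum(d)
        cdf /= cdf[-1]
        u = np.interp(xs, grid, cdf)
        assert stats.kstest(u, "uniform").pvalue > 0.01

    def test_d_marginal_matches_quadrature(self):
        """Fixed 3-tip extant tree shape moves freely, d moves too; the
        joint (d, age) sampler's d marginal must match the 2-D quadrature
        of hyperprior x tree density."""
        from tedkit.tree_priors import bd_log_density
        T = 10.0
        tree0 = TimeTree.from_newick("((A:4,B:4):6,C:10);")
        data = DataBundle(tree=tree0, fossils=FossilTable({}))
        hyper = HyperPriors(("exp", 10.0), (5000.0, 5000.0), (1.0, 1.0))
        spec = ModelSpec(tree_prior="bd", hyper=hyper, fix_root_age=T,
                         sampling_mode="complete", clock_mode="strict",
                         root_prior=RootAgePrior(mean=20, offset=4))
        cfg = McmcConfig(n_generations=80_000, n_runs=1, n_chains=1,
                         sample_every=10, seed=11, prior_only=True)
        run = run_mc3(spec, data, cfg)[0]
        ds = run.trace[~run.trace["burnin"]]["d"].to_numpy()
        # oracle: p(d) ~ Exp(10)(d) * int_0^T f_bd(x | d, r=0.5) dx, on a
        # log-dense d grid (the lower tail is sharp) with a trapezoid CDF
        from scipy.integrate import cumulative_trapezoid
        rp = RootAgePrior(mean=20, offset=4)
        dgrid = np.concatenate([np.geomspace(1e-4, 0.05, 220),
                                np.linspace(0.051, 1.2, 200)])
        xgrid = np.linspace(1e-3, T - 1e-3, 160)
        marg = []
        for d in dgrid:
            p = FBDParams(d, 0.5, 0.0, sampling_mode="complete")
            vals = [math.exp(bd_log_density(
                TimeTree.from_newick(f"((A:{x},B:{x}):{T-x},C:{T});"),
                p, rp)) for x in xgrid]
            marg.append(10 * math.exp(-10 * d) * np.trapezoid(vals, xgrid))
        cdf = cumulative_trapezoid(marg, dgrid, initial=0.0)
        cdf /= cdf[-1]
        # thin to near-independence before the KS test: KS assumes iid
        import warnings
        import arviz as az
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ess = float(az.ess(ds[None, :]))
        thin = max(1, int(3 * len(ds) / max(ess, 1.0)))
        u = np.interp(ds[::thin], dgrid, cdf)
        assert stats.kstest(u, "uniform").pvalue > 0.01


class TestInducedPrior:
    def test_root_never_below_oldest_fossil(self):
        tree0 = TimeTree.from_newick("((A:10,F:4):10,B:20);",
                                     fossil_ages={"F": 6})
        data = DataBundle(tree=tree0, fossils=FossilTable({"F": 6.0}))
        spec = ModelSpec(tree_prior="fbd", sampling_mode="complete",
                         clock_mode="strict",
                         root_prior=RootAgePrior(mean=15.0, offset=2.0))
        cfg = McmcConfig(n_generations=5000, n_runs=1, n_chains=1,
                         sample_every=10, seed=3)
        run = sample_induced_prior(spec, data, cfg)[0]
        assert (run.trace["root_age"] >= 6.0).all()

    def test_constraints_hold_in_every_sample(self):
        tree0 = TimeTree.from_newick("(((A:4,B:4):4,C:8):4,D:12);")
        data = DataBundle(tree=tree0, fossils=FossilTable({}))
        spec = ModelSpec(tree_prior="uniform", sampling_mode="complete",
                         clock_mode="strict",
                         constraints=(CladeConstraint("AB",
                                                      frozenset({"A", "B"})),),
                         root_prior=RootAgePrior(mean=20.0, offset=2.0))
        cfg = McmcConfig(n_generations=6000, n_runs=1, n_chains=1,
                         sample_every=10, seed=5, prior_only=True)
        run = run_mc3(spec, data, cfg)[0]
        from tedkit.timetree import satisfies_constraint
        for t in run.trees:
            assert satisfies_constraint(t, spec.constraints[0])


class TestFossilAttachmentProposal:
    def _state(self):
        T = 10.0
        tree0 = TimeTree.from_newick(f"((A:5,F:2):5,B:{T});",
                                     fossil_ages={"F": 3})
        data = DataBundle(tree=tree0, fossils=FossilTable({"F": 3.0}))
        spec = ModelSpec(tree_prior="fbd", sampling_mode="complete",
                         clock_mode="strict", fix_root_age=T,
                         root_prior=RootAgePrior(mean=20, offset=2))
        cfg = McmcConfig(n_generations=1, n_runs=1, n_chains=1,
                         prior_only=True, seed=0)
        rng = np.random.default_rng(9)
        return ChainState(spec, data, cfg, tree0.copy(), rng)

    def test_slots_exclude_too_young_parents(self):
        # a branch whose parent is younger than the fossil is infeasible
        t = TimeTree.from_newick("((A:2,B:2):8,C:10);")
        slots = _attachment_slots(t, 5.0, allow_root=False)
        # feasible branches: those with parent age > 5: the two root
        # children (ages 2 and 0 -> parents 10), not A or B (parent age 2)
        assert len(slots) == 2

    def test_proposal_uniform_over_slots(self):
        state = self._state()
        rng = np.random.default_rng(1)
        counts = {}
        n = 4000
        for _ in range(n):
            res = propose_fossil_attachment(state, rng)
            assert res is not None
            _, _, undo = res
            parent = state.tree.tip("F").parent
            sib = [c for c in parent.children
                   if c is not state.tree.tip("F")][0]
            key = sib.label or "internal"
            counts[key] = counts.get(key, 0) + 1
            undo()
        # root fixed: feasible slots are the A branch, the B branch and the
        # old attachment branch; chi-square uniformity over slot choice
        observed = np.array(list(counts.values()))
        expected = np.full(len(observed), n / len(observed))
        chi2 = ((observed - expected) ** 2 / expected).sum()
        crit = stats.chi2(df=len(observed) - 1).ppf(0.999)
        assert chi2 < crit

    def test_undo_restores_tree(self):
        state = self._state()
        before = state.tree.to_newick()
        rng = np.random.default_rng(2)
        for _ in range(200):
            res = propose_fossil_attachment(state, rng)
            res[2]()
            assert state.tree.to_newick() == before

    def test_fossil_only_subtree_detection(self):
        t = TimeTree.from_newick(
            "(((F1:1,F2:3):2,A:8):2,B:10);",
            fossil_ages={"F1": 5, "F2": 3})
        movers = _fossil_only_subtrees(t)
        assert len(movers) == 1
        assert not movers[0].is_tip  # the (F1,F2) clade moves as one unit


class TestCacheConsistency:
    def test_full_recompute_check_passes_during_run(self):
        # run_mc3 raises if cached and fresh components drift; a clean run
        # through mixed move types is the assertion
        tree0 = TimeTree.from_newick("((A:10,F:4):10,B:20);",
                                     fossil_ages={"F": 6})
        data = DataBundle(tree=tree0, fossils=FossilTable({"F": 6.0}))
        spec = ModelSpec(tree_prior="fbd", sampling_mode="complete",
                         clock_mode="igr",
                         root_prior=RootAgePrior(mean=15.0, offset=2.0))
        cfg = McmcConfig(n_generations=3000, n_runs=1, n_chains=2,
                         sample_every=50, seed=13, prior_only=True,
                         check_every=250)
        run_mc3(spec, data, cfg)


class TestInitialTree:
    def test_respects_constraints_and_fossils(self):
        labels = [f"t{i}" for i in range(8)]
        from tedkit.char_models import MorphMatrix
        states = np.tile(np.array([[0], [1]]), (4, 1)).astype(np.int8)
        morph = MorphMatrix(labels + ["F1"],
                            np.vstack([states, [[0]]]), np.array([2]),
                            variable_only=False)
        data = DataBundle(morph=morph, fossils=FossilTable({"F1": 30.0}))
        spec = ModelSpec(tree_prior="fbd", clock_mode="strict",
                         sampling_mode="complete",
                         constraints=(CladeConstraint(
                             "c", frozenset({"t0", "t1", "t2"})),),
                         root_prior=RootAgePrior(mean=164.0, offset=64.0))
        cfg = McmcConfig(n_generations=1, seed=1)
        rng = np.random.default_rng(0)
        from tedkit.timetree import satisfies_constraint
        for _ in range(5):
            t = initial_tree(spec, data, cfg, rng)
            assert satisfies_constraint(t, spec.constraints[0])
            assert t.root.age >= 64.0
            assert {x.label for x in t.fossil_tips()} == {"F1"}
            assert t.tip("F1").age == pytest.approx(30.0)


class TestDiagnostics:
    def _runs_from(self, arrays):
        runs = []
        for arr in arrays:
            trace = pd.DataFrame({"x": arr, "gen": np.arange(len(arr))})
            trace["burnin"] = False
            run = type("R", (), {})()
            run.trace = trace
            run.trees = []
            runs.append(run)
        return runs

    def test_identical_traces_psrf_one(self):
        x = np.sin(np.arange(400) / 7.0)
        report = convergence_diagnostics(self._runs_from([x, x]),
                                         params=["x"])
        assert report["psrf"]["x"] == pytest.approx(1.0, abs=1e-6)

    def test_independent_normals_psrf_near_one(self, rng):
        a = rng.normal(0, 1, 10_000)
        b = rng.normal(0, 1, 10_000)
        report = convergence_diagnostics(self._runs_from([a, b]),
                                         params=["x"])
        assert report["psrf"]["x"] < 1.01
        assert not report["flags"]

    def test_iid_ess_near_length(self, rng):
        a = rng.normal(0, 1, 5000)
        b = rng.normal(0, 1, 5000)
        report = convergence_diagnostics(self._runs_from([a, b]),
                                         params=["x"])
        assert report["ess"]["x"] == pytest.approx(10_000, rel=0.2)

    def test_shifted_chains_flagged(self, rng):
        a = rng.normal(0, 1, 2000)
        b = rng.normal(4, 1, 2000)
        report = convergence_diagnostics(self._runs_from([a, b]),
                                         params=["x"])
        assert report["psrf"]["x"] > 1.05
        assert report["flags"]
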