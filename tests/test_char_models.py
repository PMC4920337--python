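"""Character likelihoods: gamma discretization, pruning vs enumeration,
ascertainment correction, partition-rate prior, filtering."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats, integrate

from tedkit.timetree import TimeTree
from tedkit.char_models import (
    MorphMatrix, MolAlignment, SiteModelParams, GTRPartitionParams,
    PartitionRates, discretize_gamma, mk_transition_probs, gtr_rate_matrix,
    pruning_loglik, mkv_correction, morph_log_likelihood,
    partition_rate_log_prior, filter_characters, compile_morph, compile_mol,
    compiled_morph_loglik, compiled_mol_loglik, _GTRTransition,
)
from tedkit.clocks import effective_lengths_strict


def enumerate_loglik(tree, eff, pattern, k, alpha, ncat, rate_mult=1.0):
    """Independent oracle: exhaustive sum over interior-state assignments."""
    cats = discretize_gamma(alpha, ncat)
    nodes = list(tree.postorder())
    internal = [n for n in nodes if not n.is_tip]
    total = 0.0
    for rate in cats:
        for assign in itertools.product(range(k), repeat=len(internal)):
            amap = {id(n): s for n, s in zip(internal, assign)}
            prob = 1.0 / k
            for n in nodes:
                if n.parent is None:
                    continue
                ps = amap[id(n.parent)]
                if n.is_tip:
                    cs = pattern[n.label]
                    if cs is None:  # missing: sum over states
                        continue
                else:
                    cs = amap[id(n)]
                v = eff.length_of(n) * rate * rate_mult
                P = mk_transition_probs(k, np.array(v))
                if n.is_tip:
                    prob *= P[ps, cs]
                else:
                    prob *= P[ps, cs]
            # missing tips: multiply sum over their states = 1 (row sums 1)
            total += prob / len(cats)
    return math.log(total)


class TestDiscretizeGamma:
    def test_single_category(self):
        assert discretize_gamma(0.5, 1) == pytest.approx([1.0])

    def test_no_variation_limit(self):
        rates = discretize_gamma(1e6, 4)
        assert np.allclose(rates, 1.0, atol=1e-2)

    def test_matches_quadrature(self):
        # numeric integration of the quantile-bin means, alpha = 0.5
        alpha, ncat = 0.5, 4
        rates = discretize_gamma(alpha, ncat)
        dist = stats.gamma(a=alpha, scale=1 / alpha)
        bounds = [0] + list(dist.ppf(np.arange(1, ncat) / ncat)) + [np.inf]
        expected = []
        for lo, hi in zip(bounds, bounds[1:]):
            m, _ = integrate.quad(lambda x: x * dist.pdf(x), lo, hi)
            expected.append(m * ncat)
        expected = np.array(expected) / np.mean(expected)
        assert np.allclose(rates, expected, atol=1e-6)

    def test_mean_exactly_one(self):
        for alpha in (0.1, 0.7, 3.0):
            assert discretize_gamma(alpha, 4).mean() == pytest.approx(1.0)

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            discretize_gamma(0.0, 4)


class TestPruning:
    def test_two_tips_zero_length_same_state(self):
        tree = TimeTree.from_newick("(A:5,B:5);")
        eff = effective_lengths_strict(tree, 1.0)
        for node in tree.tips():
            eff.set_length(node, 0.0)
        data = MorphMatrix(["A", "B"], np.array([[0], [0]]), np.array([2]),
                           variable_only=False)
        ll = pruning_loglik(tree, eff, data, SiteModelParams())
        assert ll == pytest.approx(-math.log(2))

    def test_mk_state_relabeling_invariance(self):
        tree = TimeTree.from_newick("((A:4,B:4):6,(C:7,D:7):3);")
        eff = effective_lengths_strict(tree, 0.05)
        model = SiteModelParams(morph_alpha=0.7)
        states = np.array([[0], [1], [0], [1]])
        a = pruning_loglik(tree, eff, MorphMatrix(
            ["A", "B", "C", "D"], states, np.array([2]),
            variable_only=False), model)
        b = pruning_loglik(tree, eff, MorphMatrix(
            ["A", "B", "C", "D"], 1 - states, np.array([2]),
            variable_only=False), model)
        assert a == pytest.approx(b)

    @pytest.mark.parametrize("pattern", [(0, 1, 2, 1), (2, 2, 0, 1),
                                         (0, None, 2, 1)])
    def test_matches_exhaustive_enumeration(self, pattern):
        tree = TimeTree.from_newick("((A:4,B:4):6,(C:7,D:7):3);")
        eff = effective_lengths_strict(tree, 0.05)
        obs = dict(zip("ABCD", pattern))
        col = [[-1 if v is None else v] for v in pattern]
        data = MorphMatrix(list("ABCD"), np.array(col), np.array([3]),
                           variable_only=False)
        ll = pruning_loglik(tree, eff, data, SiteModelParams(morph_alpha=0.7))
        oracle = enumerate_loglik(tree, eff, obs, 3, 0.7, 4)
        assert ll == pytest.approx(oracle, abs=1e-8)

    def test_taxon_and_character_order_invariance(self, rng):
        tree = TimeTree.from_newick("((A:4,B:4):6,(C:7,D:7):3);")
        eff = effective_lengths_strict(tree, 0.05)
        states = rng.integers(0, 2, (4, 12)).astype(np.int8)
        model = SiteModelParams(morph_alpha=1.2)
        base = pruning_loglik(tree, eff, MorphMatrix(
            list("ABCD"), states, np.full(12, 2), variable_only=False), model)
        perm_t = [2, 0, 3, 1]
        perm_c = rng.permutation(12)
        shuffled = pruning_loglik(tree, eff, MorphMatrix(
            [list("ABCD")[i] for i in perm_t], states[perm_t][:, perm_c],
            np.full(12, 2), variable_only=False), model)
        assert base == pytest.approx(shuffled)

    def test_gtr_matches_brute_force(self):
        tree = TimeTree.from_newick("(A:3,B:3);")
        eff = effective_lengths_strict(tree, 0.1)
        gp = GTRPartitionParams(exch=[1, 2, 1, 1, 3, 1],
                                freqs=[.3, .2, .3, .2], alpha=0.5, pinv=0.2)
        mol = MolAlignment(["A", "B"], np.array([[0], [2]]), np.array([0]))
        ll = pruning_loglik(tree, eff, mol, SiteModelParams(gtr=[gp]))
        g = _GTRTransition(gp)
        cats = discretize_gamma(0.5, 4)
        tot = 0.0
        for rate in cats:
            PA = g.probs(np.array(eff.length_of(tree.tip("A")) * rate))
            PB = g.probs(np.array(eff.length_of(tree.tip("B")) * rate))
            tot += sum(gp.freqs[s] * PA[s, 0] * PB[s, 2]
                       for s in range(4)) / len(cats)
        assert ll == pytest.approx(math.log((1 - gp.pinv) * tot), abs=1e-10)

    def test_gtr_rate_matrix_properties(self):
        gp = GTRPartitionParams(exch=[1, 2, 1, 1, 3, 1],
                                freqs=[.3, .2, .3, .2])
        Q = gtr_rate_matrix(gp)
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)
        assert np.allclose(gp.freqs @ Q, 0.0, atol=1e-12)  # stationarity
        assert -(gp.freqs * np.diag(Q)).sum() == pytest.approx(1.0)

    def test_rate_length_confounding(self, rng):
        # scaling all effective lengths by c and the multiplier by 1/c
        # leaves the likelihood unchanged
        tree = TimeTree.from_newick("((A:4,B:4):6,(C:7,D:7):3);")
        eff = effective_lengths_strict(tree, 0.05)
        states = rng.integers(0, 2, (4, 8)).astype(np.int8)
        data = MorphMatrix(list("ABCD"), states, np.full(8, 2),
                           variable_only=False)
        model = SiteModelParams(morph_alpha=1.0)
        r1 = PartitionRates(np.array([1.0]), np.array([1.0]))
        base = pruning_loglik(tree, eff, data, model, r1)
        eff2 = effective_lengths_strict(tree, 0.05 * 3.0)
        blocks = compile_morph(data)
        scaled = compiled_morph_loglik(tree, eff2, blocks, 1.0, 4,
                                       multiplier=1 / 3.0,
                                       variable_only=False)
        assert base == pytest.approx(scaled, abs=1e-9)

    def test_taxon_mismatch_raises(self, three_tip, strict_effects):
        data = MorphMatrix(["A", "B", "X"], np.zeros((3, 1), dtype=int) +
                           [[0], [1], [1]], np.array([2]),
                           variable_only=False)
        with pytest.raises(ValueError, match="missing from data"):
            pruning_loglik(three_tip, strict_effects, data,
                           SiteModelParams())


class TestMkvCorrection:
    def test_long_branch_limit(self):
        # saturated tree: P(constant) -> sum_j (1/k)^ntips * k; for k=2,
        # 3 tips: 2 * (1/2)^3 = 1/4 -> correction = -log(3/4) per char
        tree = TimeTree.from_newick("((A:2,B:2):3,C:5);")
        eff = effective_lengths_strict(tree, 1.0)
        for node in tree.preorder():
            if node.parent is not None:
                eff.set_length(node, 50.0)
        corr = mkv_correction(tree, eff, SiteModelParams(), 2, 1)
        assert corr == pytest.approx(-math.log(0.75), abs=1e-6)

    def test_zero_lengths_degenerate(self):
        tree = TimeTree.from_newick("((A:2,B:2):3,C:5);")
        eff = effective_lengths_strict(tree, 1.0)
        for node in tree.preorder():
            if node.parent is not None:
                eff.set_length(node, 0.0)
        assert mkv_correction(tree, eff, SiteModelParams(), 2, 5) == -math.inf

    def test_matches_variable_pattern_enumeration(self):
        tree = TimeTree.from_newick("((A:2,B:2):3,C:5);")
        eff = effective_lengths_strict(tree, 0.1)
        model = SiteModelParams(morph_alpha=0.7)
        corr = mkv_correction(tree, eff, model, 2, 1)
        tot_var = 0.0
        for pat in itertools.product(range(2), repeat=3):
            if len(set(pat)) == 1:
                continue
            d = MorphMatrix(list("ABC"), np.array([[p] for p in pat]),
                            np.array([2]), variable_only=False)
            tot_var += math.exp(pruning_loglik(tree, eff, d, model))
        assert corr == pytest.approx(-math.log(tot_var), abs=1e-10)

    def test_corrected_variable_probabilities_sum_to_one(self):
        tree = TimeTree.from_newick("((A:2,B:2):3,C:5);")
        eff = effective_lengths_strict(tree, 0.1)
        model = SiteModelParams(morph_alpha=0.7)
        corr = mkv_correction(tree, eff, model, 2, 1)
        total = 0.0
        for pat in itertools.product(range(2), repeat=3):
            if len(set(pat)) == 1:
                continue
            d = MorphMatrix(list("ABC"), np.array([[p] for p in pat]),
                            np.array([2]), variable_only=False)
            total += math.exp(pruning_loglik(tree, eff, d, model) + corr)
        assert total == pytest.approx(1.0, abs=1e-10)


class TestPartitionRates:
    def test_flat_constraint(self):
        pr = PartitionRates.flat([300, 600, 600])
        assert float(pr.weights @ pr.multipliers) == pytest.approx(1.0)

    def test_constraint_violation_raises(self):
        with pytest.raises(ValueError):
            PartitionRates(np.array([2.0, 2.0]), np.array([0.5, 0.5]))

    def test_two_partition_beta_closed_form(self):
        # equal weights: x1 = m1/2 ~ Beta(a, a); change of variables
        pr = PartitionRates(np.array([0.6, 1.4]), np.array([0.5, 0.5]))
        lp = partition_rate_log_prior(pr, 2.0)
        expected = math.log(stats.beta.pdf(0.3, 2, 2) * 0.5)
        assert lp == pytest.approx(expected, abs=1e-10)

    def test_flat_concentration_is_uniform(self):
        # all-ones concentration: the scaled-Dirichlet density is constant
        # over the constraint surface (so m = 1 sits at a flat optimum)
        w = np.array([0.25, 0.25, 0.5])
        center = partition_rate_log_prior(PartitionRates(np.ones(3), w), 1.0)
        m = np.array([1.1, 1.1, 0.9])
        m = m / (w @ m)
        off = partition_rate_log_prior(PartitionRates(m, w), 1.0)
        assert center == pytest.approx(off, abs=1e-10)


class TestFilterCharacters:
    def _matrix(self):
        states = np.array([
            [0, 0, 1, 0, 2],
            [1, 0, 1, 1, 1],
            [0, 0, 0, 1, 0],
        ])
        return MorphMatrix(["A", "B", "C"], states,
                           np.array([2, 2, 2, 2, 3]), variable_only=False)

    def test_constant_character_removed(self):
        out = filter_characters(self._matrix())
        assert out.n_chars == 4  # column 1 is constant

    def test_taxon_drop_cascades(self):
        # dropping B makes column 3 constant across {A, C}? A=0, C=1 -> no;
        # dropping C makes column 2 constant (A=1, B=1)
        out = filter_characters(self._matrix(), drop_taxa=["C"])
        assert out.n_taxa == 2
        assert out.n_chars == 3  # constant col 1 and newly-constant col 2

    def test_noop_identity(self):
        m = self._matrix()
        out = filter_characters(m, remove_constant=False)
        assert out.n_chars == m.n_chars
        assert np.array_equal(out.states, m.states)


class TestCompiledPaths:
    def test_compiled_matches_public_morph(self, rng):
        tree = TimeTree.from_newick("((A:4,B:4):6,(C:7,D:7):3);")
        eff = effective_lengths_strict(tree, 0.05)
        states = rng.integers(0, 2, (4, 40)).astype(np.int8)
        keep = [j for j in range(40) if len(set(states[:, j])) > 1]
        m = MorphMatrix(list("ABCD"), states[:, keep],
                        np.full(len(keep), 2), variable_only=True)
        a = morph_log_likelihood(tree, eff, m, SiteModelParams(morph_alpha=.7))
        b = compiled_morph_loglik(tree, eff, compile_morph(m), 0.7, 4)
        assert a == pytest.approx(b, abs=1e-10)

    def test_compiled_matches_public_mol(self, rng):
        tree = TimeTree.from_newick("((A:4,B:4):6,(C:7,D:7):3);")
        eff = effective_lengths_strict(tree, 0.05)
        sites = rng.integers(0, 4, (4, 60)).astype(np.int8)
        sites[0, :5] = -1
        gtr = [GTRPartitionParams(alpha=0.5, pinv=0.1),
               GTRPartitionParams(alpha=2.0)]
        mol = MolAlignment(list("ABCD"), sites,
                           np.repeat([0, 1], 30))
        a = pruning_loglik(tree, eff, mol, SiteModelParams(gtr=gtr))
        b = compiled_mol_loglik(tree, eff, compile_mol(mol, gtr), gtr)
        assert a == pytest.approx(b, abs=1e-10)
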