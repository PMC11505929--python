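"""Likelihoods, priors, MCMC, stepping stone, model weights and grid scans."""

import math

import numpy as np
import pytest
import scipy.integrate
import scipy.stats

from conftest import brute_force_loglik
from solutemap.history_sampler import simulate_unconditioned
from solutemap.likelihood_inference import (Analysis, ConditionedModel,
                                            MarkovCharacter, Prior, PriorSpec,
                                            RootPrior, empirical_bayes_priors,
                                            gamma_age_prior_mass,
                                            information_criteria, mcmc_sample,
                                            mle_fit,
                                            model_weights_and_average,
                                            rate_grid_scan,
                                            stepping_stone_logml,
                                            transition_matrix, tree_likelihood)
from solutemap.phylo_io import CharacterMatrix, DatedTree, TreeSample
from solutemap.trait_models import RateModel, StateSpace

BIN = StateSpace.binary("L", "H")


def _char(tree, states, model, alphabet=("L", "H"), name="x"):
    data = CharacterMatrix(name, alphabet,
                           {t: frozenset(s) for t, s in states.items()})
    return MarkovCharacter(name, model, data)


class TestTransitionMatrix:
    def test_t0_is_identity(self):
        Q = RateModel.ard(BIN, [0.3, 0.7]).Q
        np.testing.assert_allclose(transition_matrix(Q, 0.0), np.eye(2),
                                   atol=1e-12)

    def test_er_closed_form(self):
        # stay probability (1 + exp(-2 r t)) / 2 at r t = ln 2 / 2 ... r=0.5
        Q = RateModel.er(BIN, 0.5).Q
        P = transition_matrix(Q, math.log(2))
        assert P[0, 0] == pytest.approx((1 + math.exp(-2 * 0.5 * math.log(2))) / 2)
        assert P[0, 0] == pytest.approx(0.75)

    def test_ard_long_time_reaches_stationary(self):
        a, b = 0.12, 0.31
        Q = RateModel.ard(BIN, [a, b]).Q
        P = transition_matrix(Q, 1e5)
        pi = np.array([b, a]) / (a + b)
        np.testing.assert_allclose(P, np.tile(pi, (2, 1)), atol=1e-9)


class TestTreeLikelihood:
    def test_two_tip_er_closed_form(self, two_tip_tree):
        ch = _char(two_tip_tree, {"A": "L", "B": "L"}, RateModel.er(BIN, 0.5))
        ll = tree_likelihood(two_tip_tree, [ch])
        # 0.5 * (0.75^2 + 0.25^2)
        assert math.exp(ll) == pytest.approx(0.3125, rel=1e-12)

    def test_zero_rate_same_state(self, four_tip_tree):
        ch = _char(four_tip_tree, {t: "L" for t in "ABCD"},
                   RateModel.er(BIN, 0.0))
        assert math.exp(tree_likelihood(four_tip_tree, [ch])) == \
            pytest.approx(0.5)

    def test_missing_taxon_errors(self, four_tip_tree):
        ch = _char(four_tip_tree, {t: "L" for t in "ABC"},
                   RateModel.er(BIN, 0.1))
        with pytest.raises(KeyError):
            tree_likelihood(four_tip_tree, [ch])

    @pytest.mark.parametrize("states,model", [
        ({"A": "L", "B": "H", "C": "L", "D": "LH"}, RateModel.er(BIN, 0.3)),
        ({"A": "L", "B": "H", "C": "H", "D": "L"},
         RateModel.ard(BIN, [0.2, 0.6])),
    ])
    def test_pruning_matches_brute_force_binary(self, four_tip_tree, states,
                                                model):
        ch = _char(four_tip_tree, states, model)
        ll = tree_likelihood(four_tip_tree, [ch])
        bf = brute_force_loglik(four_tip_tree,
                                [(model.Q, np.array([0.5, 0.5]), ch.data)])
        assert ll == pytest.approx(bf, rel=1e-10)

    def test_pruning_matches_brute_force_4state(self, five_tip_tree):
        space = StateSpace.product([("g1", ("A", "P")), ("g2", ("A", "P"))])
        rng = np.random.default_rng(4)
        model = RateModel.ard(space, rng.uniform(0.01, 0.3, 12))
        labels = space.labels
        states = {t: frozenset([labels[i]])
                  for t, i in zip("ABCDE", [0, 3, 1, 2, 3])}
        states["C"] = frozenset([labels[1], labels[2]])   # ambiguous tip
        data = CharacterMatrix("gg", labels, states)
        ch = MarkovCharacter("gg", model, data)
        ll = tree_likelihood(five_tip_tree, [ch])
        bf = brute_force_loglik(five_tip_tree,
                                [(model.Q, np.full(4, 0.25), data)])
        assert ll == pytest.approx(bf, rel=1e-10)

    def test_conditioned_deterministic_table_factor_one(self, four_tip_tree):
        gene = _char(four_tip_tree, {t: "P" for t in "ABCD"},
                     RateModel.er(StateSpace.binary(), 0.1),
                     alphabet=("A", "P"), name="g")
        cm = ConditionedModel(StateSpace.binary(), ("L", "H"),
                              [[1.0, 0.0], [0.0, 1.0]])   # pi(H|P)=1, pi(L|A)=1
        focal = CharacterMatrix("hab", ("L", "H"),
                                {t: frozenset("H") for t in "ABCD"})
        ll_cond = tree_likelihood(four_tip_tree, [gene], cm, focal)
        ll_plain = tree_likelihood(four_tip_tree, [gene])
        assert ll_cond == pytest.approx(ll_plain)   # focal factor is 1

    def test_conditioned_factorization_identity(self, four_tip_tree):
        """With unambiguous conditioning tips, total loglik = Markov loglik
        + sum of log pi(focal | conditioning) over tips."""
        gene = _char(four_tip_tree, {"A": "P", "B": "A", "C": "P", "D": "A"},
                     RateModel.ard(StateSpace.binary(), [0.2, 0.1]),
                     alphabet=("A", "P"), name="g")
        table = np.array([[0.8, 0.2], [0.3, 0.7]])
        cm = ConditionedModel(StateSpace.binary(), ("L", "H"), table)
        fstates = {"A": "H", "B": "L", "C": "L", "D": "H"}
        focal = CharacterMatrix("hab", ("L", "H"),
                                {t: frozenset(s) for t, s in fstates.items()})
        ll = tree_likelihood(four_tip_tree, [gene], cm, focal)
        expected = tree_likelihood(four_tip_tree, [gene])
        for t, f in fstates.items():
            row = 1 if gene.data.states[t] == {"P"} else 0
            expected += math.log(table[row, 0 if f == "L" else 1])
        assert ll == pytest.approx(expected, rel=1e-12)

    def test_conditioned_ambiguous_matches_brute_force(self, four_tip_tree):
        """Ambiguity in conditioning tips is summed inside the pruning pass."""
        gene_states = {"A": "P", "B": "AP", "C": "P", "D": "A"}
        model = RateModel.ard(StateSpace.binary(), [0.2, 0.1])
        gene = _char(four_tip_tree, gene_states, model,
                     alphabet=("A", "P"), name="g")
        table = np.array([[0.8, 0.2], [0.3, 0.7]])
        cm = ConditionedModel(StateSpace.binary(), ("L", "H"), table)
        focal = CharacterMatrix("hab", ("L", "H"),
                                {"A": {"H"}, "B": {"L"}, "C": {"L", "H"},
                                 "D": {"H"}})
        ll = tree_likelihood(four_tip_tree, [gene], cm, focal)
        bf = brute_force_loglik(
            four_tip_tree, [(model.Q, np.array([0.5, 0.5]), gene.data)],
            table=table, focal_data=focal,
            cond_space=StateSpace.binary(), focal_alphabet=("L", "H"))
        assert ll == pytest.approx(bf, rel=1e-10)


class TestMLE:
    def test_er_rate_recovery_within_factor_2(self):
        rng = np.random.default_rng(11)
        # 200-tip balanced tree, depth chosen so ~1 change per path
        n = 200
        import dendropy
        import random as _random
        dtree = dendropy.model.birthdeath.birth_death_tree(
            birth_rate=1.0, death_rate=0.0, num_extant_tips=n,
            rng=_random.Random(7))
        tree = DatedTree.from_dendropy(dtree, repair=True)
        tree = DatedTree(tree.parent, tree.ages * (1000.0 / tree.root_age),
                         tree.labels)
        true_r = 0.01
        Q = RateModel.er(BIN, true_r).Q
        h = simulate_unconditioned(tree, Q, np.array([0.5, 0.5]), rng,
                                   labels=("L", "H"))
        data = CharacterMatrix("x", ("L", "H"),
                               {tree.labels[v]: frozenset([h.node_state(v)])
                                for v in tree.tip_indices})
        res = mle_fit(tree, [MarkovCharacter("x", RateModel.er(BIN), data)],
                      n_starts=3, seed=1)
        assert true_r / 2 < res.rates[0] < true_r * 2

    def test_identical_tips_hit_lower_bound(self, four_tip_tree):
        ch = _char(four_tip_tree, {t: "L" for t in "ABCD"}, RateModel.er(BIN))
        res = mle_fit(four_tip_tree, [ch], n_starts=2, seed=0)
        assert res.rates[0] == pytest.approx(1e-9, rel=1e-3)

    def test_conditioned_table_closed_form(self, four_tip_tree):
        gene = _char(four_tip_tree, {"A": "P", "B": "P", "C": "A", "D": "A"},
                     RateModel.er(StateSpace.binary()),
                     alphabet=("A", "P"), name="g")
        focal = CharacterMatrix("hab", ("L", "H"),
                                {"A": {"H"}, "B": {"H"}, "C": {"L"},
                                 "D": {"H"}})
        cm = ConditionedModel(StateSpace.binary(), ("L", "H"))
        res = mle_fit(four_tip_tree, [gene], cm, focal, n_starts=2, seed=0)
        np.testing.assert_allclose(res.table,
                                   [[0.5, 0.5],    # A-state tips: 1 L, 1 H
                                    [0.0, 1.0]])   # P-state tips: 2 H


class TestPriors:
    def test_empirical_bayes_lognormal_mass(self):
        spec = empirical_bayes_priors([0.5])
        p = spec.rates[0]
        assert p.kind == "lognormal" and p.mu == pytest.approx(math.log(0.5))
        # ~98% of the density between MLE/10 and 10*MLE;
        # closed form: Phi(ln 10) - Phi(-ln 10)
        exact = 2 * scipy.stats.norm.cdf(math.log(10)) - 1
        assert p.mass(0.05, 5.0) == pytest.approx(exact, abs=1e-9)

    def test_median_equals_mle(self):
        p = empirical_bayes_priors([0.37]).rates[0]
        assert p._dist().median() == pytest.approx(0.37)

    def test_small_mle_gets_exponential(self):
        spec = empirical_bayes_priors([0.005, 0.01, 0.011])
        kinds = [p.kind for p in spec.rates]
        assert kinds == ["exponential", "exponential", "lognormal"]
        assert spec.rates[0].lam == 100.0

    def test_negative_mle_rejected(self):
        with pytest.raises(ValueError):
            empirical_bayes_priors([-0.1])

    def test_gamma_root_prior_mass(self):
        assert gamma_age_prior_mass(2639, 179, 2300, 3000) == \
            pytest.approx(0.95, abs=0.005)


def _flat_analysis():
    """ER model with one observed tip and one missing tip: the likelihood is
    0.5 for every rate (uniform root is stationary under ER)."""
    tree = DatedTree.from_newick("(A:1,B:1);")
    data = CharacterMatrix("x", ("L", "H"), {"A": {"L"}, "B": {"L", "H"}})
    return Analysis(TreeSample([tree]),
                    [MarkovCharacter("x", RateModel.er(BIN), data)])


class TestMCMC:
    def test_flat_likelihood_recovers_prior(self):
        an = _flat_analysis()
        priors = PriorSpec([Prior("exponential", lam=100.0)])
        ps = mcmc_sample(an, None, priors, n_iter=40000, n_draws=4000, seed=5)
        stat = scipy.stats.kstest(ps.rates[:, 0],
                                  scipy.stats.expon(scale=0.01).cdf)
        assert stat.pvalue > 0.01

    def test_same_seed_identical_chains(self, four_tip_tree):
        ch = _char(four_tip_tree, {"A": "L", "B": "H", "C": "L", "D": "L"},
                   RateModel.er(BIN))
        an = Analysis(TreeSample([four_tip_tree]), [ch])
        priors = empirical_bayes_priors([0.1])
        a = mcmc_sample(an, None, priors, n_iter=2000, n_draws=100, seed=9)
        b = mcmc_sample(an, None, priors, n_iter=2000, n_draws=100, seed=9)
        np.testing.assert_array_equal(a.rates, b.rates)
        np.testing.assert_array_equal(a.tree_indices, b.tree_indices)

    def test_reports_acceptance_and_ess(self, four_tip_tree):
        ch = _char(four_tip_tree, {"A": "L", "B": "H", "C": "L", "D": "L"},
                   RateModel.er(BIN))
        an = Analysis(TreeSample([four_tip_tree]), [ch])
        ps = mcmc_sample(an, None, empirical_bayes_priors([0.1]),
                         n_iter=2000, n_draws=100, seed=3)
        assert 0 < ps.meta["acceptance"][0] <= 1
        assert ps.meta["ess"][0] > 0


class TestSteppingStone:
    def test_flat_likelihood_gives_log_half(self):
        an = _flat_analysis()
        priors = PriorSpec([Prior("exponential", lam=100.0)])
        lm, se = stepping_stone_logml(an, None, priors, n_rungs=8,
                                      samples_per_rung=400, seed=2)
        assert lm == pytest.approx(math.log(0.5), abs=max(3 * se, 1e-3))

    def test_matches_quadrature_on_er(self, four_tip_tree):
        ch = _char(four_tip_tree, {"A": "L", "B": "H", "C": "L", "D": "L"},
                   RateModel.er(BIN))
        an = Analysis(TreeSample([four_tip_tree]), [ch])
        lam = 2.0
        priors = PriorSpec([Prior("exponential", lam=lam)])

        def integrand(r):
            return math.exp(an.loglik(np.array([r]))) * lam * math.exp(-lam * r)

        quad, _err = scipy.integrate.quad(integrand, 0, 60, limit=300)
        lm, _se = stepping_stone_logml(an, None, priors, n_rungs=24,
                                       samples_per_rung=1500, seed=3)
        assert lm == pytest.approx(math.log(quad), abs=0.1)

    def test_doubling_rungs_is_self_consistent(self, four_tip_tree):
        ch = _char(four_tip_tree, {"A": "L", "B": "H", "C": "L", "D": "L"},
                   RateModel.er(BIN))
        an = Analysis(TreeSample([four_tip_tree]), [ch])
        priors = PriorSpec([Prior("exponential", lam=2.0)])
        lm1, se1 = stepping_stone_logml(an, None, priors, n_rungs=12,
                                        samples_per_rung=800, seed=4)
        lm2, se2 = stepping_stone_logml(an, None, priors, n_rungs=24,
                                        samples_per_rung=800, seed=5)
        assert abs(lm1 - lm2) < 2 * (se1 + se2) + 0.05

    def test_too_few_rungs_rejected(self):
        with pytest.raises(ValueError):
            stepping_stone_logml(_flat_analysis(), None,
                                 PriorSpec([Prior("exponential")]), n_rungs=4)


class TestModelWeights:
    def test_equal_logml_equal_weights(self):
        mw = model_weights_and_average([-10.0, -10.0])
        np.testing.assert_allclose(mw.posterior, [0.5, 0.5])

    def test_ln9_difference(self):
        mw = model_weights_and_average([0.0, -math.log(9)])
        np.testing.assert_allclose(mw.posterior, [0.9, 0.1], rtol=1e-12)

    def test_blending_matches_model_averaging_equation(self):
        # weights (0.55, 0.45) on per-model posteriors (0.77, 0.55)
        mw = model_weights_and_average([math.log(0.55), math.log(0.45)])
        np.testing.assert_allclose(mw.posterior, [0.55, 0.45], rtol=1e-12)
        assert mw.blend(np.array([0.77, 0.55])) == pytest.approx(0.671)

    def test_nonfinite_model_excluded_with_warning(self):
        mw = model_weights_and_average([-5.0, -np.inf, -5.0])
        assert mw.posterior[1] == 0
        np.testing.assert_allclose(mw.posterior, [0.5, 0, 0.5])
        assert mw.warnings

    def test_information_criteria(self):
        aic, bic, wa, wb = information_criteria(
            np.array([-10.0, -9.0]), np.array([1, 2]), n=50)
        np.testing.assert_allclose(aic, [22.0, 22.0])
        np.testing.assert_allclose(wa, [0.5, 0.5])
        assert bic[0] < bic[1]       # BIC penalizes the extra parameter more
        assert wb[0] > 0.5


class TestRateGridScan:
    def _analysis(self, four_tip_tree):
        return _char(four_tip_tree,
                     {"A": "L", "B": "H", "C": "L", "D": "H"},
                     RateModel.ard(BIN))

    def test_grid_max_at_mle_cell(self, four_tip_tree):
        ch = self._analysis(four_tip_tree)
        res = mle_fit(four_tip_tree, [ch], n_starts=3, seed=0)
        g = np.geomspace(1e-4, 0.1, 12)
        grid1 = np.sort(np.append(g, res.rates[0]))
        grid2 = np.sort(np.append(g, res.rates[1]))
        scan = rate_grid_scan(four_tip_tree, [ch], grid1, grid2)
        i, j = np.unravel_index(np.argmax(scan["loglik"]),
                                scan["loglik"].shape)
        assert scan["loglik"][i, j] <= res.loglik + 1e-6
        assert scan["loglik"][i, j] >= res.loglik - 0.05
        assert scan["within_2"][i, j]

    def test_symmetric_data_diagonal_root_posterior(self, four_tip_tree):
        # exchangeable tip pattern + equal rates -> root posterior 1/2
        ch = self._analysis(four_tip_tree)
        g = np.geomspace(1e-3, 0.1, 4)
        scan = rate_grid_scan(four_tip_tree, [ch], g, g)
        for k in range(len(g)):
            np.testing.assert_allclose(scan["root_posterior"][k, k],
                                       [0.5, 0.5], atol=1e-10)

    def test_landscape_matches_pointwise_likelihood(self, four_tip_tree):
        ch = self._analysis(four_tip_tree)
        g1 = np.geomspace(1e-3, 0.05, 3)
        g2 = np.geomspace(1e-3, 0.05, 3)
        scan = rate_grid_scan(four_tip_tree, [ch], g1, g2)
        for i, a in enumerate(g1):
            for j, b in enumerate(g2):
                ll = tree_likelihood(four_tip_tree,
                                     [ch], rates=np.array([a, b]))
                assert scan["loglik"][i, j] == pytest.approx(ll, rel=1e-12)
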