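"""Posterior summaries: profiles, event ages, rates through time, HPDs."""

import numpy as np
import pytest

from solutemap.history_sampler import (node_marginals, sample_markov_history,
                                       simulate_unconditioned)
from solutemap.phylo_io import (CharacterMatrix, DatedTree, HistoryCollection,
                                MappedHistory, TreeSample)
from solutemap.posterior_summaries import (first_occurrence_ages, hpd_interval,
                                           rate_ratios,
                                           state_probability_profiles,
                                           transitions_through_time)
from solutemap.likelihood_inference import PosteriorSample
from solutemap.trait_models import RateModel, StateSpace

BIN = StateSpace.binary("L", "H")


def _collection(tree, histories_per_draw):
    ts = TreeSample([tree])
    coll = HistoryCollection(ts)
    for hs in histories_per_draw:
        coll.tree_indices.append(0)
        coll.histories.append(hs)
        coll.params.append({})
    return coll


def _mapped(tree, segments, root_state, name="x"):
    return MappedHistory(tree, name, segments, root_state)


def _switch_history(tree, switch_age, before, after, name="x"):
    """All branches 'before' above switch_age and 'after' below it."""
    segs = [[] for _ in range(tree.n_nodes)]
    for v in range(tree.n_nodes):
        if v == tree.root:
            continue
        top, bot = tree.ages[tree.parent[v]], tree.ages[v]
        if bot >= switch_age:
            segs[v] = [(top, bot, before)]
        elif top <= switch_age:
            segs[v] = [(top, bot, after)]
        else:
            segs[v] = [(top, switch_age, before), (switch_age, bot, after)]
    return _mapped(tree, segs, before, name)


class TestStateProfiles:
    def test_identical_draws_give_unit_probabilities(self, four_tip_tree):
        h = _switch_history(four_tip_tree, 0.5, "L", "H")
        coll = _collection(four_tip_tree, [{"x": h} for _ in range(10)])
        prof = state_probability_profiles(coll, "x", age_step=0.25)
        for p in prof.node_probs.values():
            assert set(np.round(p, 12)) <= {0.0, 1.0}

    def test_tip_probabilities_match_observations(self, four_tip_tree):
        rng = np.random.default_rng(0)
        data = CharacterMatrix(
            "x", ("L", "H"),
            {"A": {"L"}, "B": {"H"}, "C": {"L"}, "D": {"L"}})
        Q = RateModel.er(BIN, 0.2).Q
        pi = np.array([0.5, 0.5])
        draws = [{"x": sample_markov_history(four_tip_tree, data, Q, pi, rng)}
                 for _ in range(50)]
        prof = state_probability_profiles(_collection(four_tip_tree, draws),
                                          "x")
        clades = four_tip_tree.clades()
        for v in four_tip_tree.tip_indices:
            lbl = four_tip_tree.labels[v]
            obs = next(iter(data.states[lbl]))
            p = prof.node_probs[clades[v]]
            assert p[prof.states.index(obs)] == pytest.approx(1.0)

    def test_root_probabilities_match_exact_marginals(self, four_tip_tree):
        rng = np.random.default_rng(1)
        data = CharacterMatrix(
            "x", ("L", "H"),
            {"A": {"L"}, "B": {"H"}, "C": {"L"}, "D": {"L"}})
        Q = RateModel.er(BIN, 0.25).Q
        pi = np.array([0.5, 0.5])
        marg = node_marginals(four_tip_tree, data, Q, pi)
        n = 3000
        draws = [{"x": sample_markov_history(four_tip_tree, data, Q, pi, rng)}
                 for _ in range(n)]
        prof = state_probability_profiles(_collection(four_tip_tree, draws),
                                          "x")
        clades = four_tip_tree.clades()
        root_p = prof.node_probs[clades[four_tip_tree.root]]
        pH = marg[four_tip_tree.root, 1]
        se = np.sqrt(pH * (1 - pH) / n)
        assert root_p[prof.states.index("H")] == pytest.approx(pH, abs=4 * se)

    def test_branch_grid_at_node_age_equals_node_probability(self,
                                                             four_tip_tree):
        h = _switch_history(four_tip_tree, 0.5, "L", "H")
        coll = _collection(four_tip_tree, [{"x": h} for _ in range(5)])
        prof = state_probability_profiles(coll, "x", age_step=0.5)
        clades = four_tip_tree.clades()
        for v in range(four_tip_tree.n_nodes):
            if v == four_tip_tree.root:
                continue
            cl = clades[v]
            age = four_tip_tree.ages[v]
            np.testing.assert_allclose(prof.branch_probs[cl][age],
                                       prof.node_probs[cl], atol=1e-12)

    def test_absent_character_errors(self, four_tip_tree):
        h = _switch_history(four_tip_tree, 0.5, "L", "H")
        coll = _collection(four_tip_tree, [{"x": h}])
        with pytest.raises(KeyError):
            state_probability_profiles(coll, "missing")


class TestFirstOccurrence:
    def test_root_predicate_gives_root_age_distribution(self, four_tip_tree):
        h = _switch_history(four_tip_tree, 0.5, "L", "H")
        coll = _collection(four_tip_tree, [{"x": h} for _ in range(7)])
        ev = first_occurrence_ages(coll, "x", lambda s: True)
        np.testing.assert_allclose(ev.ages, four_tip_tree.root_age)

    def test_switch_age_is_detected(self):
        tree = DatedTree.from_newick("(A:10,B:10);")
        a, b = tree.taxon_to_node["A"], tree.taxon_to_node["B"]
        segs = [[] for _ in range(tree.n_nodes)]
        segs[a] = [(10.0, 1.2, "L"), (1.2, 0.0, "H")]
        segs[b] = [(10.0, 0.0, "L")]
        coll = _collection(tree, [{"x": _mapped(tree, segs, "L")}])
        ev = first_occurrence_ages(coll, "x", lambda s: s == "H")
        assert ev.ages[0] == pytest.approx(1.2)

    def test_never_present_is_nan(self, four_tip_tree):
        h = _switch_history(four_tip_tree, 0.5, "L", "L")
        coll = _collection(four_tip_tree, [{"x": h}])
        ev = first_occurrence_ages(coll, "x", lambda s: s == "H")
        assert np.isnan(ev.ages[0])
        assert ev.present_fraction() == 0.0

    def test_prob_older_than_reference_counts_draws(self, four_tip_tree):
        draws = []
        for age in (0.4, 0.8, 1.2, 1.6):
            draws.append({"x": _switch_history(four_tip_tree, age, "L", "H")})
        coll = _collection(four_tip_tree, draws)
        ev = first_occurrence_ages(coll, "x", lambda s: s == "H")
        np.testing.assert_allclose(sorted(ev.ages), [0.4, 0.8, 1.2, 1.6])
        assert ev.prob_older_than(1.0) == pytest.approx(0.5)

    def test_clade_scope(self, four_tip_tree):
        h = _switch_history(four_tip_tree, 0.5, "L", "H")
        coll = _collection(four_tip_tree, [{"x": h}])
        ev = first_occurrence_ages(coll, "x", lambda s: s == "H",
                                   scope={"A", "B"})
        assert ev.ages[0] == pytest.approx(0.5)
        with pytest.raises(ValueError):
            first_occurrence_ages(coll, "x", lambda s: True, scope=set())


class TestTransitionsThroughTime:
    def test_no_transitions_zero_rates(self, four_tip_tree):
        h = _switch_history(four_tip_tree, 0.5, "L", "L")
        coll = _collection(four_tip_tree, [{"x": h}])
        r = transitions_through_time(coll, "x", ("L", "H"),
                                     [0.0, 1.0, 2.0])
        np.testing.assert_allclose(r.rates, 0.0)

    def test_single_transition_rate_arithmetic(self):
        # 2 lineages over a 500-Myr bin with one L->H transition inside:
        # 1 / (2 lineages * 0.5 Gyr) = 1.0 per lineage per Gyr
        tree = DatedTree.from_newick("(A:1000,B:1000);")
        a, b = tree.taxon_to_node["A"], tree.taxon_to_node["B"]
        segs = [[] for _ in range(tree.n_nodes)]
        segs[a] = [(1000.0, 250.0, "L"), (250.0, 0.0, "H")]
        segs[b] = [(1000.0, 0.0, "L")]
        coll = _collection(tree, [{"x": _mapped(tree, segs, "L")}])
        r = transitions_through_time(coll, "x", ("L", "H"),
                                     [0.0, 500.0, 1000.0])
        # bins are reported old->young: [1000,500), [500,0)
        np.testing.assert_allclose(r.rates, [0.0, 1.0])

    def test_counts_conserved_across_bins(self, four_tip_tree):
        rng = np.random.default_rng(3)
        Q = RateModel.er(BIN, 0.8).Q
        draws = []
        for _ in range(30):
            h = simulate_unconditioned(four_tip_tree, Q,
                                       np.array([0.5, 0.5]), rng, ("L", "H"))
            draws.append({"x": h})
        coll = _collection(four_tip_tree, draws)
        edges = np.linspace(0, 2.0, 9)
        r = transitions_through_time(coll, "x", ("L", "H"), edges)
        for k, hs in enumerate(coll.histories):
            h = hs["x"]
            total = sum(1 for v in range(four_tip_tree.n_nodes)
                        if v != four_tip_tree.root
                        for s0, s1 in zip(h.segments[v][:-1],
                                          h.segments[v][1:])
                        if s0[2] == "L" and s1[2] == "H")
            assert r.counts[k].sum() == total


class TestRateRatios:
    def test_er_binary_ratio_is_one(self):
        model = RateModel.er(StateSpace.binary())
        ps = PosteriorSample(np.zeros(200, dtype=int),
                             np.full((200, 1), 0.02), None, [], {})
        from solutemap.trait_models import rate_classes
        cls = rate_classes(StateSpace.binary())
        out = rate_ratios([model], [ps], [1.0], cls, n_draws=200, seed=0)
        assert out["L/G"]["median"] == pytest.approx(1.0)

    def test_hand_built_ratio(self):
        space = StateSpace.product([("g1", ("A", "P")), ("g2", ("A", "P"))])
        model = RateModel.ard(space)
        from solutemap.trait_models import rate_classes
        cls = rate_classes(space)
        rng = np.random.default_rng(1)
        # construct rates so that L-sum = 0.4 and G-sum = 0.02
        rates = np.zeros(12)
        Qtmp = model.with_rates(np.arange(12) + 1.0).Q
        labels = space.labels
        ia, ip = labels.index(("A", "A")), labels.index(("P", "P"))
        for j in range(4):
            if j != ia:
                rates[model.classes[ia, j]] = 0.02 / 3
            if j != ip:
                rates[model.classes[ip, j]] = 0.4 / 3
        ps = PosteriorSample(np.zeros(150, dtype=int),
                             np.tile(rates, (150, 1)), None, [], {})
        out = rate_ratios([model], [ps], [1.0], cls, n_draws=150, seed=2)
        assert out["L/G"]["median"] == pytest.approx(20.0)
        del rng, Qtmp

    def test_model_averaged_medians_recomputable(self):
        model = RateModel.ard(StateSpace.binary())
        rng = np.random.default_rng(5)
        rates = rng.lognormal(-4, 0.3, size=(300, 2))
        ps = PosteriorSample(np.zeros(300, dtype=int), rates, None, [], {})
        from solutemap.trait_models import rate_classes
        cls = rate_classes(StateSpace.binary())
        out = rate_ratios([model], [ps], [1.0], cls, n_draws=400, seed=3)
        # independent recomputation from the exported samples
        r = out["L/G"]["samples"]
        assert out["L/G"]["median"] == pytest.approx(np.median(r))
        assert "hpd89" in out["L/G"]


class TestHPD:
    def test_uniform_width_close_to_mass(self):
        rng = np.random.default_rng(0)
        x = rng.random(20000)
        lo, hi = hpd_interval(x, 0.89)
        assert hi - lo == pytest.approx(0.89, abs=0.02)

    def test_point_mass_zero_width(self):
        lo, hi = hpd_interval(np.full(500, 3.14), 0.95)
        assert lo == hi == pytest.approx(3.14)

    def test_matches_exhaustive_window_search(self):
        rng = np.random.default_rng(4)
        x = np.sort(rng.lognormal(0, 1, 600))
        lo, hi = hpd_interval(x, 0.89)
        k = int(np.ceil(0.89 * len(x)))
        best = min(((x[i + k - 1] - x[i], x[i], x[i + k - 1])
                    for i in range(len(x) - k + 1)))
        assert (lo, hi) == (best[1], best[2])

    def test_multimodal_warns(self):
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(0, 0.05, 500),
                            rng.normal(10, 0.05, 500)])
        with pytest.warns(UserWarning, match="multimodal"):
            hpd_interval(x, 0.5)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            hpd_interval(np.arange(50), 0.89)
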