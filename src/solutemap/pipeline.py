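"""End-to-end orchestration of the multi-character mapping workflow.

Stage 1 analyzes every character independently (MLE, empirical-Bayes
priors, per-model MCMC, stepping-stone marginal likelihoods, model posterior
probabilities, model-blended stochastic maps). Stage 2 D-tests each
candidate character against the focal character and ranks them by the
significance of the association. Stage 3 re-analyzes the focal character
conditioned on the top-ranked characters, over all combinations of the
conditioners' candidate models (Bayesian sampling for small joint models,
maximum likelihood otherwise, with combination weights approximated from
the per-character marginal-likelihood differences). Stage 4 distills the
final history collection into node/branch posteriors, first-occurrence
ages, transition rates through time and rate ratios.

Every stage derives its RNG seed from the master seed, so a run is fully
reproducible from (inputs, config); stages checkpoint their numeric state
to JSON so an interrupted run can resume without recomputation.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import history_sampler, posterior_summaries
from .correlation_dtest import d_test
from .likelihood_inference import (Analysis, ConditionedModel, MarkovCharacter,
                                   PosteriorSample, empirical_bayes_priors,
                                   mcmc_sample, mle_fit,
                                   model_weights_and_average,
                                   information_criteria,
                                   stepping_stone_logml)
from .history_sampler import node_marginals, simulate_unconditioned
from .phylo_io import (CharacterMatrix, HistoryCollection, TreeSample,
                       write_histories)
from .trait_models import (CandidateModel, RateModel, StateSpace,
                           combine_characters, enumerate_pathway_models)

__all__ = [
    "PipelineConfig",
    "CharacterInput",
    "SingleCharacterResult",
    "single_character_pipeline",
    "conditioned_pipeline",
    "full_workflow",
    "inputs_from_bundle",
]


def inputs_from_bundle(bundle):
    """Split a synthetic benchmark bundle into workflow inputs.

    Returns (characters, focal): per-character CharacterInput objects with
    multi-gene supercharacters split back into per-gene binary columns, and
    the focal (conditioned) character if the scenario defines one.
    """
    from .synthetic_data import _split_product
    characters, focal = [], None
    focal_name = bundle.scenario.focal.name if bundle.scenario.focal else None
    for spec in bundle.scenario.characters:
        m = bundle.matrices[spec.name]
        if isinstance(m.alphabet[0], tuple):
            genes = {g: CharacterMatrix(g, p.alphabet, p.states)
                     for g, p in zip(spec.genes, _split_product(m))}
        else:
            genes = {spec.genes[0]: m}
        characters.append(CharacterInput(spec.name, genes))
    if focal_name is not None:
        focal = CharacterInput(focal_name,
                               {focal_name: bundle.matrices[focal_name]})
    return characters, focal


@dataclass
class PipelineConfig:
    """Tuning knobs for the workflow; defaults target a full-size analysis.

    Tests and small studies should scale ``n_mcmc_iter``, ``ss_rungs``,
    ``ss_samples``, ``n_history_draws`` and ``n_dtest_draws`` down.
    """

    seed: int = 0
    n_mcmc_iter: int = 100000
    n_posterior_draws: int = 1000
    n_history_draws: int = 5000
    n_dtest_draws: int = 1000
    n_dtest_null: int = 500
    dtest_null_inner: int = 8
    ss_rungs: int = 32
    ss_samples: int = 10000
    mle_trees: int = 10           # tree-subsample size for the MLE stage
    mle_starts: int = 5
    top_k: int = 2                # conditioning characters entering stage 3
    root_marginal_draws: int = 100
    out_dir: str | None = None

    def stage_seed(self, stage: int, k: int = 0) -> int:
        return (self.seed * 10007 + stage * 101 + k) % (2**31 - 1)


@dataclass
class CharacterInput:
    """One analyzable character: 1-3 binary gene columns under one name."""

    name: str
    genes: dict                   # gene name -> CharacterMatrix

    def candidate_models(self):
        if len(self.genes) == 1:
            gene = next(iter(self.genes))
            return [CandidateModel(((gene,),), tag) for tag in ("ER", "ARD")]
        return enumerate_pathway_models(tuple(self.genes)).candidates


def _build_chars(ci: CharacterInput, cand: CandidateModel) -> list:
    chars = []
    for block in cand.partition:
        if len(block) == 1:
            data = ci.genes[block[0]]
            model = RateModel.from_tag(cand.tag, StateSpace(data.alphabet),
                                       name=block[0])
        else:
            data = combine_characters([ci.genes[g] for g in block])
            space = StateSpace.product(
                [(g, ci.genes[g].alphabet) for g in block])
            model = RateModel.from_tag(cand.tag, space, name="+".join(block))
        chars.append(MarkovCharacter(model.name, model, data))
    return chars


def _thin_trees(sample: TreeSample, n: int) -> TreeSample:
    if len(sample) <= n:
        return sample
    idx = np.linspace(0, len(sample) - 1, n).astype(int)
    return TreeSample([sample[i] for i in idx])


def _root_posterior(an: Analysis, ps: PosteriorSample, n: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Posterior root-state probabilities over the flattened joint space,
    averaged over a subsample of posterior draws (blocks are independent,
    so the joint root posterior is the Kronecker product of block marginals)."""
    take = rng.integers(len(ps), size=min(n, len(ps)))
    acc = None
    for i in take:
        tree = an.tree_sample[int(ps.tree_indices[i])]
        Qs = an.generators(ps.rates[i])
        joint = np.ones(1)
        for c, Q in zip(an.chars, Qs):
            marg = node_marginals(tree, c.data, Q, c.root.resolve(Q))
            joint = np.kron(joint, marg[tree.root])
        acc = joint if acc is None else acc + joint
    return acc / len(take)


@dataclass
class SingleCharacterResult:
    name: str
    candidates: list
    analyses: list
    mle_rates: list
    logml: np.ndarray
    logml_se: np.ndarray
    posteriors: list
    weights: object
    root_posteriors: list          # per model, flattened joint space
    root_posterior_blended: np.ndarray
    joint_states: tuple
    histories: HistoryCollection | None = None

    def to_json(self) -> dict:
        return {
            "name": self.name,
            "candidates": [c.describe() for c in self.candidates],
            "logml": self.logml.tolist(),
            "logml_se": self.logml_se.tolist(),
            "weights": self.weights.posterior.tolist(),
            "mle_rates": [np.asarray(r).tolist() for r in self.mle_rates],
            "root_posteriors": [r.tolist() for r in self.root_posteriors],
            "root_posterior_blended": self.root_posterior_blended.tolist(),
            "joint_states": [list(s) if isinstance(s, tuple) else s
                             for s in self.joint_states],
            "posteriors": [
                {"tree_indices": p.tree_indices.tolist(),
                 "rates": p.rates.tolist()} for p in self.posteriors],
        }


def single_character_pipeline(ci: CharacterInput, tree_sample: TreeSample,
                              config: PipelineConfig,
                              candidates=None,
                              with_histories: bool = True) -> SingleCharacterResult:
    """Stage-1 analysis of one character across its candidate model space."""
    candidates = list(candidates) if candidates is not None \
        else ci.candidate_models()
    mle_sample = _thin_trees(tree_sample, config.mle_trees)
    analyses, mles, logmls, ses, posteriors = [], [], [], [], []
    for k, cand in enumerate(candidates):
        chars = _build_chars(ci, cand)
        an_mle = Analysis(mle_sample, chars)
        mle = mle_fit(an_mle, None, n_starts=config.mle_starts,
                      seed=config.stage_seed(1, 10 * k))
        priors = empirical_bayes_priors(mle.rates)
        an = Analysis(tree_sample, chars)
        lm, se = stepping_stone_logml(
            an, None, priors, n_rungs=config.ss_rungs,
            samples_per_rung=config.ss_samples,
            seed=config.stage_seed(1, 10 * k + 1))
        ps = mcmc_sample(an, None, priors, n_iter=config.n_mcmc_iter,
                         n_draws=config.n_posterior_draws,
                         seed=config.stage_seed(1, 10 * k + 2),
                         init_rates=mle.rates)
        analyses.append(an)
        mles.append(mle.rates)
        logmls.append(lm)
        ses.append(se)
        posteriors.append(ps)
    weights = model_weights_and_average(
        np.array(logmls), names=[c.describe() for c in candidates])
    rng = np.random.default_rng(config.stage_seed(1, 999))
    roots = [_root_posterior(an, ps, config.root_marginal_draws, rng)
             for an, ps in zip(analyses, posteriors)]
    blended = weights.blend(np.stack(roots))
    from .likelihood_inference import itertools_product_labels
    joint_states = tuple(itertools_product_labels(
        [c.model.space for c in analyses[0].chars]))
    hist = None
    if with_histories:
        hist = history_sampler.sample_histories(
            analyses, posteriors, weights.posterior,
            n_draws=config.n_history_draws,
            seed=config.stage_seed(1, 998))
    return SingleCharacterResult(ci.name, candidates, analyses, mles,
                                 np.array(logmls), np.array(ses), posteriors,
                                 weights, roots, blended, joint_states, hist)


# ---------------------------------------------------------------------------
# Conditioned analysis (stage 3)


@dataclass
class ConditionedResult:
    focal: str
    conditioners: list
    combos: list                   # per combo: {conditioner: CandidateModel}
    weights: np.ndarray
    weight_source: str
    analyses: list
    posteriors: list
    tables: list
    aic_weights: np.ndarray | None
    bic_weights: np.ndarray | None
    histories: HistoryCollection | None
    focal_root_posterior: np.ndarray | None = None

    def to_json(self) -> dict:
        return {
            "focal": self.focal,
            "combos": [{n: c.describe() for n, c in combo.items()}
                       for combo in self.combos],
            "weights": self.weights.tolist(),
            "weight_source": self.weight_source,
            "aic_weights": None if self.aic_weights is None
            else self.aic_weights.tolist(),
            "bic_weights": None if self.bic_weights is None
            else self.bic_weights.tolist(),
            "focal_root_posterior": None if self.focal_root_posterior is None
            else self.focal_root_posterior.tolist(),
        }


def conditioned_pipeline(focal: CharacterInput, conditioners: list,
                         tree_sample: TreeSample, config: PipelineConfig,
                         stage1=None, conditioner_candidates=None,
                         exact_weights: bool = False) -> ConditionedResult:
    """Analyze the focal character conditioned on the given characters.

    ``conditioner_candidates`` maps conditioner name to the candidate models
    to combine (default: the dependent/ARD model for multi-gene characters,
    ER and ARD for binary ones). Bayesian parameter sampling is used when at
    most 2 conditioning Markov characters are involved, maximum likelihood
    otherwise. Combination weights come from exact stepping stone when
    requested (and Bayesian), else from the per-character marginal-likelihood
    differences of ``stage1`` results, renormalized; AIC/BIC weights are
    reported alongside for the ML case.
    """
    focal_name = focal.name
    focal_data = next(iter(focal.genes.values()))
    cand_lists = []
    for ci in conditioners:
        if conditioner_candidates and ci.name in conditioner_candidates:
            cand_lists.append(list(conditioner_candidates[ci.name]))
        elif len(ci.genes) >= 2:
            cand_lists.append([CandidateModel((tuple(ci.genes),), "ARD")])
        else:
            gene = next(iter(ci.genes))
            cand_lists.append([CandidateModel(((gene,),), t)
                               for t in ("ER", "ARD")])

    combos = [dict(zip([c.name for c in conditioners], combo))
              for combo in itertools.product(*cand_lists)]
    n_taxa = len(tree_sample.taxon_labels)
    analyses, posteriors, tables = [], [], []
    logliks, n_params = [], []
    bayesian = None
    for k, combo in enumerate(combos):
        chars = []
        for ci in conditioners:
            chars.extend(_build_chars(ci, combo[ci.name]))
        from .likelihood_inference import itertools_product_labels
        joint = StateSpace(tuple(itertools_product_labels(
            [c.model.space for c in chars])))
        cm = ConditionedModel(joint, focal_data.alphabet)
        an = Analysis(tree_sample, chars, cm, focal_data)
        bayesian = len(chars) <= 2
        mle_an = Analysis(_thin_trees(tree_sample, config.mle_trees),
                          chars, cm, focal_data)
        mle = mle_fit(mle_an, None, n_starts=config.mle_starts,
                      seed=config.stage_seed(3, 10 * k))
        logliks.append(mle.loglik)
        # free parameters: rates + (rows * (focal states - 1))
        n_params.append(an.n_rates +
                        cm.n_rows * (len(cm.focal_alphabet) - 1))
        if bayesian:
            priors = empirical_bayes_priors(mle.rates)
            ps = mcmc_sample(an, None, priors, n_iter=config.n_mcmc_iter,
                             n_draws=config.n_posterior_draws,
                             seed=config.stage_seed(3, 10 * k + 1),
                             init_rates=mle.rates)
        else:
            reps = max(config.n_posterior_draws // 10, 1)
            rng = np.random.default_rng(config.stage_seed(3, 10 * k + 2))
            ps = PosteriorSample(
                rng.integers(len(tree_sample), size=reps),
                np.tile(mle.rates, (reps, 1)),
                np.tile(mle.table, (reps, 1, 1)), an.slices,
                {"kind": "ML plug-in"})
        analyses.append(an)
        posteriors.append(ps)
        tables.append(mle.table)

    aic_w = bic_w = None
    if len(combos) > 1:
        _aic, _bic, aic_w, bic_w = information_criteria(
            np.array(logliks), np.array(n_params, dtype=float), n_taxa)
    if exact_weights and bayesian:
        lms = []
        for k, an in enumerate(analyses):
            priors = empirical_bayes_priors(
                np.maximum(posteriors[k].rates.mean(axis=0), 1e-9))
            lm, _se = stepping_stone_logml(
                an, None, priors, n_rungs=config.ss_rungs,
                samples_per_rung=config.ss_samples,
                seed=config.stage_seed(3, 500 + k))
            lms.append(lm)
        w = np.exp(np.array(lms) - max(lms))
        w /= w.sum()
        source = "stepping-stone"
    elif len(combos) > 1 and stage1 is not None:
        logw = np.zeros(len(combos))
        for k, combo in enumerate(combos):
            for ci in conditioners:
                res = stage1[ci.name]
                names = [c.describe() for c in res.candidates]
                tag_name = combo[ci.name].describe()
                if tag_name in names:
                    logw[k] += res.logml[names.index(tag_name)]
        w = np.exp(logw - logw.max())
        w /= w.sum()
        source = "per-character marginal-likelihood approximation"
    else:
        w = np.full(len(combos), 1.0 / len(combos))
        source = "uniform (single combination)" if len(combos) == 1 else "uniform"

    hist = history_sampler.sample_histories(
        analyses, posteriors, w, n_draws=config.n_history_draws,
        seed=config.stage_seed(3, 997))
    prof = posterior_summaries.state_probability_profiles(hist, focal_name)
    root_clade = tree_sample[0].clades()[tree_sample[0].root]
    falpha = tuple(focal_data.alphabet)
    fr = np.array([
        prof.node_probs[root_clade][prof.states.index(s)]
        if s in prof.states else 0.0 for s in falpha])
    return ConditionedResult(focal_name, [c.name for c in conditioners],
                             combos, w, source, analyses, posteriors, tables,
                             aic_w, bic_w, hist, fr)


# ---------------------------------------------------------------------------
# D-test stage


def paired_collections(result_a, result_b, tree_sample: TreeSample,
                       n_draws: int, seed: int, n_null: int | None = None,
                       null_inner: int = 8):
    """Paired (observed, null) collections for a D-test of two characters.

    Each draw uses one shared tree index for both characters so dwell times
    are computed on a common tree. Observed draws map both characters
    conditioned on their tips. Each null replicate simulates a null dataset
    (both characters evolving independently under a posterior parameter
    draw), then re-maps it conditioned on its own simulated tips
    ``null_inner`` times; the returned group labels average those inner maps
    into one deviation per replicate, mirroring the averaged observed
    statistic.
    """
    rng = np.random.default_rng(seed)
    n_null = n_draws if n_null is None else n_null
    obs = HistoryCollection(tree_sample)
    null = HistoryCollection(tree_sample)
    groups = []

    def _draw_model(res):
        m = int(rng.choice(len(res.weights.posterior),
                           p=res.weights.posterior))
        ps = res.posteriors[m]
        i = int(rng.integers(len(ps)))
        return res.analyses[m], ps.rates[i]

    def _map_char(res, an, Qs, tree, data_by_char, out):
        for c, Q in zip(an.chars, Qs):
            pi = c.root.resolve(Q)
            out[c.name] = history_sampler.sample_markov_history(
                tree, data_by_char[c.name], Q, pi, rng, character=c.name)
        if len(an.chars) > 1:
            out[res.name] = _merge_block_histories(
                [out[c.name] for c in an.chars], res.name)
        else:
            out[res.name] = out[an.chars[0].name]

    for _d in range(n_draws):
        ti = int(rng.integers(len(tree_sample)))
        tree = tree_sample[ti]
        od: dict = {}
        for res in (result_a, result_b):
            an, rates = _draw_model(res)
            _map_char(res, an, an.generators(rates), tree,
                      {c.name: c.data for c in an.chars}, od)
        obs.tree_indices.append(ti)
        obs.histories.append(od)

    for r in range(n_null):
        ti = int(rng.integers(len(tree_sample)))
        tree = tree_sample[ti]
        sims = []
        for res in (result_a, result_b):
            an, rates = _draw_model(res)
            Qs = an.generators(rates)
            simdata = {}
            for c, Q in zip(an.chars, Qs):
                pi = c.root.resolve(Q)
                h = simulate_unconditioned(tree, Q, pi, rng,
                                           labels=c.data.alphabet,
                                           character=c.name)
                simdata[c.name] = CharacterMatrix(
                    c.name, c.data.alphabet,
                    {tree.labels[v]: frozenset([h.node_state(v)])
                     for v in tree.tip_indices})
            sims.append((res, an, Qs, simdata))
        for _k in range(null_inner):
            nd: dict = {}
            for res, an, Qs, simdata in sims:
                _map_char(res, an, Qs, tree, simdata, nd)
            null.tree_indices.append(ti)
            null.histories.append(nd)
            groups.append(r)
    return obs, null, groups


def _merge_block_histories(hists, name):
    """Combine block histories of one character into a joint-state history."""
    from .likelihood_inference import _joint_label
    tree = hists[0].tree
    segments = [[] for _ in range(tree.n_nodes)]
    for v in range(tree.n_nodes):
        if v == tree.root:
            continue
        cuts = sorted({e for h in hists for seg in h.segments[v]
                       for e in (seg[0], seg[1])}, reverse=True)
        out = []
        for a, b in zip(cuts[:-1], cuts[1:]):
            mid = 0.5 * (a + b)
            lab = _joint_label(tuple(h.state_at(v, mid) for h in hists), None)
            if out and out[-1][2] == lab:
                out[-1] = (out[-1][0], b, lab)
            else:
                out.append((a, b, lab))
        segments[v] = out
    root = _joint_label(tuple(h.root_state for h in hists), None)
    from .phylo_io import MappedHistory
    return MappedHistory(tree, name, segments, root, validate=False)


# ---------------------------------------------------------------------------
# Full workflow


def full_workflow(tree_sample: TreeSample, characters: list,
                  focal: CharacterInput, config: PipelineConfig,
                  resume: bool = False) -> dict:
    """Run the whole pipeline and return a machine-readable report.

    ``characters`` are the candidate conditioning characters (CharacterInput,
    each 1-3 binary genes); ``focal`` is the single-gene focal character.
    With ``config.out_dir`` set, stages checkpoint JSON fragments and the
    final report + history TSVs are written there; ``resume=True`` skips
    stages whose checkpoints exist.
    """
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    def load(stage):
        if out is None or not resume:
            return None
        p = out / f"stage{stage}.json"
        return json.loads(p.read_text()) if p.exists() else None

    def save(stage, payload):
        if out is not None:
            (out / f"stage{stage}.json").write_text(
                json.dumps(payload, indent=1))

    report: dict = {"seed": config.seed}

    # stage 1: per-character independent analyses (focal first)
    stage1: dict = {}
    s1_json = load(1)
    if s1_json is not None:
        for ci in [focal] + list(characters):
            stage1[ci.name] = _rebuild_single(ci, tree_sample,
                                              s1_json[ci.name])
    else:
        for ci in [focal] + list(characters):
            stage1[ci.name] = single_character_pipeline(
                ci, tree_sample, config, with_histories=False)
        s1_json = {name: res.to_json() for name, res in stage1.items()}
        save(1, s1_json)
    report["stage1"] = {k: {kk: vv for kk, vv in v.items()
                            if kk != "posteriors"}
                        for k, v in s1_json.items()}

    # stage 2: D-tests against the focal character, ranked by significance
    s2_json = load(2)
    if s2_json is None:
        dtest_frames = {}
        dtests = {}
        for k, ci in enumerate(characters):
            obs, null, groups = paired_collections(
                stage1[ci.name], stage1[focal.name], tree_sample,
                config.n_dtest_draws, config.stage_seed(2, k),
                n_null=config.n_dtest_null, null_inner=config.dtest_null_inner)
            res = stage1[ci.name]
            dtests[ci.name] = d_test(obs, null, ci.name, focal.name,
                                     res.joint_states,
                                     stage1[focal.name].joint_states,
                                     null_groups=groups)
            dtest_frames[ci.name] = dtests[ci.name].summary_frame()
        ranking = sorted(dtests, key=lambda n: (dtests[n].P, -dtests[n].D))
        s2_json = {
            "ranking": ranking,
            "dtests": {n: {"D_percent": dtests[n].D, "P": dtests[n].P,
                           "d_percent": dtests[n].d.tolist(),
                           "P_matrix": dtests[n].P_matrix.tolist()}
                       for n in dtests}}
        save(2, s2_json)
        if out:
            for n, f in dtest_frames.items():
                f.to_csv(out / f"dtest_{n}.tsv", sep="\t", index=False)
    ranking = s2_json["ranking"]
    report["stage2"] = s2_json

    # stage 3: conditioned analysis on the top-ranked characters
    top = [ci for name in ranking[:config.top_k]
           for ci in characters if ci.name == name]
    cond = conditioned_pipeline(focal, top, tree_sample, config,
                                stage1=stage1)
    report["stage3"] = cond.to_json()
    save(3, report["stage3"])

    # stage 4: summaries of the final conditioned history collection
    hist = cond.histories
    falpha = tuple(next(iter(focal.genes.values())).alphabet)
    prof = posterior_summaries.state_probability_profiles(hist, focal.name)
    first = {}
    for s in falpha:
        ev = posterior_summaries.first_occurrence_ages(
            hist, focal.name, lambda x, s=s: x == s)
        first[str(s)] = ev.summary()
    root_age = float(np.mean([t.root_age for t in tree_sample.trees]))
    edges = np.arange(0.0, root_age + 100.0, 100.0)
    ttt = {}
    for a, b in itertools.permutations(falpha, 2):
        r = posterior_summaries.transitions_through_time(
            hist, focal.name, (a, b), edges)
        ttt[f"{a}->{b}"] = np.where(np.isnan(r.rates), None, r.rates).tolist()
    report["stage4"] = {
        "focal_root_posterior": dict(zip(
            map(str, falpha),
            (cond.focal_root_posterior.tolist()
             if cond.focal_root_posterior is not None else []))),
        "first_occurrence": first,
        "transitions_through_time_bins_ma": edges.tolist(),
        "transitions_through_time": ttt,
    }
    if out:
        (out / "report.json").write_text(json.dumps(report, indent=1))
        prof.node_frame().to_csv(out / "node_posteriors.tsv", sep="\t",
                                 index=False)
        prof.branch_frame().to_csv(out / "branch_posteriors.tsv", sep="\t",
                                   index=False)
        write_histories(hist, out / "histories.tsv")
    return report


def _rebuild_single(ci: CharacterInput, tree_sample: TreeSample,
                    payload: dict) -> SingleCharacterResult:
    """Reconstruct a stage-1 result from its JSON checkpoint."""
    candidates = ci.candidate_models()
    if [c.describe() for c in candidates] != payload["candidates"]:
        raise ValueError(
            f"checkpoint for {ci.name} does not match the current inputs")
    analyses = [Analysis(tree_sample, _build_chars(ci, c)) for c in candidates]
    posteriors = []
    for p, an in zip(payload["posteriors"], analyses):
        posteriors.append(PosteriorSample(
            np.asarray(p["tree_indices"], dtype=int),
            np.asarray(p["rates"], dtype=float), None, an.slices,
            {"kind": "checkpoint"}))
    logml = np.asarray(payload["logml"], dtype=float)
    weights = model_weights_and_average(logml, names=payload["candidates"])
    roots = [np.asarray(r) for r in payload["root_posteriors"]]
    joint_states = tuple(tuple(s) if isinstance(s, list) else s
                         for s in payload["joint_states"])
    return SingleCharacterResult(
        ci.name, candidates, analyses,
        [np.asarray(r) for r in payload["mle_rates"]], logml,
        np.asarray(payload["logml_se"]), posteriors, weights, roots,
        np.asarray(payload["root_posterior_blended"]), joint_states)
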