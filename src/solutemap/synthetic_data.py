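"""Synthetic dated-tree samples and character data with known ground truth.

The generator emulates the shape of a deep-time bacterial trait study: a
single birth-death topology scaled to an Archean root age (~3200 Ma), a
sample of replicate trees obtained by log-normally jittering internal node
ages (standing in for molecular-clock dating uncertainty), binary gene
presence/absence characters evolved under known ER/ARD/SYM rates (around
1e-3 per Myr, so a tree carries tens of transitions), optional dependent
multi-gene supercharacters, and a focal habitat-preference character drawn
from a known conditional probability table over the gene states.

Both the tip data and the generating (true) histories are returned, so the
true histories can serve as oracles for summary operations.
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from . import history_sampler, phylo_io
from .likelihood_inference import RootPrior, _joint_label
from .phylo_io import CharacterMatrix, DatedTree, TreeSample
from .trait_models import PRESENT, ABSENT, RateModel, StateSpace

__all__ = [
    "CharacterSpec",
    "FocalSpec",
    "SimulationScenario",
    "simulate_tree_sample",
    "simulate_characters",
    "benchmark_dataset",
    "PRESETS",
]


@dataclass
class CharacterSpec:
    """True model of one Markov character (possibly a multi-gene block).

    ``genes``: one name for a plain binary character, several for a
    supercharacter over the product space (``dependent`` selects whether the
    block evolves under a joint ``tag`` model or whether *rates* holds the
    concatenated per-gene rates of independent binary models — for
    simulation both are just a generator on the product space).
    """

    name: str
    genes: tuple
    tag: str = "ER"
    rates: tuple = (1e-3,)
    dependent: bool = False
    alphabet: tuple = (ABSENT, PRESENT)   # single-gene characters only

    def model(self) -> RateModel:
        if len(self.genes) == 1:
            space = StateSpace(tuple(self.alphabet))
            return RateModel.from_tag(self.tag, space, np.asarray(self.rates),
                                      name=self.name)
        if self.dependent:
            space = StateSpace.product([(g, (ABSENT, PRESENT))
                                        for g in self.genes])
            return RateModel.from_tag(self.tag, space, np.asarray(self.rates),
                                      name=self.name)
        from .trait_models import build_product_model
        comps = []
        k = 0
        for g in self.genes:
            m = RateModel.from_tag(self.tag, StateSpace.binary(), name=g)
            comps.append(m.with_rates(np.asarray(self.rates[k:k + m.n_free])))
            k += m.n_free
        return build_product_model(comps, dependent=False, name=self.name)


@dataclass
class FocalSpec:
    """A conditioned focal character: pi(focal | joint conditioning state).

    ``table`` rows follow the flattened product of the conditioning
    characters' state spaces in ``conditioning`` order.
    """

    name: str
    alphabet: tuple
    conditioning: tuple            # names of conditioning CharacterSpecs
    table: tuple                   # rows x focal states, rows sum to 1


@dataclass
class SimulationScenario:
    """Everything needed to generate one synthetic dataset."""

    n_taxa: int = 50
    root_age: float = 3200.0       # Ma
    birth_rate: float = 1.0
    death_rate: float = 0.3
    age_jitter_sd: float = 0.05    # log-units on internal node ages
    n_trees: int = 10
    characters: list = field(default_factory=list)   # CharacterSpec
    focal: FocalSpec | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 4:
            raise ValueError("need at least 4 taxa")
        if min(self.birth_rate, self.death_rate, self.age_jitter_sd) < 0:
            raise ValueError("rates and jitter must be non-negative")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, default=list)

    @classmethod
    def from_json(cls, text: str) -> "SimulationScenario":
        d = json.loads(text)
        d["characters"] = [CharacterSpec(**{**c, "genes": tuple(c["genes"]),
                                            "rates": tuple(c["rates"]),
                                            "alphabet": tuple(c["alphabet"])})
                           for c in d["characters"]]
        if d.get("focal"):
            f = d["focal"]
            d["focal"] = FocalSpec(f["name"], tuple(f["alphabet"]),
                                   tuple(f["conditioning"]),
                                   tuple(tuple(r) for r in f["table"]))
        return cls(**d)


# ---------------------------------------------------------------------------
# Trees


def simulate_tree_sample(scenario: SimulationScenario,
                         max_retries: int = 1000) -> TreeSample:
    """One birth-death topology, rescaled to the root age, replicated with
    log-normal node-age jitter that preserves parent > child ordering."""
    rng = np.random.default_rng(scenario.seed)
    py_rng = random.Random(int(rng.integers(2**31 - 1)))
    dtree = dendropy.model.birthdeath.birth_death_tree(
        birth_rate=scenario.birth_rate, death_rate=scenario.death_rate,
        num_extant_tips=scenario.n_taxa, rng=py_rng,
        is_retain_extinct_tips=False)
    base = DatedTree.from_dendropy(dtree, repair=True)
    scale = scenario.root_age / base.root_age
    base = DatedTree(base.parent, base.ages * scale, base.labels)

    trees = []
    sd = scenario.age_jitter_sd
    for _k in range(scenario.n_trees):
        ages = base.ages.copy()
        if sd > 0 and _k > 0:   # tree 0 is the unjittered base (truth) tree
            for v in base.preorder:
                if base.is_tip[v]:
                    continue
                upper = ages[base.parent[v]] if base.parent[v] >= 0 else np.inf
                for attempt in range(max_retries + 1):
                    prop = base.ages[v] * np.exp(sd * rng.normal())
                    if prop < upper:
                        ages[v] = prop
                        break
                else:
                    raise RuntimeError(
                        f"node-age jitter failed to respect ordering at node {v}")
        trees.append(DatedTree(base.parent, ages, base.labels))
    return TreeSample(trees)


# ---------------------------------------------------------------------------
# Characters


def _tips_from_history(h, tree: DatedTree, name: str, alphabet) -> CharacterMatrix:
    states = {tree.labels[v]: frozenset([h.node_state(v)])
              for v in tree.tip_indices}
    return CharacterMatrix(name, alphabet, states)


def simulate_characters(tree: DatedTree, scenario: SimulationScenario,
                        rng: np.random.Generator | None = None):
    """Forward-simulate all characters of a scenario on one dated tree.

    Returns ``(matrices, histories)``: per-character tip data and the true
    generating histories (keyed by character name). Markov characters are
    simulated from a uniform root state; the focal character is drawn from
    the true conditional probability table over the simulated conditioning
    histories (unclamped, since there are no observations to respect).
    """
    rng = np.random.default_rng(scenario.seed + 1) if rng is None else rng
    matrices, histories = {}, {}
    models = {}
    for spec in scenario.characters:
        m = spec.model()
        models[spec.name] = m
        Q = m.Q
        pi = RootPrior("uniform").resolve(Q)
        h = history_sampler.simulate_unconditioned(
            tree, Q, pi, rng, labels=m.space.labels, character=spec.name)
        histories[spec.name] = h
        matrices[spec.name] = _tips_from_history(h, tree, spec.name,
                                                 m.space.labels)
    if scenario.focal is not None:
        f = scenario.focal
        cond_hists = [histories[c] for c in f.conditioning]
        cond_spaces = [models[c].space for c in f.conditioning]
        joint = StateSpace(
            tuple(_joint_label(c, cond_spaces)
                  for c in _product_labels(cond_spaces)))
        from .likelihood_inference import ConditionedModel
        cm = ConditionedModel(joint, f.alphabet, np.asarray(f.table, float))
        h = history_sampler.overlay_conditioned(
            cond_hists, cm, None, rng, character=f.name, clamp_tips=False)
        histories[f.name] = h
        matrices[f.name] = _tips_from_history(h, tree, f.name, f.alphabet)
    return matrices, histories


def _product_labels(spaces):
    import itertools
    return itertools.product(*[s.labels for s in spaces])


# ---------------------------------------------------------------------------
# Presets


def _gg_like_table():
    # habitat H strongly tied to a complete 2-gene pathway (state PP),
    # indifferent for partial pathways; rows over product states
    # AA, AP, PA, PP; columns (L, H)
    return ((0.95, 0.05),
            (0.5, 0.5),
            (0.5, 0.5),
            (0.05, 0.95))


def _preset_tiny(seed: int) -> SimulationScenario:
    return SimulationScenario(
        n_taxa=8, n_trees=3, age_jitter_sd=0.03, seed=seed,
        characters=[CharacterSpec("habitat", ("habitat",), "ER", (3e-4,),
                                  alphabet=("L", "H"))])


def _preset_small(seed: int) -> SimulationScenario:
    chars = [
        CharacterSpec("habitat", ("habitat",), "ER", (1.5e-3,),
                      alphabet=("L", "H")),
        CharacterSpec("GG", ("ggpS", "ggpP"), "ARD",
                      tuple(np.full(12, 8e-4)), dependent=True),
        CharacterSpec("GGA", ("ggaA",), "ARD", (5e-4, 2e-3)),
        CharacterSpec("Tre", ("treY",), "ER", (1e-3,)),
    ]
    focal = FocalSpec("habitat_pref", ("L", "H"), ("GG",), _gg_like_table())
    return SimulationScenario(n_taxa=50, n_trees=10, age_jitter_sd=0.05,
                              seed=seed, characters=chars, focal=focal)


def _preset_study_scale(seed: int) -> SimulationScenario:
    # mirrors the study's structure: five solute pathways + habitat on a
    # 189-taxon, 1000-tree sample rooted ~3200 Ma
    chars = [
        CharacterSpec("GG", ("ggpS", "ggpP"), "ARD",
                      tuple(np.full(12, 8e-4)), dependent=True),
        CharacterSpec("GGA", ("gsmT",), "ARD", (5e-4, 2e-3)),
        CharacterSpec("GB", ("dmt",), "ARD", (3e-4, 2e-3)),
        CharacterSpec("Tre", ("treY", "treZ"), "ER",
                      (1e-3, 1e-3), dependent=False),
        CharacterSpec("Suc", ("spsA", "spp", "spsA*"), "ER",
                      tuple(np.full(1, 1e-3)), dependent=True),
    ]
    # habitat favors high salinity when GG complete or GGA present
    rows = []
    gg_space = StateSpace.product([("ggpS", (ABSENT, PRESENT)),
                                   ("ggpP", (ABSENT, PRESENT))])
    for gg in gg_space.labels:
        for gga in (ABSENT, PRESENT):
            p_high = 0.15
            if gg == (PRESENT, PRESENT):
                p_high += 0.6
            if gga == PRESENT:
                p_high += 0.2
            rows.append((1 - p_high, p_high))
    focal = FocalSpec("habitat", ("L", "H"), ("GG", "GGA"), tuple(rows))
    return SimulationScenario(n_taxa=189, n_trees=1000, age_jitter_sd=0.05,
                              seed=seed, characters=chars, focal=focal)


PRESETS = {"tiny": _preset_tiny, "small": _preset_small,
           "study-scale": _preset_study_scale}


@dataclass
class BenchmarkBundle:
    scenario: SimulationScenario
    tree_sample: TreeSample
    matrices: dict
    histories: dict


def benchmark_dataset(preset: str, seed: int = 0,
                      out_dir=None) -> BenchmarkBundle:
    """Generate a named preset; optionally write newick + TSV + truth JSON."""
    try:
        scenario = PRESETS[preset](seed)
    except KeyError:
        raise ValueError(
            f"unknown preset {preset!r}; available: {sorted(PRESETS)}")
    sample = simulate_tree_sample(scenario)
    matrices, histories = simulate_characters(sample[0], scenario)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        phylo_io.write_tree_sample(sample, out / "trees.nwk")
        flat = []
        for m in matrices.values():
            if isinstance(m.alphabet[0], tuple):
                # write product supercharacters gene-by-gene
                flat.extend(_split_product(m))
            else:
                flat.append(m)
        phylo_io.write_character_table(flat, out / "characters.tsv")
        (out / "truth.json").write_text(scenario.to_json())
    return BenchmarkBundle(scenario, sample, matrices, histories)


def _split_product(m: CharacterMatrix) -> list:
    k = len(m.alphabet[0])
    names = [f"{m.name}.g{i}" for i in range(k)]
    out = []
    for i in range(k):
        states = {t: frozenset(s[i] for s in obs)
                  for t, obs in m.states.items()}
        out.append(CharacterMatrix(names[i], (ABSENT, PRESENT), states))
    return out
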