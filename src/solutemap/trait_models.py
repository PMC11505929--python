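"""Discrete-state spaces, CTMC rate-matrix parameterizations and pathway coding.

A trait evolves on a dated tree under a continuous-time Markov chain with
generator Q (off-diagonal entries are transition rates per Myr, rows sum to
zero). Four parameterizations are supported for the mapping from free
parameters to Q: unidirectional (UNI, one nonzero rate), equal-rates (ER, a
single shared rate), symmetrical (SYM, one rate per unordered state pair) and
all-rates-different (ARD, one rate per ordered pair); free-parameter counts
are 1, (s^2-s)/2 and s^2-s for ER/SYM/ARD on s states.

Several genes of one biosynthetic pathway can be merged into a single
"supercharacter" on the product state space. In the independent case the
generator is the Kronecker sum of the per-gene generators (simultaneous
changes have rate 0); in the dependent case Q is parameterized directly over
the product space, so simultaneous gains/losses are allowed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .phylo_io import CharacterMatrix

__all__ = [
    "StateSpace",
    "RateModel",
    "PathwayDefinition",
    "CandidateModel",
    "ModelSpace",
    "build_rate_matrix",
    "build_product_model",
    "enumerate_pathway_models",
    "classify_pathway_state",
    "binarize_gene_presence",
    "combine_characters",
    "rate_classes",
]

PRESENT = "P"
ABSENT = "A"


@dataclass(frozen=True)
class StateSpace:
    """An ordered set of state labels, optionally a product of components.

    Product spaces list tuples over the component alphabets in declared
    component order, lexicographically ordered by component index.
    """

    labels: tuple
    components: tuple = ()   # per component: (name, alphabet tuple)

    def __post_init__(self):
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate state labels")

    @property
    def size(self) -> int:
        return len(self.labels)

    def index(self, label) -> int:
        return self.labels.index(label)

    @classmethod
    def binary(cls, low=ABSENT, high=PRESENT) -> "StateSpace":
        return cls((low, high))

    @classmethod
    def product(cls, components) -> "StateSpace":
        """Product space from [(name, alphabet), ...] in declared order."""
        components = tuple((str(n), tuple(a)) for n, a in components)
        labels = tuple(itertools.product(*[a for _n, a in components]))
        return cls(labels, components)

    def label_str(self, label) -> str:
        return "".join(label) if isinstance(label, tuple) else str(label)


@dataclass
class RateModel:
    """A rate-matrix parameterization: state space + constraint map + rates.

    ``classes`` is an s-by-s integer matrix assigning each off-diagonal cell
    to a free-parameter index, or -1 for structurally-zero cells; diagonal
    entries are -1. ``rates`` holds the free parameters (per Myr).
    """

    space: StateSpace
    tag: str
    classes: np.ndarray
    rates: np.ndarray | None = None
    name: str = ""

    def __post_init__(self):
        self.classes = np.asarray(self.classes, dtype=np.int64)
        s = self.space.size
        if self.classes.shape != (s, s):
            raise ValueError("constraint map shape mismatch")
        if self.rates is not None:
            self.rates = np.asarray(self.rates, dtype=float)
            if len(self.rates) != self.n_free:
                raise ValueError(
                    f"expected {self.n_free} rates, got {len(self.rates)}")

    @property
    def n_free(self) -> int:
        m = self.classes.max()
        return int(m) + 1

    def with_rates(self, rates) -> "RateModel":
        return RateModel(self.space, self.tag, self.classes,
                         np.asarray(rates, dtype=float), self.name)

    @property
    def Q(self) -> np.ndarray:
        return build_rate_matrix(self)

    # -- constructors -------------------------------------------------------

    @classmethod
    def er(cls, space: StateSpace, rate=None, name="") -> "RateModel":
        s = space.size
        classes = np.zeros((s, s), dtype=np.int64)
        np.fill_diagonal(classes, -1)
        rates = None if rate is None else np.array([float(rate)])
        return cls(space, "ER", classes, rates, name)

    @classmethod
    def sym(cls, space: StateSpace, rates=None, name="") -> "RateModel":
        s = space.size
        classes = np.full((s, s), -1, dtype=np.int64)
        k = 0
        for i in range(s):
            for j in range(i + 1, s):
                classes[i, j] = classes[j, i] = k
                k += 1
        return cls(space, "SYM", classes, rates, name)

    @classmethod
    def ard(cls, space: StateSpace, rates=None, name="") -> "RateModel":
        s = space.size
        classes = np.full((s, s), -1, dtype=np.int64)
        k = 0
        for i in range(s):
            for j in range(s):
                if i != j:
                    classes[i, j] = k
                    k += 1
        return cls(space, "ARD", classes, rates, name)

    @classmethod
    def uni(cls, space: StateSpace, source, target, rate=None, name="") -> "RateModel":
        """Unidirectional model: a single nonzero rate source -> target."""
        s = space.size
        classes = np.full((s, s), -1, dtype=np.int64)
        classes[space.index(source), space.index(target)] = 0
        rates = None if rate is None else np.array([float(rate)])
        return cls(space, f"UNI({space.label_str(source)}->{space.label_str(target)})",
                   classes, rates, name)

    @classmethod
    def from_tag(cls, tag: str, space: StateSpace, rates=None, name="") -> "RateModel":
        tag = tag.upper()
        if tag == "ER":
            return cls.er(space, None if rates is None else rates[0], name)
        if tag == "SYM":
            return cls.sym(space, rates, name)
        if tag == "ARD":
            return cls.ard(space, rates, name)
        raise ValueError(f"unknown parameterization tag {tag!r}")


def build_rate_matrix(model: RateModel) -> np.ndarray:
    """Fill the generator matrix Q from the model's free parameters."""
    if model.rates is None:
        raise ValueError("model has no rates set")
    if np.any(model.rates < 0):
        raise ValueError("negative rate parameter")
    s = model.space.size
    Q = np.zeros((s, s))
    mask = model.classes >= 0
    Q[mask] = model.rates[model.classes[mask]]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def build_product_model(components: list, dependent: bool = False,
                        tag: str = "ARD", name: str = "") -> RateModel:
    """Merge component models into one supercharacter model.

    Independent mode: the generator is the Kronecker sum of the component
    generators — only single-component changes have nonzero rate, equal to
    the component rate, and the free parameters are the concatenated
    component parameters. Dependent mode: a fresh ER/SYM/ARD
    parameterization over the full product space (``tag``), including
    simultaneous-change cells.
    """
    if len(components) < 2:
        raise ValueError("need at least 2 component models")
    comp_spaces = []
    for k, m in enumerate(components):
        cname = m.name or f"c{k}"
        comp_spaces.append((cname, m.space.labels))
    space = StateSpace.product(comp_spaces)
    if dependent:
        return RateModel.from_tag(tag, space, name=name)

    sizes = [m.space.size for m in components]
    offsets = np.cumsum([0] + [m.n_free for m in components])
    s = space.size
    classes = np.full((s, s), -1, dtype=np.int64)
    idx = list(itertools.product(*[range(n) for n in sizes]))
    for a, ia in enumerate(idx):
        for b, ib in enumerate(idx):
            diff = [k for k in range(len(sizes)) if ia[k] != ib[k]]
            if len(diff) != 1:
                continue
            k = diff[0]
            c = components[k].classes[ia[k], ib[k]]
            if c >= 0:
                classes[a, b] = offsets[k] + c
    rates = None
    if all(m.rates is not None for m in components):
        rates = np.concatenate([m.rates for m in components])
    model = RateModel(space, "INDEP(" + "+".join(m.tag for m in components) + ")",
                      classes, rates, name)
    return model


# ---------------------------------------------------------------------------
# Pathways


def _predicate_all(presence: tuple) -> bool:
    return all(p == PRESENT for p in presence)


def _predicate_any(presence: tuple) -> bool:
    return any(p == PRESENT for p in presence)


def _predicate_suc(presence: tuple) -> bool:
    # gene order (spsA, spp, spsA*): functional if spsA present, or
    # spp present together with spsA*
    spsA, spp, spsA_star = presence
    return spsA == PRESENT or (spp == PRESENT and spsA_star == PRESENT)


_PREDICATES = {"all_present": _predicate_all, "any_present": _predicate_any,
               "suc_rule": _predicate_suc}


@dataclass(frozen=True)
class PathwayDefinition:
    """A biosynthetic pathway: ordered gene list + functional-state predicate.

    The predicate says which gene presence/absence combinations constitute a
    complete (functional) pathway; it may be a keyword (``all_present``,
    ``any_present``, ``suc_rule``) or a callable over presence tuples.
    """

    name: str
    genes: tuple
    predicate: object = "all_present"

    def __post_init__(self):
        object.__setattr__(self, "genes", tuple(self.genes))

    def functional(self, presence: tuple) -> bool:
        pred = self.predicate
        if isinstance(pred, str):
            try:
                pred = _PREDICATES[pred]
            except KeyError:
                raise ValueError(f"unknown predicate keyword {self.predicate!r}")
        return bool(pred(tuple(presence)))


def classify_pathway_state(presence, pathway: PathwayDefinition) -> str:
    """Classify a per-gene presence tuple as functional/incomplete/absent."""
    presence = tuple(presence)
    if len(presence) != len(pathway.genes):
        raise ValueError("presence tuple length != gene count")
    if pathway.functional(presence):
        return "functional"
    if all(p == ABSENT for p in presence):
        return "absent"
    return "incomplete"


def binarize_gene_presence(genes: list, name: str = "") -> CharacterMatrix:
    """Collapse per-gene presence characters to one present/absent character.

    A strain is scored present if at least one pathway gene is present.
    Ambiguity propagates: if presence cannot be decided from the observed
    sets, both states are retained.
    """
    taxa = genes[0].taxa
    for g in genes[1:]:
        if g.taxa != taxa:
            raise ValueError(f"taxon mismatch between {genes[0].name} and {g.name}")
    states = {}
    for taxon in taxa:
        possible = set()
        for combo in itertools.product(*[sorted(g.states[taxon]) for g in genes]):
            possible.add(PRESENT if any(c == PRESENT for c in combo) else ABSENT)
        states[taxon] = frozenset(possible)
    return CharacterMatrix(name or "+".join(g.name for g in genes),
                           (ABSENT, PRESENT), states)


def combine_characters(genes: list, space: StateSpace | None = None,
                       name: str = "") -> CharacterMatrix:
    """Merge per-gene characters into a supercharacter over the product space."""
    if space is None:
        space = StateSpace.product([(g.name, g.alphabet) for g in genes])
    taxa = genes[0].taxa
    states = {}
    for taxon in taxa:
        states[taxon] = frozenset(
            itertools.product(*[[s for s in g.alphabet if s in g.states[taxon]]
                                for g in genes]))
    return CharacterMatrix(name or "+".join(g.name for g in genes),
                           space.labels, states)


# ---------------------------------------------------------------------------
# Model-space enumeration


@dataclass(frozen=True)
class CandidateModel:
    """One candidate: a dependency partition of the genes + a shared tag."""

    partition: tuple   # tuple of tuples of gene names (dependency blocks)
    tag: str

    def describe(self) -> str:
        blocks = ["(" + "+".join(b) + ")" for b in self.partition]
        return f"{'/'.join(blocks)}:{self.tag}"


@dataclass
class ModelSpace:
    genes: tuple
    candidates: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.candidates)


def _partitions(items: tuple):
    """All set partitions of ``items`` (order of blocks canonicalized)."""
    if len(items) == 1:
        yield (items,)
        return
    first, rest = items[0], items[1:]
    for part in _partitions(rest):
        yield ((first,),) + part
        for k in range(len(part)):
            yield part[:k] + (((first,) + part[k]),) + part[k + 1:]


def enumerate_pathway_models(genes) -> ModelSpace:
    """Enumerate dependency-partition x parameterization candidates.

    For each set partition of the genes into independent blocks, the same
    parameterization tag is applied uniformly across all blocks; ER and ARD
    are always offered, SYM only when some block has more than 2 states
    (i.e. contains >=2 binary genes). This yields 5 candidates for a 2-gene
    pathway and 14 for a 3-gene pathway.
    """
    genes = tuple(genes)
    if not 2 <= len(genes) <= 3:
        raise ValueError("pathway model enumeration supports 2 or 3 genes")
    space = ModelSpace(genes)
    for part in _partitions(genes):
        tags = ["ER", "ARD"]
        if any(len(block) >= 2 for block in part):
            tags = ["ER", "SYM", "ARD"]
        for tag in tags:
            space.candidates.append(CandidateModel(part, tag))
    return space


# ---------------------------------------------------------------------------
# Gain / loss / exchange rate classes


def rate_classes(space: StateSpace, pathway: PathwayDefinition | None = None,
                 mode: str | None = None) -> dict:
    """Cell sets for the summed gain (G), loss (L) and exchange (E) rates.

    Binary present/absent character: G = A->P, L = P->A, no E class.
    Product spaces, ``mode="endpoint"`` (default for 2 genes): G = all-absent
    to any state with >=1 gene, L = all-present to any state with >=1 loss,
    E = transitions between incomplete states. ``mode="functional"``
    (default for >=3 genes; needs the pathway predicate): G = non-functional
    -> functional, L = functional -> non-functional, E = remaining cells.
    """
    labels = space.labels
    s = space.size
    if not space.components:
        if set(labels) != {ABSENT, PRESENT}:
            raise ValueError("binary rate classes need a present/absent alphabet")
        a, p = space.index(ABSENT), space.index(PRESENT)
        return {"G": [(a, p)], "L": [(p, a)], "E": []}

    ngenes = len(space.components)
    if mode is None:
        mode = "endpoint" if ngenes == 2 else "functional"
    out = {"G": [], "L": [], "E": []}
    if mode == "endpoint":
        all_absent = tuple([ABSENT] * ngenes)
        all_present = tuple([PRESENT] * ngenes)
        ia, ip = labels.index(all_absent), labels.index(all_present)
        for j, lab in enumerate(labels):
            if j != ia:
                out["G"].append((ia, j))
            if j != ip:
                out["L"].append((ip, j))
        for i, li in enumerate(labels):
            for j, lj in enumerate(labels):
                if i == j or i in (ia, ip) or j in (ia, ip):
                    continue
                out["E"].append((i, j))
    elif mode == "functional":
        if pathway is None:
            raise ValueError("functional mode requires a PathwayDefinition")
        func = [pathway.functional(lab) for lab in labels]
        for i in range(s):
            for j in range(s):
                if i == j:
                    continue
                if not func[i] and func[j]:
                    out["G"].append((i, j))
                elif func[i] and not func[j]:
                    out["L"].append((i, j))
                else:
                    out["E"].append((i, j))
    else:
        raise ValueError(f"unknown rate-class mode {mode!r}")
    return out
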