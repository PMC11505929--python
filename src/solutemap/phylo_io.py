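"""Dated trees, character tables and mapped histories: containers and file I/O.

Trees are rooted and dated: every node carries an age in Ma before present
(root oldest, tips at 0), and branch lengths are age differences in Myr.
Newick parsing and writing are delegated to dendropy; internally a tree is an
array-based structure (parent pointers, ages, traversal orders) suited to
repeated pruning-algorithm passes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "DatedTree",
    "TreeSample",
    "CharacterMatrix",
    "MappedHistory",
    "HistoryCollection",
    "TreeValidationError",
    "read_tree_sample",
    "read_character_table",
    "read_character_tables",
    "write_tree_sample",
    "write_character_table",
    "prune_taxa",
    "write_histories",
    "read_histories",
    "write_simmap",
]


class TreeValidationError(ValueError):
    """Raised when a tree violates the dated-tree invariants."""


# ---------------------------------------------------------------------------
# DatedTree


class DatedTree:
    """A rooted, dated (ultrametric) tree.

    Parameters
    ----------
    parent : array of int
        Parent index per node; the root has parent ``-1``.
    ages : array of float
        Node ages in Ma before present. Tips are at (approximately) 0.
    labels : sequence of str or None
        Tip labels (internal nodes may be ``None``). Tip labels must be
        unique.
    """

    def __init__(self, parent, ages, labels, *, tip_age_tol: float | None = None,
                 repair: bool = False):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.ages = np.asarray(ages, dtype=float).copy()
        self.labels = list(labels)
        n = len(self.parent)
        if len(self.ages) != n or len(self.labels) != n:
            raise TreeValidationError("parent/ages/labels length mismatch")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise TreeValidationError(f"expected exactly one root, found {len(roots)}")
        self.root = int(roots[0])
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                self.children[p].append(i)
        self.is_tip = np.array([len(c) == 0 for c in self.children])
        tip_idx = np.flatnonzero(self.is_tip)
        tip_labels = [self.labels[i] for i in tip_idx]
        if any(lbl is None for lbl in tip_labels):
            raise TreeValidationError("unlabeled tip")
        if len(set(tip_labels)) != len(tip_labels):
            raise TreeValidationError("duplicate tip labels")
        self.tip_indices = tip_idx
        self.taxon_to_node = {self.labels[i]: int(i) for i in tip_idx}

        if tip_age_tol is None:
            tip_age_tol = 1e-6 * max(self.root_age, 1e-300)
        bad = [self.labels[i] for i in tip_idx if abs(self.ages[i]) > tip_age_tol]
        if bad:
            if repair:
                for i in tip_idx:
                    self.ages[i] = 0.0
            else:
                raise TreeValidationError(
                    f"non-ultrametric tree: tip ages exceed tolerance for {bad[:5]}")
        else:
            self.ages[tip_idx] = 0.0
        for i, p in enumerate(self.parent):
            if p >= 0 and self.ages[p] < self.ages[i] - 1e-9 * max(self.root_age, 1.0):
                raise TreeValidationError(
                    f"parent younger than child at node {i} "
                    f"({self.ages[p]:g} < {self.ages[i]:g})")

        # postorder: children before parents
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        self.preorder = np.array(order, dtype=np.int64)
        self.postorder = self.preorder[::-1].copy()

    # -- basic properties ---------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_tips(self) -> int:
        return len(self.tip_indices)

    @property
    def root_age(self) -> float:
        return float(self.ages[self.root])

    @property
    def branch_lengths(self) -> np.ndarray:
        """Branch length (Myr) above each node; 0 for the root."""
        bl = np.zeros(self.n_nodes)
        nz = self.parent >= 0
        bl[nz] = self.ages[self.parent[nz]] - self.ages[nz]
        return bl

    @property
    def taxon_labels(self) -> frozenset:
        return frozenset(self.taxon_to_node)

    @property
    def total_branch_length(self) -> float:
        return float(self.branch_lengths.sum())

    def clades(self) -> list[frozenset]:
        """Tip-label set below each node (used to match branches across trees)."""
        out: list[frozenset | None] = [None] * self.n_nodes
        for v in self.postorder:
            if self.is_tip[v]:
                out[v] = frozenset([self.labels[v]])
            else:
                acc: frozenset = frozenset()
                for c in self.children[v]:
                    acc = acc | out[c]
                out[v] = acc
        return out  # type: ignore[return-value]

    # -- conversion ---------------------------------------------------------

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree, **kw) -> "DatedTree":
        nodes = list(dtree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=np.int64)
        depth = np.zeros(len(nodes))
        labels: list[str | None] = [None] * len(nodes)
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                el = nd.edge.length if nd.edge.length is not None else 0.0
                depth[i] = depth[parent[i]] + float(el)
            if nd.taxon is not None:
                labels[i] = nd.taxon.label
            elif nd.is_leaf():
                labels[i] = nd.label
        ages = depth.max() - depth
        return cls(parent, ages, labels, **kw)

    @classmethod
    def from_newick(cls, newick: str, **kw) -> "DatedTree":
        dtree = dendropy.Tree.get(data=newick, schema="newick",
                                  suppress_internal_node_taxa=True)
        return cls.from_dendropy(dtree, **kw)

    def to_newick(self, precision: int = 10) -> str:
        bl = self.branch_lengths

        def rec(v: int) -> str:
            if self.is_tip[v]:
                core = _quote(self.labels[v])
            else:
                core = "(" + ",".join(rec(c) for c in self.children[v]) + ")"
            if v == self.root:
                return core
            return f"{core}:{bl[v]:.{precision}g}"

        return rec(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"<DatedTree {self.n_tips} tips, root age {self.root_age:g} Ma>"


def _quote(label: str) -> str:
    if any(ch in label for ch in " ()[]{}:;,'\t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------------
# TreeSample


@dataclass
class TreeSample:
    """An ordered sample of dated trees over a shared taxon set.

    Trees are typically equally-weighted draws from a dating analysis
    posterior; per-tree weights default to uniform.
    """

    trees: list[DatedTree]
    weights: np.ndarray | None = None

    def __post_init__(self):
        if not self.trees:
            raise TreeValidationError("empty tree sample")
        taxa0 = self.trees[0].taxon_labels
        for k, t in enumerate(self.trees[1:], start=1):
            if t.taxon_labels != taxa0:
                diff = t.taxon_labels ^ taxa0
                raise TreeValidationError(
                    f"tree {k} has a different taxon set (offending taxa: "
                    f"{sorted(diff)[:5]})")
        if self.weights is None:
            self.weights = np.full(len(self.trees), 1.0 / len(self.trees))
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            self.weights = self.weights / self.weights.sum()

    def __len__(self) -> int:
        return len(self.trees)

    def __getitem__(self, i: int) -> DatedTree:
        return self.trees[i]

    @property
    def taxon_labels(self) -> frozenset:
        return self.trees[0].taxon_labels


def read_tree_sample(path, max_trees: int | None = None, *,
                     on_nonultrametric: str = "reject",
                     tip_age_tol: float | None = None) -> TreeSample:
    """Read ≥1 newick trees from a file into a :class:`TreeSample`.

    Node ages are reconstructed by root-to-tip accumulation of branch
    lengths. ``on_nonultrametric`` is ``"reject"`` (default; raise) or
    ``"repair"`` (reset tip ages to 0, stretching terminal branches).
    """
    if on_nonultrametric not in ("reject", "repair"):
        raise ValueError("on_nonultrametric must be 'reject' or 'repair'")
    try:
        tl = dendropy.TreeList.get(path=str(path), schema="newick",
                                   suppress_internal_node_taxa=True)
    except Exception as exc:
        raise TreeValidationError(f"newick parse error in {path}: {exc}") from exc
    if len(tl) == 0:
        raise TreeValidationError(f"no trees found in {path}")
    if max_trees is not None:
        tl = tl[:max_trees]
    trees = [DatedTree.from_dendropy(t, tip_age_tol=tip_age_tol,
                                     repair=(on_nonultrametric == "repair"))
             for t in tl]
    return TreeSample(trees)


def write_tree_sample(sample: TreeSample, path, precision: int = 10) -> None:
    with open(path, "w") as fh:
        for t in sample.trees:
            fh.write(t.to_newick(precision=precision) + "\n")


def prune_taxa(tree: DatedTree, drop) -> DatedTree:
    """Remove the given tips; collapse resulting unary nodes and unary roots.

    Ages of retained nodes are unchanged; branch lengths follow from ages.
    """
    drop = set(drop)
    unknown = drop - tree.taxon_labels
    if unknown:
        raise KeyError(f"unknown taxa: {sorted(unknown)}")
    keep_tips = [i for i in tree.tip_indices if tree.labels[i] not in drop]
    if len(keep_tips) < 2:
        raise ValueError("pruning would leave fewer than 2 tips")
    if not drop:
        return DatedTree(tree.parent, tree.ages, tree.labels)

    keep = np.zeros(tree.n_nodes, dtype=bool)
    keep[keep_tips] = True
    for v in tree.postorder:
        if not tree.is_tip[v]:
            keep[v] = any(keep[c] for c in tree.children[v])

    # new parent = nearest kept ancestor; then collapse nodes with one kept child
    n_kept_children = np.zeros(tree.n_nodes, dtype=np.int64)
    for v in range(tree.n_nodes):
        if keep[v] and tree.parent[v] >= 0:
            n_kept_children[tree.parent[v]] += 1
    retain = keep.copy()
    for v in range(tree.n_nodes):
        if keep[v] and not tree.is_tip[v] and n_kept_children[v] < 2:
            retain[v] = False  # unary (or childless-after-prune) internal node

    idx_map = {}
    new_parent, new_ages, new_labels = [], [], []
    for v in tree.preorder:
        if not retain[v]:
            continue
        p = tree.parent[v]
        while p >= 0 and not retain[p]:
            p = tree.parent[p]
        idx_map[v] = len(new_parent)
        new_parent.append(idx_map[p] if p >= 0 else -1)
        new_ages.append(tree.ages[v])
        new_labels.append(tree.labels[v])
    return DatedTree(new_parent, new_ages, new_labels)


# ---------------------------------------------------------------------------
# CharacterMatrix


@dataclass
class CharacterMatrix:
    """Observed states of one discrete character, possibly ambiguous.

    ``states[taxon]`` is a non-empty frozenset of allowed states: a singleton
    for a certain observation, the full alphabet for missing data.
    """

    name: str
    alphabet: tuple
    states: dict

    def __post_init__(self):
        self.alphabet = tuple(self.alphabet)
        alpha = set(self.alphabet)
        if len(alpha) != len(self.alphabet):
            raise ValueError(f"duplicate states in alphabet for {self.name}")
        clean = {}
        for taxon, obs in self.states.items():
            obs = frozenset(obs)
            if not obs or not obs <= alpha:
                raise ValueError(
                    f"character {self.name}, taxon {taxon}: observed set "
                    f"{sorted(obs)} not a non-empty subset of the alphabet")
            clean[taxon] = obs
        self.states = clean

    @property
    def taxa(self) -> frozenset:
        return frozenset(self.states)

    def partials(self, taxa_order) -> np.ndarray:
        """0/1 tip partial-likelihood matrix, rows follow ``taxa_order``."""
        out = np.zeros((len(taxa_order), len(self.alphabet)))
        for r, taxon in enumerate(taxa_order):
            try:
                obs = self.states[taxon]
            except KeyError:
                raise KeyError(f"character {self.name}: missing taxon {taxon}")
            for j, s in enumerate(self.alphabet):
                if s in obs:
                    out[r, j] = 1.0
        return out

    def is_ambiguous(self) -> bool:
        return any(len(v) > 1 for v in self.states.values())


def _parse_cell(cell: str, alphabet: tuple, taxon: str, name: str) -> frozenset:
    cell = cell.strip()
    if cell == "?":
        return frozenset(alphabet)
    parts = [p.strip() for p in cell.split("/")]
    bad = [p for p in parts if p not in alphabet]
    if bad:
        raise ValueError(
            f"character {name}, taxon {taxon}: unknown state label {bad[0]!r}")
    return frozenset(parts)


def read_character_tables(path, alphabets: dict) -> list[CharacterMatrix]:
    """Read a TSV (header ``taxon<TAB>char...``) into CharacterMatrix objects.

    ``alphabets`` maps character (column) name to its ordered state list.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.columns[0].lower() != "taxon":
        raise ValueError(f"first column of {path} must be 'taxon'")
    taxa = df.iloc[:, 0].tolist()
    dup = {t for t in taxa if taxa.count(t) > 1}
    if dup:
        raise ValueError(f"duplicate taxon rows: {sorted(dup)}")
    out = []
    for col in df.columns[1:]:
        if col not in alphabets:
            continue
        alpha = tuple(alphabets[col])
        states = {t: _parse_cell(c, alpha, t, col)
                  for t, c in zip(taxa, df[col])}
        out.append(CharacterMatrix(col, alpha, states))
    missing = set(alphabets) - set(df.columns[1:])
    if missing:
        raise ValueError(f"characters not found in {path}: {sorted(missing)}")
    return out


def read_character_table(path, alphabet, character: str | None = None) -> CharacterMatrix:
    """Read one character column from a TSV table (see read_character_tables)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, nrows=0)
    cols = [c for c in df.columns[1:]]
    if character is None:
        if len(cols) != 1:
            raise ValueError(
                f"{path} has {len(cols)} character columns; pass character=")
        character = cols[0]
    return read_character_tables(path, {character: alphabet})[0]


def write_character_table(matrices: list, path) -> None:
    taxa = sorted(matrices[0].taxa)
    rows = []
    for t in taxa:
        row = {"taxon": t}
        for m in matrices:
            obs = m.states[t]
            if obs == frozenset(m.alphabet):
                row[m.name] = "?"
            else:
                row[m.name] = "/".join(s for s in m.alphabet if s in obs)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Mapped histories


class MappedHistory:
    """A full, piecewise-constant character history on one dated tree.

    ``segments[v]`` is the ordered list of (older_age, younger_age, state)
    tuples on the branch above node ``v`` (empty for the root); ages decrease
    toward the present, segments are contiguous and span the branch exactly.
    """

    def __init__(self, tree: DatedTree, character: str, segments: list,
                 root_state, validate: bool = True):
        self.tree = tree
        self.character = character
        self.segments = segments
        self.root_state = root_state
        if validate:
            self.validate()

    def validate(self, atol: float = 1e-6):
        t = self.tree
        scale = max(t.root_age, 1.0)
        for v in range(t.n_nodes):
            if v == t.root:
                if self.segments[v]:
                    raise ValueError("root must have no branch segments")
                continue
            segs = self.segments[v]
            if not segs:
                raise ValueError(f"branch above node {v} has no segments")
            start, end = t.ages[t.parent[v]], t.ages[v]
            if abs(segs[0][0] - start) > atol * scale or \
               abs(segs[-1][1] - end) > atol * scale:
                raise ValueError(f"segments do not span branch above node {v}")
            prev = segs[0][0]
            for a, b, _s in segs:
                if b > a + atol * scale:
                    raise ValueError(
                        f"segment end {b} older than start {a} (ages must "
                        f"decrease toward the present)")
                if abs(a - prev) > atol * scale:
                    raise ValueError(f"non-contiguous segments above node {v}")
                prev = b

    def node_state(self, v: int):
        """State at node ``v`` (end of its branch; root state for the root)."""
        if v == self.tree.root:
            return self.root_state
        return self.segments[v][-1][2]

    def start_state(self, v: int):
        if v == self.tree.root:
            return self.root_state
        return self.segments[v][0][2]

    def state_at(self, v: int, age: float):
        """State on the branch above ``v`` at the given age."""
        if v == self.tree.root:
            return self.root_state
        for a, b, s in self.segments[v]:
            if b <= age <= a:
                return s
        raise ValueError(f"age {age} outside branch above node {v}")

    def n_transitions(self) -> int:
        n = 0
        for v in range(self.tree.n_nodes):
            segs = self.segments[v]
            n += sum(1 for i in range(1, len(segs))
                     if segs[i][2] != segs[i - 1][2])
            if v != self.tree.root:
                par = self.tree.parent[v]
                if segs and segs[0][2] != self.node_state(par):
                    raise ValueError("child start state != parent end state")
        return n


@dataclass
class HistoryCollection:
    """Posterior draws of mapped histories, one set of characters per draw."""

    tree_sample: TreeSample
    tree_indices: list = field(default_factory=list)       # per draw
    histories: list = field(default_factory=list)          # per draw: {char: MappedHistory}
    params: list = field(default_factory=list)             # per draw: metadata dict

    def __len__(self) -> int:
        return len(self.histories)

    def characters(self) -> list:
        return sorted(self.histories[0]) if self.histories else []


_HIST_COLS = ["draw", "character", "tree_index", "branch",
              "start_ma", "end_ma", "state"]


def write_histories(collection: HistoryCollection, path) -> None:
    """Write a history collection to a documented TSV.

    One row per segment: draw id, character, tree index, branch id (index of
    the child node of the branch in that tree), older age, younger age,
    state. The root state is stored as a zero-length row on the root node.
    """
    rows = []
    for d, (ti, hs) in enumerate(zip(collection.tree_indices,
                                     collection.histories)):
        for char in sorted(hs):
            h = hs[char]
            tree = h.tree
            rows.append((d, char, ti, tree.root, tree.root_age,
                         tree.root_age, str(h.root_state)))
            for v in range(tree.n_nodes):
                for a, b, s in h.segments[v]:
                    rows.append((d, char, ti, v, a, b, str(s)))
    pd.DataFrame(rows, columns=_HIST_COLS).to_csv(path, sep="\t", index=False,
                                                  float_format="%.12g")


def read_histories(path, tree_sample: TreeSample) -> HistoryCollection:
    df = pd.read_csv(path, sep="\t", dtype={"state": str})
    coll = HistoryCollection(tree_sample)
    if df.empty:
        return coll
    for d, g in df.groupby("draw", sort=True):
        ti = int(g["tree_index"].iloc[0])
        tree = tree_sample[ti]
        per_char = {}
        for char, gc in g.groupby("character"):
            segments: list = [[] for _ in range(tree.n_nodes)]
            root_state = None
            for _, row in gc.iterrows():
                v = int(row["branch"])
                if v == tree.root:
                    root_state = row["state"]
                else:
                    segments[v].append((float(row["start_ma"]),
                                        float(row["end_ma"]), row["state"]))
            for v in range(tree.n_nodes):
                segments[v].sort(key=lambda seg: -seg[0])
            per_char[char] = MappedHistory(tree, str(char), segments, root_state)
        coll.tree_indices.append(ti)
        coll.histories.append(per_char)
        coll.params.append({})
    return coll


def write_simmap(history: MappedHistory, path_or_buf=None) -> str:
    """Write one history as a simmap-style annotated newick string.

    Each branch is annotated ``{state,duration:state,duration}`` from the
    oldest segment to the youngest, durations in Myr.
    """
    tree = history.tree

    def rec(v: int) -> str:
        if tree.is_tip[v]:
            core = _quote(tree.labels[v])
        else:
            core = "(" + ",".join(rec(c) for c in tree.children[v]) + ")"
        if v == tree.root:
            return core
        ann = ":".join(f"{s},{a - b:.10g}" for a, b, s in history.segments[v])
        return core + ":{" + ann + "}"

    s = rec(tree.root) + ";"
    if path_or_buf is not None:
        if isinstance(path_or_buf, (str, bytes)) or hasattr(path_or_buf, "__fspath__"):
            with open(path_or_buf, "w") as fh:
                fh.write(s + "\n")
        else:
            path_or_buf.write(s + "\n")
    return s
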