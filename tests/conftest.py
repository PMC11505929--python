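"""Shared fixtures and independent oracles for the test suite."""

import itertools

import numpy as np
import pytest

from solutemap.likelihood_inference import transition_matrix
from solutemap.phylo_io import CharacterMatrix, DatedTree


@pytest.fixture
def two_tip_tree():
    import math
    return DatedTree.from_newick(f"(A:{math.log(2)},B:{math.log(2)});")


@pytest.fixture
def four_tip_tree():
    return DatedTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def five_tip_tree():
    return DatedTree.from_newick("(((A:1,B:1):1,C:2):1,(D:2.5,E:2.5):0.5);")


def brute_force_loglik(tree: DatedTree, chars, table=None, focal_data=None,
                       cond_space=None, focal_alphabet=None):
    """Likelihood by exhaustive summation over all node-state assignments.

    ``chars`` is a list of (Q, root_prior, CharacterMatrix). With a
    conditional probability ``table`` the per-tip focal factors
    pi(focal obs | joint conditioning state) are included, summing over
    ambiguity in both the conditioning and focal observations.
    """
    n = tree.n_nodes
    per_char_tables = []
    for Q, root_prior, data in chars:
        s = Q.shape[0]
        P = [transition_matrix(Q, tree.branch_lengths[v]) for v in range(n)]
        allowed = []
        for v in range(n):
            if tree.is_tip[v]:
                obs = data.states[tree.labels[v]]
                allowed.append([k for k, lab in enumerate(data.alphabet)
                                if lab in obs])
            else:
                allowed.append(list(range(s)))
        per_char_tables.append((P, root_prior, allowed, data.alphabet))

    total = 0.0
    all_assignments = [list(itertools.product(*allowed))
                       for (_P, _pi, allowed, _a) in per_char_tables]
    for combo in itertools.product(*all_assignments):
        p = 1.0
        for (P, pi, _allowed, _a), assign in zip(per_char_tables, combo):
            p *= pi[assign[tree.root]]
            for v in range(n):
                if v != tree.root:
                    p *= P[v][assign[tree.parent[v]], assign[v]]
        if table is not None:
            for v in tree.tip_indices:
                joint = []
                for (_P, _pi, _al, alpha), assign in zip(per_char_tables, combo):
                    lab = alpha[assign[v]]
                    joint.extend(lab if isinstance(lab, tuple) else [lab])
                joint = tuple(joint) if len(joint) > 1 else joint[0]
                row = table[cond_space.index(joint)]
                obs = focal_data.states[tree.labels[v]]
                p *= sum(row[k] for k, f in enumerate(focal_alphabet)
                         if f in obs)
        total += p
    return np.log(total)


@pytest.fixture
def brute_force():
    return brute_force_loglik
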