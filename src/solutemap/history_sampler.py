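"""Stochastic mapping: sampling full character histories on dated trees.

A stochastic map is a draw from the posterior distribution of complete
character histories given tip data: joint node states are sampled from the
pruning partials (root draw proportional to root prior x root partial, then
a pre-order descent), and each branch is filled in with an
endpoint-conditioned CTMC path sampled by uniformization. A conditioned
focal character (no rates of its own) is overlaid afterwards: on each
maximal constant segment of the joint conditioning state the focal state is
drawn from the corresponding row of the conditional probability table,
except that segments abutting tips are clamped to the observed focal state.
"""

from __future__ import annotations

import math

import numpy as np

from .likelihood_inference import (Analysis, ConditionedModel, _joint_label,
                                   _prune, transition_matrices)
from .phylo_io import (CharacterMatrix, DatedTree, HistoryCollection,
                       MappedHistory, TreeSample)

__all__ = [
    "sample_joint_node_states",
    "node_marginals",
    "sample_branch_history",
    "rejection_sample_branch",
    "sample_markov_history",
    "sample_histories",
    "overlay_conditioned",
    "simulate_unconditioned",
]

_UNIF_SLACK = 1.05   # uniformization constant = slack * max |q_ii|
_MAX_JUMPS = 100000


def _pick(rng: np.random.Generator, w) -> int:
    """Index draw proportional to unnormalized non-negative weights.

    Much cheaper than Generator.choice for the tiny weight vectors used in
    per-node and per-jump sampling."""
    tot = 0.0
    for x in w:
        tot += x
    u = rng.random() * tot
    acc = 0.0
    for i, x in enumerate(w):
        acc += x
        if u <= acc:
            return i
    return len(w) - 1


# ---------------------------------------------------------------------------
# Node-state sampling


def _pruning_setup(tree: DatedTree, Q: np.ndarray, data: CharacterMatrix,
                   root_prior: np.ndarray):
    s = Q.shape[0]
    tips = np.ones((tree.n_nodes, s))
    tips[tree.tip_indices] = data.partials(
        [tree.labels[i] for i in tree.tip_indices])
    P = transition_matrices(Q, tree.branch_lengths)
    ll, partial = _prune(tree, P, tips, root_prior, return_partials=True)
    if not np.isfinite(ll):
        raise ValueError("data have zero probability under this model")
    return P, partial


def sample_joint_node_states(tree: DatedTree, data: CharacterMatrix,
                             Q: np.ndarray, root_prior: np.ndarray,
                             rng: np.random.Generator,
                             setup=None) -> np.ndarray:
    """One joint draw of node state indices from the conditional posterior.

    The root is drawn proportional to root_prior x root partial; a pre-order
    descent draws each node proportional to P(parent->state, branch) x its
    partial. Pass ``setup = (P, partial)`` (from a previous call on the same
    inputs) to skip recomputing the pruning pass.
    """
    P, partial = _pruning_setup(tree, Q, data, root_prior) if setup is None else setup
    states = np.empty(tree.n_nodes, dtype=np.int64)
    p = root_prior * partial[tree.root]
    tot = p.sum()
    if tot <= 0:
        raise ValueError("zero-probability root configuration")
    states[tree.root] = _pick(rng, p)
    for v in tree.preorder:
        if v == tree.root:
            continue
        w = P[v][states[tree.parent[v]]] * partial[v]
        tot = w.sum()
        if tot <= 0:
            raise ValueError(f"zero-probability configuration at node {v}")
        states[v] = _pick(rng, w)
    return states


def node_marginals(tree: DatedTree, data: CharacterMatrix, Q: np.ndarray,
                   root_prior: np.ndarray) -> np.ndarray:
    """Exact marginal posterior state probabilities at every node (up-down)."""
    P, partial = _pruning_setup(tree, Q, data, root_prior)
    s = Q.shape[0]
    down = np.empty((tree.n_nodes, s))
    down[tree.root] = root_prior
    for u in tree.preorder:
        msgs = {c: P[c] @ partial[c] for c in tree.children[u]}
        for v in tree.children[u]:
            out = down[u].copy()
            for c, m in msgs.items():
                if c != v:
                    out = out * m
            down[v] = P[v].T @ out
    marg = partial * down
    marg /= marg.sum(axis=1, keepdims=True)
    return marg


# ---------------------------------------------------------------------------
# Endpoint-conditioned branch paths


def sample_branch_history(a: int, b: int, t: float, Q: np.ndarray,
                          rng: np.random.Generator,
                          P_ab: float | None = None) -> list:
    """Endpoint-conditioned CTMC path on a branch of duration t (Myr).

    Uniformization: the virtual-jump count is drawn from its conditional
    law P(N=n | X_0=a, X_t=b) ∝ Poisson(Ω t)(n) R^n[a,b] with
    R = I + Q/Ω and Ω = 1.05 max|q_ii|; the jump chain is sampled
    conditioned on the endpoint, jump times are uniform order statistics,
    and self-jumps are dropped. Returns [(time_from_start, new_state), ...].
    """
    s = Q.shape[0]
    if s == 2:
        return _sample_branch_2state(a, b, t, Q, rng, P_ab)
    omega = _UNIF_SLACK * float(np.max(-np.diag(Q)))
    if omega <= 0 or t <= 0:
        if a != b:
            raise ValueError("zero-rate chain cannot connect different endpoints")
        return []
    R = np.eye(s) + Q / omega
    if P_ab is None:
        P_ab = transition_matrices(Q, np.array([t]))[0][a, b]
    if P_ab <= 0:
        raise ValueError(f"numerically zero transition probability {a}->{b}")

    # N | a,b,t by inverse CDF over n; the Poisson tail bounds the search
    mu = omega * t
    log_target = math.log(P_ab) + mu
    u = rng.random()
    cdf = 0.0
    Rn = np.eye(s)
    log_w = 0.0   # log(mu^n / n!)
    n = 0
    n_cap = min(_MAX_JUMPS, int(mu + 12.0 * math.sqrt(mu + 1.0) + 50.0))
    while True:
        pn = math.exp(log_w - log_target + math.log(Rn[a, b])) \
            if Rn[a, b] > 0 else 0.0
        cdf += pn
        if u <= cdf or n >= n_cap:
            break
        n += 1
        Rn = Rn @ R
        log_w += math.log(mu) - math.log(n)

    if n == 0:
        return []
    # powers of R for conditioned jump-chain sampling
    powers = [np.eye(s)]
    for _ in range(n):
        powers.append(powers[-1] @ R)
    states = [a]
    for j in range(1, n + 1):
        remaining = n - j
        w = R[states[-1]] * powers[remaining][:, b]
        tot = w.sum()
        states.append(_pick(rng, w))
    times = np.sort(rng.random(n)) * t
    out = []
    cur = a
    for tm, st in zip(times, states[1:]):
        if st != cur:
            out.append((float(tm), int(st)))
            cur = st
    return out


def _sample_branch_2state(a: int, b: int, t: float, Q, rng, P_ab=None) -> list:
    """Scalar closed-form uniformization for binary chains.

    R = I + Q/Omega has eigenvalues 1 and lam = 1 - (q01+q10)/Omega, so
    R^n[i,j] = pi_j + lam^n (delta_ij - pi_j) with pi the stationary law;
    everything stays in plain floats, which matters because this is the
    innermost loop of every stochastic-mapping draw.
    """
    q01 = float(Q[0][1])
    q10 = float(Q[1][0])
    tot = q01 + q10
    omega = _UNIF_SLACK * max(q01, q10)
    if omega <= 0 or t <= 0:
        if a != b:
            raise ValueError("zero-rate chain cannot connect different endpoints")
        return []
    pi1 = q01 / tot
    pi = (1.0 - pi1, pi1)
    lam = 1.0 - tot / omega

    def Rn(i, j, lam_n):
        v = pi[j] + lam_n * ((1.0 if i == j else 0.0) - pi[j])
        return v if v > 0.0 else 0.0

    if P_ab is None:
        e = math.exp(-tot * t)
        P_ab = pi[b] + e * ((1.0 if a == b else 0.0) - pi[b])
    if P_ab <= 0:
        raise ValueError(f"numerically zero transition probability {a}->{b}")

    mu = omega * t
    log_target = math.log(P_ab) + mu
    u = rng.random()
    cdf = 0.0
    log_w = 0.0
    lam_n = 1.0
    n = 0
    n_cap = min(_MAX_JUMPS, int(mu + 12.0 * math.sqrt(mu + 1.0) + 50.0))
    while True:
        r_ab = Rn(a, b, lam_n)
        if r_ab > 0.0:
            cdf += math.exp(log_w - log_target + math.log(r_ab))
        if u <= cdf or n >= n_cap:
            break
        n += 1
        lam_n *= lam
        log_w += math.log(mu) - math.log(n)

    if n == 0:
        return []
    r00 = 1.0 - q01 / omega
    r01 = q01 / omega
    r10 = q10 / omega
    r11 = 1.0 - q10 / omega
    R = ((r00, r01), (r10, r11))
    # lam^k for k = n..0 as we walk the conditioned jump chain
    lam_pows = [1.0] * (n + 1)
    for k in range(1, n + 1):
        lam_pows[k] = lam_pows[k - 1] * lam
    states = [a]
    cur = a
    for j in range(1, n + 1):
        rem = n - j
        w0 = R[cur][0] * Rn(0, b, lam_pows[rem])
        w1 = R[cur][1] * Rn(1, b, lam_pows[rem])
        cur = 0 if rng.random() * (w0 + w1) <= w0 else 1
        states.append(cur)
    times = sorted(rng.random(n))
    out = []
    cur = a
    for tm, st in zip(times, states[1:]):
        if st != cur:
            out.append((float(tm * t), int(st)))
            cur = st
    return out


def rejection_sample_branch(a: int, b: int, t: float, Q: np.ndarray,
                            rng: np.random.Generator,
                            max_tries: int = 1000000) -> list:
    """Forward-simulation rejection sampler (oracle for uniformization)."""
    s = Q.shape[0]
    exit_rates = -np.diag(Q)
    for _ in range(max_tries):
        path = []
        cur, tm = a, 0.0
        while True:
            r = exit_rates[cur]
            if r <= 0:
                break
            tm += rng.exponential(1.0 / r)
            if tm >= t:
                break
            w = Q[cur].copy()
            w[cur] = 0.0
            nxt = _pick(rng, w)
            path.append((tm, nxt))
            cur = nxt
        if cur == b:
            return path
    raise RuntimeError("rejection sampler failed to hit the endpoint")


# ---------------------------------------------------------------------------
# Whole-tree histories


def _segments_from_path(tree: DatedTree, v: int, start_state, path,
                        labels) -> list:
    """Branch path [(time_from_start, state_idx)] -> age segments."""
    a0 = tree.ages[tree.parent[v]]
    a1 = tree.ages[v]
    segs = []
    cur_age, cur_state = a0, start_state
    for tm, st in path:
        age = a0 - tm
        segs.append((cur_age, age, labels[cur_state] if isinstance(cur_state, (int, np.integer)) else cur_state))
        cur_age, cur_state = age, st
    segs.append((cur_age, a1, labels[cur_state] if isinstance(cur_state, (int, np.integer)) else cur_state))
    return segs


def sample_markov_history(tree: DatedTree, data: CharacterMatrix,
                          Q: np.ndarray, root_prior: np.ndarray,
                          rng: np.random.Generator, character: str = "",
                          setup=None) -> MappedHistory:
    """One full stochastic map of a Markov character (node states + paths)."""
    if setup is None:
        setup = _pruning_setup(tree, Q, data, root_prior)
    P, _partial = setup
    states = sample_joint_node_states(tree, data, Q, root_prior, rng, setup)
    labels = data.alphabet
    segments: list = [[] for _ in range(tree.n_nodes)]
    for v in range(tree.n_nodes):
        if v == tree.root:
            continue
        a, b = states[tree.parent[v]], states[v]
        t = tree.ages[tree.parent[v]] - tree.ages[v]
        path = sample_branch_history(int(a), int(b), float(t), Q, rng,
                                     P_ab=float(P[v][a, b]))
        segments[v] = _segments_from_path(tree, v, int(a), path, labels)
    return MappedHistory(tree, character or data.name, segments,
                         labels[states[tree.root]], validate=False)


def simulate_unconditioned(tree: DatedTree, Q: np.ndarray,
                           root_prior: np.ndarray,
                           rng: np.random.Generator,
                           labels=None, character: str = "") -> MappedHistory:
    """Forward (predictive) simulation: root drawn from the root prior, no
    tip conditioning."""
    s = Q.shape[0]
    labels = tuple(labels) if labels is not None else tuple(range(s))
    exit_rates = -np.diag(Q)
    states = np.empty(tree.n_nodes, dtype=np.int64)
    states[tree.root] = _pick(rng, np.asarray(root_prior))
    segments: list = [[] for _ in range(tree.n_nodes)]
    for v in tree.preorder:
        if v == tree.root:
            continue
        cur = int(states[tree.parent[v]])
        t = tree.ages[tree.parent[v]] - tree.ages[v]
        path = []
        tm = 0.0
        while exit_rates[cur] > 0:
            tm += rng.exponential(1.0 / exit_rates[cur])
            if tm >= t:
                break
            w = Q[cur].copy()
            w[cur] = 0.0
            cur = _pick(rng, w)
            path.append((tm, cur))
        states[v] = cur
        segments[v] = _segments_from_path(tree, v, int(states[tree.parent[v]]),
                                          path, labels)
    return MappedHistory(tree, character, segments,
                         labels[states[tree.root]], validate=False)


def sample_histories(analyses, posteriors, model_weights, n_draws: int = 5000,
                     seed: int = 0, conditioned_tables=None,
                     clamp_tips: bool = True) -> HistoryCollection:
    """Draw a model-averaged collection of stochastic maps.

    ``analyses``/``posteriors`` are parallel lists (one Analysis and one
    PosteriorSample per candidate model); each output draw picks a model
    with probability proportional to ``model_weights``, then a posterior
    draw (tree index, rates, table) from that model's sample, then maps all
    Markov characters and finally overlays the conditioned focal character
    if the model has one.
    """
    if np.isscalar(model_weights):
        model_weights = [model_weights]
    w = np.asarray(model_weights, dtype=float)
    w = w / w.sum()
    if len(w) != len(analyses) or len(analyses) != len(posteriors):
        raise ValueError("analyses/posteriors/weights length mismatch")
    rng = np.random.default_rng(seed)
    coll = HistoryCollection(analyses[0].tree_sample)
    for _d in range(n_draws):
        m = int(rng.choice(len(w), p=w))
        an, ps = analyses[m], posteriors[m]
        i = int(rng.integers(len(ps)))
        ti = int(ps.tree_indices[i])
        rates = ps.rates[i]
        table = ps.tables[i] if ps.tables is not None else None
        tree = an.tree_sample[ti]
        Qs = an.generators(rates)
        draw = {}
        for c, Q in zip(an.chars, Qs):
            pi = c.root.resolve(Q)
            draw[c.name] = sample_markov_history(tree, c.data, Q, pi, rng,
                                                 character=c.name)
        if an.conditioned is not None:
            cond_hists = [draw[c.name] for c in an.chars]
            draw[an.focal_data.name] = overlay_conditioned(
                cond_hists, an.conditioned, an.focal_data, rng,
                table=table, clamp_tips=clamp_tips)
        coll.tree_indices.append(ti)
        coll.histories.append(draw)
        coll.params.append({"model": m, "rates": rates.tolist()})
    return coll


# ---------------------------------------------------------------------------
# Conditioned-character overlay


def _branch_joint_segments(histories, tree: DatedTree, v: int) -> list:
    """Merged (older, younger, joint_label) segments on the branch above v."""
    a0, a1 = tree.ages[tree.parent[v]], tree.ages[v]
    cuts = {a0, a1}
    for h in histories:
        for a, b, _s in h.segments[v]:
            cuts.add(a)
            cuts.add(b)
    edges = sorted((c for c in cuts if a1 <= c <= a0), reverse=True)
    if len(edges) < 2:   # zero-length branch
        combo = tuple(h.state_at(v, a0) for h in histories)
        return [(a0, a1, _joint_label(combo, None))]
    out = []
    for a, b in zip(edges[:-1], edges[1:]):
        mid = 0.5 * (a + b)
        combo = tuple(h.state_at(v, mid) for h in histories)
        lab = _joint_label(combo, None)
        if out and out[-1][2] == lab:
            out[-1] = (out[-1][0], b, lab)
        else:
            out.append((a, b, lab))
    return out


def overlay_conditioned(conditioning_histories, model: ConditionedModel,
                        focal_data: CharacterMatrix | None,
                        rng: np.random.Generator, character: str = "",
                        table: np.ndarray | None = None,
                        clamp_tips: bool = True) -> MappedHistory:
    """Overlay a conditioned focal history on conditioning histories.

    The joint conditioning state is piecewise constant on the tree; on each
    maximal constant region the focal state is drawn once from the table row
    for that joint state (a region extending across a node keeps its drawn
    state), independently across regions. The segment abutting each tip is
    clamped to the observed focal tip state; an observed state with zero
    table probability given the tip's conditioning state raises (model
    misfit). With ``clamp_tips=False`` the overlay is posterior-predictive.
    """
    table = model.table if table is None else np.asarray(table, dtype=float)
    if table is None:
        raise ValueError("no conditional probability table")
    tree = conditioning_histories[0].tree
    row_of = {lab: i for i, lab in enumerate(model.space.labels)}
    falpha = model.focal_alphabet

    def draw_focal(joint_lab):
        return falpha[_pick(rng, table[row_of[joint_lab]])]

    root_joint = _joint_label(
        tuple(h.root_state for h in conditioning_histories), None)
    root_focal = draw_focal(root_joint)
    segments: list = [[] for _ in range(tree.n_nodes)]
    end_joint = [None] * tree.n_nodes
    end_focal = [None] * tree.n_nodes
    end_joint[tree.root] = root_joint
    end_focal[tree.root] = root_focal
    for v in tree.preorder:
        if v == tree.root:
            continue
        u = tree.parent[v]
        segs = _branch_joint_segments(conditioning_histories, tree, v)
        out = []
        prev_joint, prev_focal = end_joint[u], end_focal[u]
        for (a, b, lab) in segs:
            focal = prev_focal if lab == prev_joint else draw_focal(lab)
            out.append((a, b, focal))
            prev_joint, prev_focal = lab, focal
        if clamp_tips and tree.is_tip[v]:
            taxon = tree.labels[v]
            obs = focal_data.states[taxon]
            jrow = table[row_of[segs[-1][2]]] * np.array(
                [1.0 if f in obs else 0.0 for f in falpha])
            if jrow.sum() <= 0:
                raise ValueError(
                    f"tip {taxon}: observed focal state has zero table "
                    f"probability given its conditioning state")
            obs_state = falpha[_pick(rng, jrow)]
            a, b, _f = out[-1]
            out[-1] = (a, b, obs_state)
        # merge equal adjacent focal segments
        merged = [out[0]]
        for a, b, f in out[1:]:
            if merged[-1][2] == f:
                merged[-1] = (merged[-1][0], b, f)
            else:
                merged.append((a, b, f))
        segments[v] = merged
        end_joint[v] = segs[-1][2]
        end_focal[v] = merged[-1][2]
    name = character or (focal_data.name if focal_data is not None else "focal")
    return MappedHistory(tree, name, segments, root_focal, validate=False)
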