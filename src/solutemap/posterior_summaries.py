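"""Posterior summaries of mapped-history collections.

Turns a sample of stochastic maps into the quantities a trait-evolution
study reports: posterior state probabilities at nodes and along branches (on
a regular age grid), the age of the first lineage satisfying a state
predicate, direction-specific transition rates through time (transitions per
lineage per Gyr), summed gain/loss/exchange rate ratios, and highest
posterior density intervals.

Branches are matched across trees of the sample by their tip-set clade, so
collections over jittered-age (or varying-topology) tree samples aggregate
correctly: a draw whose tree lacks a clade simply does not contribute to it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phylo_io import HistoryCollection
from .trait_models import build_rate_matrix

__all__ = [
    "StateProfile",
    "EventAgeSample",
    "RateThroughTime",
    "state_probability_profiles",
    "first_occurrence_ages",
    "transitions_through_time",
    "rate_ratios",
    "hpd_interval",
]


# ---------------------------------------------------------------------------
# Node / branch-time state probabilities


@dataclass
class StateProfile:
    """Posterior state probabilities per clade (node) and per branch-age."""

    character: str
    states: tuple
    node_probs: dict              # clade -> np.ndarray over states
    node_support: dict            # clade -> number of draws containing it
    branch_probs: dict            # clade -> {age: np.ndarray over states}
    age_step: float

    def node_frame(self) -> pd.DataFrame:
        rows = []
        for clade, p in self.node_probs.items():
            row = {"clade": "|".join(sorted(clade)),
                   "n_draws": self.node_support[clade]}
            row.update({f"p_{_lab(s)}": p[k] for k, s in enumerate(self.states)})
            rows.append(row)
        return pd.DataFrame(rows)

    def branch_frame(self) -> pd.DataFrame:
        rows = []
        for clade, ages in self.branch_probs.items():
            for age, p in sorted(ages.items(), reverse=True):
                row = {"clade": "|".join(sorted(clade)), "age_ma": age}
                row.update({f"p_{_lab(s)}": p[k]
                            for k, s in enumerate(self.states)})
                rows.append(row)
        return pd.DataFrame(rows)


def _lab(s) -> str:
    return "".join(s) if isinstance(s, tuple) else str(s)


def state_probability_profiles(histories: HistoryCollection, character: str,
                               age_step: float = 10.0) -> StateProfile:
    """Draw frequencies of states at every node and on a regular age grid."""
    if not len(histories):
        raise ValueError("empty history collection")
    if character not in histories.histories[0]:
        raise KeyError(f"character {character!r} absent from histories")
    states: list = []
    state_idx: dict = {}

    def idx(s):
        if s not in state_idx:
            state_idx[s] = len(states)
            states.append(s)
        return state_idx[s]

    node_counts: dict = {}
    node_n: dict = {}
    branch_counts: dict = {}
    branch_n: dict = {}
    for hs in histories.histories:
        h = hs[character]
        tree = h.tree
        clades = tree.clades()
        for v in range(tree.n_nodes):
            cl = clades[v]
            k = idx(h.node_state(v))
            node_counts.setdefault(cl, {})
            node_counts[cl][k] = node_counts[cl].get(k, 0) + 1
            node_n[cl] = node_n.get(cl, 0) + 1
            if v == tree.root:
                continue
            top = tree.ages[tree.parent[v]]
            bot = tree.ages[v]
            g0 = int(np.ceil(bot / age_step))
            g1 = int(np.floor(top / age_step))
            ages = [a * age_step for a in range(g0, g1 + 1)]
            if bot not in ages:
                ages.append(float(bot))
            bc = branch_counts.setdefault(cl, {})
            bn = branch_n.setdefault(cl, {})
            for age in ages:
                k = idx(h.state_at(v, age))
                bc.setdefault(age, {})
                bc[age][k] = bc[age].get(k, 0) + 1
                bn[age] = bn.get(age, 0) + 1

    S = len(states)
    node_probs = {}
    for cl, counts in node_counts.items():
        p = np.zeros(S)
        for k, c in counts.items():
            p[k] = c
        node_probs[cl] = p / node_n[cl]
    branch_probs = {}
    for cl, per_age in branch_counts.items():
        branch_probs[cl] = {}
        for age, counts in per_age.items():
            p = np.zeros(S)
            for k, c in counts.items():
                p[k] = c
            branch_probs[cl][age] = p / branch_n[cl][age]
    return StateProfile(character, tuple(states), node_probs, node_n,
                        branch_probs, age_step)


# ---------------------------------------------------------------------------
# First-occurrence ages


@dataclass
class EventAgeSample:
    """Per-draw age (Ma) of an event; NaN marks draws where it never occurs."""

    ages: np.ndarray
    description: str = ""

    def present_fraction(self) -> float:
        return float(np.mean(np.isfinite(self.ages)))

    def prob_older_than(self, reference_age: float) -> float:
        """Fraction of draws in which the event predates ``reference_age``."""
        ok = np.isfinite(self.ages)
        return float(np.mean(ok & (self.ages > reference_age)))

    def summary(self, masses=(0.89, 0.95)) -> dict:
        finite = self.ages[np.isfinite(self.ages)]
        out = {"n": len(self.ages), "present_fraction": self.present_fraction()}
        if len(finite):
            out["median"] = float(np.median(finite))
            for m in masses:
                if len(finite) >= 100:
                    lo, hi = hpd_interval(finite, m)
                    out[f"hpd{int(m * 100)}"] = (lo, hi)
        return out


def first_occurrence_ages(histories: HistoryCollection, character: str,
                          predicate, scope=None) -> EventAgeSample:
    """Oldest age, per draw, at which any lineage satisfies ``predicate``.

    ``predicate`` maps a state to bool. ``scope`` restricts the search to the
    clade spanned by the given tip labels (the MRCA and everything below);
    the default is the whole tree. If the state at the scope root satisfies
    the predicate the event age is that node's age; a draw in which no
    lineage ever satisfies it yields NaN.
    """
    if scope is not None:
        scope = frozenset(scope)
        if not scope:
            raise ValueError("empty scope")
    ages = np.full(len(histories), np.nan)
    for k, hs in enumerate(histories.histories):
        h = hs[character]
        tree = h.tree
        if scope is None:
            top = tree.root
        else:
            clades = tree.clades()
            candidates = [v for v in range(tree.n_nodes) if scope <= clades[v]]
            top = min(candidates, key=lambda v: len(clades[v]))
        if predicate(h.node_state(top)):
            ages[k] = tree.ages[top]
            continue
        best = np.nan
        stack = list(tree.children[top])
        while stack:
            v = stack.pop()
            stack.extend(tree.children[v])
            for a, _b, s in h.segments[v]:
                if predicate(s):
                    # predicate first holds at the older edge of this segment
                    if not (best == best) or a > best:
                        best = a
                    break
        ages[k] = best
    return EventAgeSample(ages, f"first occurrence of predicate on {character}")


# ---------------------------------------------------------------------------
# Transition rates through time


@dataclass
class RateThroughTime:
    """Mean transitions per lineage per Gyr in contiguous age bins."""

    edges: np.ndarray             # bin edges, Ma, descending spans [e[i+1], e[i])
    rates: np.ndarray             # mean over draws, per bin
    counts: np.ndarray            # (n_draws, n_bins) raw transition counts
    lineage_gyr: np.ndarray       # (n_draws, n_bins) lineage-time per bin
    direction: tuple

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_old_ma": self.edges[:-1], "bin_young_ma": self.edges[1:],
            "rate_per_lineage_gyr": self.rates})


def transitions_through_time(histories: HistoryCollection, character: str,
                             direction, bin_edges) -> RateThroughTime:
    """Direction-specific transition rates per lineage-Gyr in age bins.

    For each draw and bin: (number of ``from -> to`` transitions with age in
    the bin) / (lineage-time in the bin), where lineage-time integrates the
    number of contemporaneous branches over the bin, expressed in
    lineage-Gyr. The reported rate is the mean over draws; bins with zero
    lineage-time are NaN.
    """
    frm, to = direction
    edges = np.sort(np.asarray(bin_edges, dtype=float))[::-1]
    nb = len(edges) - 1
    nd = len(histories)
    counts = np.zeros((nd, nb))
    ltime = np.zeros((nd, nb))

    def bin_of(age):
        for i in range(nb):
            if edges[i + 1] <= age < edges[i] or (i == 0 and age == edges[0]):
                return i
        return None

    for k, hs in enumerate(histories.histories):
        h = hs[character]
        tree = h.tree
        for v in range(tree.n_nodes):
            if v == tree.root:
                continue
            top, bot = tree.ages[tree.parent[v]], tree.ages[v]
            for i in range(nb):
                ov = min(top, edges[i]) - max(bot, edges[i + 1])
                if ov > 0:
                    ltime[k, i] += ov / 1000.0
            segs = h.segments[v]
            for s0, s1 in zip(segs[:-1], segs[1:]):
                if s0[2] == frm and s1[2] == to:
                    b = bin_of(s1[0])
                    if b is not None:
                        counts[k, b] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        per_draw = np.where(ltime > 0, counts / np.maximum(ltime, 1e-300), np.nan)
    rates = np.nanmean(per_draw, axis=0)
    rates = np.where(np.all(ltime == 0, axis=0), np.nan, rates)
    return RateThroughTime(edges, rates, counts, ltime, (frm, to))


# ---------------------------------------------------------------------------
# Gain/loss/exchange rate ratios


def rate_ratios(models, posteriors, weights, classes: dict,
                n_draws: int = 2000, seed: int = 0) -> dict:
    """Posterior samples of summed-rate ratios (L/G, L/E, G/E) after model
    averaging.

    ``models`` are parameterized RateModel templates (one per candidate
    model, sharing a state space), ``posteriors`` the matching rate samples,
    ``weights`` the model posterior probabilities, and ``classes`` the
    gain/loss/exchange cell sets from :func:`solutemap.trait_models.rate_classes`.
    Ratios whose denominator class is empty are omitted.
    """
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    rng = np.random.default_rng(seed)
    sums = {name: [] for name in classes}
    for _ in range(n_draws):
        m = int(rng.choice(len(w), p=w))
        ps = posteriors[m]
        i = int(rng.integers(len(ps)))
        Q = build_rate_matrix(models[m].with_rates(ps.rates[i]))
        for name, cells in classes.items():
            sums[name].append(sum(Q[i_, j_] for i_, j_ in cells))
    sums = {k: np.asarray(v) for k, v in sums.items()}
    out = {}
    for num, den in (("L", "G"), ("L", "E"), ("G", "E")):
        if num in sums and den in sums and len(classes.get(den, [])):
            with np.errstate(divide="ignore"):
                r = sums[num] / np.maximum(sums[den], 1e-300)
            key = f"{num}/{den}"
            out[key] = {"samples": r, "median": float(np.median(r))}
            if len(r) >= 100:
                out[key]["hpd89"] = hpd_interval(r, 0.89)
    for name, v in sums.items():
        out[name] = {"samples": v, "median": float(np.median(v))}
    return out


# ---------------------------------------------------------------------------
# HPD intervals


def hpd_interval(samples, mass: float = 0.89):
    """Shortest contiguous interval containing ceil(mass * n) sorted samples.

    Warns when the distribution looks multimodal (the shortest window is
    >10% shorter than the central interval with the same mass).
    """
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n < 100:
        raise ValueError("need at least 100 samples for an HPD interval")
    if not 0 < mass < 1:
        raise ValueError("mass must be in (0, 1)")
    k = int(np.ceil(mass * n))
    widths = x[k - 1:] - x[:n - k + 1]
    i = int(np.argmin(widths))
    lo, hi = float(x[i]), float(x[i + k - 1])
    tail = (n - k) // 2
    central = x[min(tail + k - 1, n - 1)] - x[tail]
    if central > 0 and (hi - lo) < 0.9 * central:
        warnings.warn("possibly multimodal sample: HPD much shorter than the "
                      "central interval", stacklevel=2)
    return lo, hi
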