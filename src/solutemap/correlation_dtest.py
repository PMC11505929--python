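"""D-test: correlation between two characters from their mapped histories.

The association between two characters is measured by comparing, for each
posterior history draw, the fraction of total tree length jointly spent in
each state pair (A_ij) with the product of the marginal dwell fractions
(a_i * b_j). The per-cell deviation d_ij = mean_k (A_ij - a_i b_j) and the
overall statistic D = sum_ij |d_ij| (both in percent) quantify the strength
and direction of association; significance comes from posterior-predictive
replicates in which the two characters evolve independently (null datasets
simulated under posterior parameter/tree draws and re-mapped conditioned on
their own simulated tips).

Positive d_ij means states i and j co-occur along the tree more than
expected under independence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phylo_io import HistoryCollection, MappedHistory

__all__ = ["AssociationTable", "DTestResult", "association_fractions", "d_test"]


@dataclass
class AssociationTable:
    """Dwell-time fractions for one draw: marginals a, b and joint A."""

    a: np.ndarray            # marginal fractions, character 1
    b: np.ndarray            # marginal fractions, character 2
    A: np.ndarray            # joint fractions, A[i, j]
    tree_length: float

    def deviation(self) -> np.ndarray:
        return self.A - np.outer(self.a, self.b)


def association_fractions(h1: MappedHistory, h2: MappedHistory,
                          states1, states2) -> AssociationTable:
    """Joint and marginal dwell-time fractions by branch-wise segment merge."""
    if h1.tree is not h2.tree:
        raise ValueError("histories must share the same tree")
    tree = h1.tree
    i1 = {s: k for k, s in enumerate(states1)}
    i2 = {s: k for k, s in enumerate(states2)}
    A = np.zeros((len(states1), len(states2)))
    for v in range(tree.n_nodes):
        if v == tree.root:
            continue
        cuts = sorted({a for a, _b, _s in h1.segments[v]} |
                      {b for _a, b, _s in h1.segments[v]} |
                      {a for a, _b, _s in h2.segments[v]} |
                      {b for _a, b, _s in h2.segments[v]}, reverse=True)
        for a, b in zip(cuts[:-1], cuts[1:]):
            mid = 0.5 * (a + b)
            A[i1[h1.state_at(v, mid)], i2[h2.state_at(v, mid)]] += a - b
    L = A.sum()
    if L <= 0:
        raise ValueError("zero total tree length")
    A /= L
    return AssociationTable(A.sum(axis=1), A.sum(axis=0), A, L)


@dataclass
class DTestResult:
    """D-test outcome; D and d are percentages, P values are probabilities."""

    states1: tuple
    states2: tuple
    D: float                       # percent
    d: np.ndarray                  # percent, shape (s1, s2)
    P: float
    P_matrix: np.ndarray
    n_observed: int
    n_null: int
    threshold: float = 0.05

    @property
    def significant(self) -> bool:
        return self.P < self.threshold

    def summary_frame(self):
        import pandas as pd
        rows = [{"comparison": "overall", "D_or_d_percent": self.D,
                 "P": self.P}]
        for i, s1 in enumerate(self.states1):
            for j, s2 in enumerate(self.states2):
                rows.append({"comparison": f"{_lab(s1)} vs {_lab(s2)}",
                             "D_or_d_percent": self.d[i, j],
                             "P": self.P_matrix[i, j]})
        return pd.DataFrame(rows)


def _lab(s) -> str:
    return "".join(s) if isinstance(s, tuple) else str(s)


def _group_means(dev: np.ndarray, groups) -> np.ndarray:
    groups = np.asarray(groups)
    if len(groups) != len(dev):
        raise ValueError("group label length mismatch")
    return np.stack([dev[groups == g].mean(axis=0)
                     for g in np.unique(groups)])


def d_test(observed: HistoryCollection, null: HistoryCollection,
           char1: str, char2: str, states1, states2,
           threshold: float = 0.05, min_draws: int = 1,
           null_groups=None, obs_groups=None) -> DTestResult:
    """Strength, direction and posterior-predictive significance of
    association between two mapped characters.

    ``observed`` holds paired conditioned (tip-respecting) histories; the
    reported d_ij/D average the per-draw deviations. For the significance,
    each null replicate should mirror the observed statistic's construction:
    simulate a null dataset (the two characters evolving independently under
    a posterior parameter/tree draw), re-map it conditioned on its own
    simulated tips, and average the deviations of a small inner sample of
    maps. ``null_groups`` assigns each null draw to its replicate (draws
    sharing an id are averaged before |.| is taken); ``obs_groups`` should
    chunk the observed draws into groups of the same inner size so both
    sides of the comparison carry the same Monte-Carlo noise. Without
    groups, every draw is its own replicate (the plain unconditioned null,
    which is markedly more conservative).
    """
    states1, states2 = tuple(states1), tuple(states2)
    if len(observed) < min_draws or len(null) < min_draws:
        raise ValueError(f"need at least {min_draws} draws")
    obs_dev = np.stack([
        association_fractions(hs[char1], hs[char2], states1, states2).deviation()
        for hs in observed.histories])
    d = obs_dev.mean(axis=0)
    D = np.abs(d).sum()
    null_dev = np.stack([
        association_fractions(hs[char1], hs[char2], states1, states2).deviation()
        for hs in null.histories])
    if null_groups is not None:
        null_dev = _group_means(null_dev, null_groups)
    if obs_groups is not None:
        og = _group_means(obs_dev, obs_groups)
        stat_D = np.abs(og).sum(axis=(1, 2)).mean()
        stat_ij = np.abs(og).mean(axis=0)
    else:
        stat_D = D
        stat_ij = np.abs(d)
    null_D = np.abs(null_dev).sum(axis=(1, 2))
    P = float(np.mean(null_D >= stat_D))
    P_matrix = np.mean(np.abs(null_dev) >= stat_ij[None, :, :], axis=0)
    return DTestResult(states1, states2, float(D * 100), d * 100, P,
                       P_matrix, len(observed), len(null_dev), threshold)
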