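"""Likelihoods, priors, MCMC and marginal likelihoods for trait CTMC models.

The likelihood of tip data under a CTMC on a dated tree is computed with the
pruning algorithm; several independent Markov characters multiply, and an
optional *conditioned* character (a focal trait that is a probabilistic
function of the joint state of the Markov characters, with no rates of its
own) contributes per-tip factors pi(focal obs | joint conditioning state).

Bayesian machinery: empirical-Bayes priors centered on the MLE, a
Metropolis-Hastings sampler over rates / conditional-probability tables /
the tree index, stepping-stone estimation of the marginal likelihood on a
Beta(0.3, 1)-quantile power ladder, and Bayesian model averaging with a
uniform model prior (AIC/BIC weights are also available).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.optimize
import scipy.special
import scipy.stats

from .phylo_io import CharacterMatrix, DatedTree, TreeSample
from .trait_models import RateModel, StateSpace, build_rate_matrix

__all__ = [
    "RootPrior",
    "MarkovCharacter",
    "ConditionedModel",
    "Prior",
    "PriorSpec",
    "PosteriorSample",
    "ModelWeights",
    "Analysis",
    "transition_matrix",
    "tree_likelihood",
    "mle_fit",
    "empirical_bayes_priors",
    "mcmc_sample",
    "stepping_stone_logml",
    "model_weights_and_average",
    "information_criteria",
    "rate_grid_scan",
    "effective_sample_size",
]

RATE_LO, RATE_HI = 1e-9, 1e3
# Default upper bound for the *optimizer*: with ages in Ma and rates per Myr,
# 0.1/Myr already saturates any branch longer than ~50 Myr, so the likelihood
# is flat beyond it; capping keeps empirical-Bayes priors (and the stochastic
# maps sampled under them) away from degenerate infinite-rate plateaus.
RATE_OPT_HI = 0.1


# ---------------------------------------------------------------------------
# Transition probabilities


def transition_matrix(Q: np.ndarray, t: float) -> np.ndarray:
    """P(t) = exp(Qt) for a single duration t (Myr)."""
    if t < 0:
        raise ValueError("negative branch duration")
    return transition_matrices(np.asarray(Q, dtype=float), np.array([t]))[0]


def transition_matrices(Q: np.ndarray, ts: np.ndarray) -> np.ndarray:
    """exp(Q t) for an array of durations, shape (len(ts), s, s).

    2-state generators use the closed form; larger ones an eigendecomposition
    with a scaling-and-squaring (Pade) fallback when reconstruction is poor.
    """
    Q = np.asarray(Q, dtype=float)
    ts = np.asarray(ts, dtype=float)
    s = Q.shape[0]
    n = len(ts)
    if s == 2:
        a, b = Q[0, 1], Q[1, 0]
        tot = a + b
        P = np.empty((n, 2, 2))
        if tot <= 0:
            P[:] = np.eye(2)
            return P
        e = np.exp(-tot * ts)
        pi0, pi1 = b / tot, a / tot
        P[:, 0, 0] = pi0 + pi1 * e
        P[:, 0, 1] = pi1 * (1.0 - e)
        P[:, 1, 0] = pi0 * (1.0 - e)
        P[:, 1, 1] = pi1 + pi0 * e
        return P
    try:
        w, V = np.linalg.eig(Q)
        Vi = np.linalg.inv(V)
        E = np.exp(np.multiply.outer(ts, w))       # (n, s)
        P = np.einsum("ij,tj,jk->tik", V, E, Vi)
        P = np.real(P)
        err = np.abs(P.sum(axis=2) - 1.0).max()
        if not np.isfinite(err) or err > 1e-8:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        P = np.stack([scipy.linalg.expm(Q * t) for t in ts])
    np.clip(P, 0.0, None, out=P)
    P /= P.sum(axis=2, keepdims=True)
    return P


# ---------------------------------------------------------------------------
# Model pieces


@dataclass
class RootPrior:
    """Probability vector over the root state; 'uniform', 'stationary' or fixed."""

    kind: str = "uniform"
    vector: np.ndarray | None = None

    def resolve(self, Q: np.ndarray) -> np.ndarray:
        s = Q.shape[0]
        if self.kind == "uniform":
            return np.full(s, 1.0 / s)
        if self.kind == "stationary":
            # left null vector of Q
            w, V = np.linalg.eig(Q.T)
            k = int(np.argmin(np.abs(w)))
            pi = np.real(V[:, k])
            pi = np.abs(pi)
            return pi / pi.sum()
        if self.kind == "fixed":
            v = np.asarray(self.vector, dtype=float)
            if v.min() < 0 or abs(v.sum() - 1) > 1e-9:
                raise ValueError("root prior must be a probability vector")
            return v
        raise ValueError(f"unknown root prior kind {self.kind!r}")


@dataclass
class MarkovCharacter:
    """One CTMC character: parameterized model + observed tip data + root prior."""

    name: str
    model: RateModel
    data: CharacterMatrix
    root: RootPrior = field(default_factory=RootPrior)

    def __post_init__(self):
        if tuple(self.data.alphabet) != tuple(self.model.space.labels):
            raise ValueError(
                f"character {self.name}: data alphabet does not match the "
                f"model state space")


@dataclass
class ConditionedModel:
    """A focal character conditioned on the joint state of Markov characters.

    ``table[j, f]`` = pi(focal state f | joint conditioning state j); rows are
    probability vectors. The focal character has no rate parameters.
    """

    space: StateSpace          # joint conditioning space (product, declared order)
    focal_alphabet: tuple
    table: np.ndarray | None = None

    def __post_init__(self):
        self.focal_alphabet = tuple(self.focal_alphabet)
        if self.table is not None:
            self.table = np.asarray(self.table, dtype=float)
            if self.table.shape != (self.space.size, len(self.focal_alphabet)):
                raise ValueError("conditional probability table shape mismatch")
            if self.table.min() < -1e-12 or \
               np.abs(self.table.sum(axis=1) - 1).max() > 1e-9:
                raise ValueError("table rows must be probability vectors")

    @property
    def n_rows(self) -> int:
        return self.space.size


# ---------------------------------------------------------------------------
# Priors


@dataclass
class Prior:
    """A prior on one rate parameter: LogNormal(mu, sigma) or Exponential(lam).

    Rates are per Myr; the exponential scale ``lam`` is per Myr^-1 (lam=100
    concentrates mass on rates below ~0.05 per Myr).
    """

    kind: str
    mu: float = 0.0
    sigma: float = 1.0
    lam: float = 100.0

    def _dist(self):
        if self.kind == "lognormal":
            return scipy.stats.lognorm(s=self.sigma, scale=math.exp(self.mu))
        if self.kind == "exponential":
            return scipy.stats.expon(scale=1.0 / self.lam)
        raise ValueError(f"unknown prior kind {self.kind!r}")

    def logpdf(self, x: float) -> float:
        if x <= 0:
            return -math.inf
        if self.kind == "lognormal":
            z = (math.log(x) - self.mu) / self.sigma
            return -math.log(x * self.sigma * math.sqrt(2 * math.pi)) - 0.5 * z * z
        if self.kind == "exponential":
            return math.log(self.lam) - self.lam * x
        raise ValueError(f"unknown prior kind {self.kind!r}")

    def sample(self, rng: np.random.Generator, size=None):
        if self.kind == "lognormal":
            return np.exp(rng.normal(self.mu, self.sigma, size=size))
        return rng.exponential(1.0 / self.lam, size=size)

    def mass(self, lo: float, hi: float) -> float:
        d = self._dist()
        return float(d.cdf(hi) - d.cdf(lo))


@dataclass
class PriorSpec:
    """Priors for an analysis: one Prior per free rate + flat Dirichlet rows."""

    rates: list
    dirichlet_concentration: float = 1.0   # all-ones Dirichlet on table rows

    def logpdf_rates(self, rates: np.ndarray) -> float:
        return float(sum(p.logpdf(r) for p, r in zip(self.rates, rates)))

    def sample_rates(self, rng: np.random.Generator) -> np.ndarray:
        return np.array([p.sample(rng) for p in self.rates])


def empirical_bayes_priors(mle: np.ndarray, threshold: float = 0.01,
                           sigma: float = 1.0, lam: float = 100.0) -> PriorSpec:
    """Empirical-Bayes priors centered on the MLE.

    LogNormal(log MLE, 1) when the MLE exceeds ``threshold`` (median = MLE,
    ~98% of mass between MLE/10 and 10*MLE); Exponential(lam=100) otherwise.
    """
    priors = []
    for m in np.asarray(mle, dtype=float):
        if m < 0:
            raise ValueError("negative MLE")
        if m > threshold:
            priors.append(Prior("lognormal", mu=math.log(m), sigma=sigma))
        else:
            priors.append(Prior("exponential", lam=lam))
    return PriorSpec(priors)


def low_rates_priors(n: int, lam: float = 100.0) -> PriorSpec:
    """The low-rates (LR) prior: Exponential(lam=100) on every rate."""
    return PriorSpec([Prior("exponential", lam=lam) for _ in range(n)])


def gamma_age_prior_mass(mean: float, sd: float, lo: float, hi: float) -> float:
    """Mass a Gamma(mean, sd) node-age prior places on [lo, hi] Ma.

    Used to sanity-check dating priors, e.g. a root prior with mean 2639 Ma
    and SD 179 Myr should put ~95% of its density in 2300-3000 Ma.
    """
    shape = (mean / sd) ** 2
    scale = sd ** 2 / mean
    d = scipy.stats.gamma(a=shape, scale=scale)
    return float(d.cdf(hi) - d.cdf(lo))


# ---------------------------------------------------------------------------
# Pruning


def _prune(tree: DatedTree, P: np.ndarray, tips: np.ndarray,
           root_prior: np.ndarray, return_partials: bool = False):
    """Pruning pass. P: (n_nodes, s, s) per-branch transition matrices;
    tips: (n_nodes, s) partials (rows only meaningful at tips)."""
    n, s = tips.shape
    partial = np.empty((n, s))
    logscale = 0.0
    for v in tree.postorder:
        if tree.is_tip[v]:
            partial[v] = tips[v]
        else:
            acc = np.ones(s)
            for c in tree.children[v]:
                acc = acc * (P[c] @ partial[c])
            m = acc.max()
            if m <= 0:
                return -np.inf if not return_partials else (-np.inf, partial)
            acc /= m
            logscale += math.log(m)
            partial[v] = acc
    lik = float(root_prior @ partial[tree.root])
    if lik <= 0:
        ll = -np.inf
    else:
        ll = math.log(lik) + logscale
    if return_partials:
        return ll, partial
    return ll


class _CharCache:
    """Per-tree, per-character precomputation (tip partials, branch lengths)."""

    def __init__(self, tree: DatedTree, char: MarkovCharacter):
        self.bl = tree.branch_lengths
        s = char.model.space.size
        self.tips = np.ones((tree.n_nodes, s))
        part = char.data.partials([tree.labels[i] for i in tree.tip_indices])
        self.tips[tree.tip_indices] = part


class Analysis:
    """A joint model bound to data: Markov characters (+ optional conditioned
    focal character) on a sample of dated trees.

    The free rate parameters of all characters are concatenated into one
    vector; ``slices`` maps characters to their segment of that vector.
    """

    def __init__(self, tree_sample: TreeSample, chars: list,
                 conditioned: ConditionedModel | None = None,
                 focal_data: CharacterMatrix | None = None):
        if isinstance(tree_sample, DatedTree):
            tree_sample = TreeSample([tree_sample])
        self.tree_sample = tree_sample
        self.chars = list(chars)
        self.conditioned = conditioned
        self.focal_data = focal_data
        if (conditioned is None) != (focal_data is None):
            raise ValueError("conditioned model and focal data go together")
        if conditioned is not None:
            expect = tuple(
                itertools_product_labels([c.model.space for c in self.chars]))
            if tuple(conditioned.space.labels) != expect:
                raise ValueError(
                    "conditioned space must be the product of the Markov "
                    "character spaces in declared order")
        taxa = tree_sample.taxon_labels
        for c in self.chars:
            missing = taxa - c.data.taxa
            if missing:
                raise KeyError(
                    f"character {c.name}: missing taxa {sorted(missing)[:5]}")
        self.slices = []
        k = 0
        for c in self.chars:
            self.slices.append(slice(k, k + c.model.n_free))
            k += c.model.n_free
        self.n_rates = k
        self._cache: dict = {}

    # -- bookkeeping --------------------------------------------------------

    def _tree_cache(self, ti: int):
        if ti not in self._cache:
            tree = self.tree_sample[ti]
            per_char = [_CharCache(tree, c) for c in self.chars]
            cond = None
            if self.conditioned is not None:
                cond = self._conditioned_cache(tree)
            self._cache[ti] = (tree, per_char, cond)
        return self._cache[ti]

    def _conditioned_cache(self, tree: DatedTree):
        """Per-tip indices into the joint conditioning space + focal obs mask."""
        spaces = [c.model.space for c in self.chars]
        joint_labels = {lab: i for i, lab in
                        enumerate(self.conditioned.space.labels)}
        falpha = self.conditioned.focal_alphabet
        tip_rows = []
        ambiguous = False
        for v in tree.tip_indices:
            taxon = tree.labels[v]
            obs_sets = [self.chars[k].data.states[taxon] for k in range(len(spaces))]
            if any(len(o) > 1 for o in obs_sets):
                ambiguous = True
            import itertools as _it
            joint_idx = [joint_labels[_joint_label(combo, spaces)]
                         for combo in _it.product(*[sorted(o) for o in obs_sets])]
            fobs = self.focal_data.states[taxon]
            fmask = np.array([1.0 if f in fobs else 0.0 for f in falpha])
            tip_rows.append((v, joint_idx, fmask))
        return tip_rows, ambiguous

    def split_rates(self, rates: np.ndarray) -> list:
        return [np.asarray(rates, dtype=float)[sl] for sl in self.slices]

    def generators(self, rates: np.ndarray) -> list:
        return [build_rate_matrix(c.model.with_rates(r))
                for c, r in zip(self.chars, self.split_rates(rates))]

    # -- likelihood ---------------------------------------------------------

    def loglik(self, rates: np.ndarray, table: np.ndarray | None = None,
               tree_index: int = 0, return_root: bool = False):
        """Natural-log likelihood on one tree of the sample."""
        tree, caches, cond = self._tree_cache(tree_index)
        Qs = self.generators(rates)
        Ps = [transition_matrices(Q, cc.bl) for Q, cc in zip(Qs, caches)]
        priors = [c.root.resolve(Q) for c, Q in zip(self.chars, Qs)]

        if self.conditioned is None:
            total = 0.0
            root_post = []
            for c, cc, P, pi in zip(self.chars, caches, Ps, priors):
                if return_root:
                    ll, part = _prune(tree, P, cc.tips, pi, return_partials=True)
                    num = pi * part[tree.root]
                    root_post.append(num / num.sum() if num.sum() > 0 else num)
                else:
                    ll = _prune(tree, P, cc.tips, pi)
                total += ll
            if not np.isfinite(total) and total != -np.inf:
                raise FloatingPointError("non-finite likelihood")
            return (total, root_post) if return_root else total

        table = self.conditioned.table if table is None else np.asarray(table)
        if table is None:
            raise ValueError("conditioned model has no table")
        tip_rows, ambiguous = cond
        if not ambiguous:
            total = 0.0
            for c, cc, P, pi in zip(self.chars, caches, Ps, priors):
                total += _prune(tree, P, cc.tips, pi)
            for _v, joint_idx, fmask in tip_rows:
                p = float(table[joint_idx[0]] @ fmask)
                if p <= 0:
                    return -np.inf
                total += math.log(p)
            return total
        return self._loglik_joint(tree, caches, Ps, priors, table, tip_rows)

    def _loglik_joint(self, tree, caches, Ps, priors, table, tip_rows):
        """Exact likelihood with ambiguous conditioning tips: pruning on the
        product chain (transition matrices are Kronecker products)."""
        sizes = [c.model.space.size for c in self.chars]
        S = int(np.prod(sizes))
        n = tree.n_nodes
        Pj = np.ones((n, 1, 1))
        for P in Ps:
            Pj = np.einsum("nij,nkl->nikjl", Pj, P).reshape(
                n, Pj.shape[1] * P.shape[1], Pj.shape[2] * P.shape[2])
        pij = priors[0]
        for p in priors[1:]:
            pij = np.kron(pij, p)
        tips = np.ones((n, S))
        for k, (cc, sz) in enumerate(zip(caches, sizes)):
            rep_after = int(np.prod(sizes[k + 1:]))
            rep_before = int(np.prod(sizes[:k]))
            expand = np.repeat(np.tile(cc.tips, (1, rep_before)), rep_after, axis=1)
            tips *= expand
        focal_factor = np.ones((n, S))
        for v, _joint_idx, fmask in tip_rows:
            focal_factor[v] = table @ fmask
        tips *= focal_factor
        return _prune(tree, Pj, tips, pij)

    def loglik_marginal(self, rates, table=None) -> float:
        """Log mean likelihood over the (weighted) tree sample."""
        lls = np.array([self.loglik(rates, table, ti)
                        for ti in range(len(self.tree_sample))])
        w = self.tree_sample.weights
        return float(scipy.special.logsumexp(lls, b=w))

    # -- closed-form table MLE ---------------------------------------------

    def table_counts(self, tree_index: int = 0) -> np.ndarray:
        """Per-row focal-state counts (unambiguous conditioning tips only)."""
        cm = self.conditioned
        counts = np.zeros((cm.n_rows, len(cm.focal_alphabet)))
        _tree, _caches, (tip_rows, _amb) = self._tree_cache(tree_index)
        for _v, joint_idx, fmask in tip_rows:
            if len(joint_idx) == 1 and fmask.sum() == 1:
                counts[joint_idx[0], int(np.argmax(fmask))] += 1
        return counts


def _joint_label(combo, spaces):
    """Flatten a per-character state combination into one joint label."""
    out = []
    for c in combo:
        if isinstance(c, tuple):
            out.extend(c)
        else:
            out.append(c)
    return tuple(out) if len(out) > 1 else out[0]


def itertools_product_labels(spaces):
    """Labels of the product of several state spaces, flattened like
    StateSpace.product of the underlying binary components."""
    import itertools as _it
    for combo in _it.product(*[s.labels for s in spaces]):
        yield _joint_label(combo, spaces)


def tree_likelihood(tree, chars, conditioned=None, focal_data=None,
                    table=None, rates=None) -> float:
    """Log-likelihood of the joint model on one dated tree.

    ``rates`` defaults to the rates stored on the character models.
    """
    an = Analysis(tree, chars, conditioned, focal_data)
    if rates is None:
        rates = np.concatenate([c.model.rates for c in chars])
    return an.loglik(rates, table=table)


# ---------------------------------------------------------------------------
# Maximum likelihood


@dataclass
class MLEResult:
    rates: np.ndarray
    table: np.ndarray | None
    loglik: float
    converged: bool
    n_evals: int = 0


def mle_fit(trees, chars, conditioned=None, focal_data=None,
            n_starts: int = 5, seed: int = 0, maxiter: int = 500,
            rate_max: float = RATE_OPT_HI) -> MLEResult:
    """Multi-start Nelder-Mead maximization on log-rates.

    With a conditioned model and unambiguous conditioning tips the table MLE
    is closed form (row-wise multinomial proportions) and independent of the
    rates; otherwise table rows are optimized jointly via logits.
    """
    an = trees if isinstance(trees, Analysis) else \
        Analysis(trees, chars, conditioned, focal_data)
    rng = np.random.default_rng(seed)
    multi_tree = len(an.tree_sample) > 1

    table = None
    opt_table = False
    if an.conditioned is not None:
        _t, _c, (tip_rows, ambiguous) = an._tree_cache(0)
        if not ambiguous or all(len(j) == 1 for _v, j, _f in tip_rows):
            counts = an.table_counts(0)
            table = np.where(counts.sum(axis=1, keepdims=True) > 0,
                             counts / np.maximum(counts.sum(axis=1, keepdims=True), 1e-300),
                             1.0 / counts.shape[1])
        else:
            opt_table = True
            table = np.full((an.conditioned.n_rows,
                             len(an.conditioned.focal_alphabet)),
                            1.0 / len(an.conditioned.focal_alphabet))

    nr = an.n_rates
    n_tab = 0 if not opt_table else table.size

    def unpack(x):
        rates = np.exp(np.clip(x[:nr], math.log(RATE_LO), math.log(rate_max)))
        tab = table
        if opt_table:
            logits = x[nr:].reshape(table.shape)
            tab = np.exp(logits - logits.max(axis=1, keepdims=True))
            tab /= tab.sum(axis=1, keepdims=True)
        return rates, tab

    n_evals = 0

    def nll(x):
        nonlocal n_evals
        n_evals += 1
        rates, tab = unpack(x)
        ll = an.loglik_marginal(rates, tab) if multi_tree else \
            an.loglik(rates, tab, 0)
        return -ll if np.isfinite(ll) else 1e12

    # starts: a tree-length-scale guess plus log-uniform draws
    tl = an.tree_sample[0].total_branch_length
    base = np.full(nr, math.log(max(2.0 / max(tl, 1e-12), 1e-6)))
    starts = [base]
    for _ in range(max(n_starts - 1, 0)):
        starts.append(rng.uniform(math.log(1e-5), math.log(rate_max), size=nr))
    best = None
    converged = False
    for s0 in starts:
        x0 = np.concatenate([s0, np.zeros(n_tab)])
        res = scipy.optimize.minimize(nll, x0, method="Nelder-Mead",
                                      options={"maxiter": maxiter * (nr + n_tab + 1),
                                               "xatol": 1e-6, "fatol": 1e-9})
        if best is None or res.fun < best.fun:
            best = res
        converged = converged or bool(res.success)
    rates, tab = unpack(best.x)
    result = MLEResult(rates, tab, -float(best.fun), converged, n_evals)
    if not converged:
        raise RuntimeError(
            f"optimizer failed to converge after {n_starts} restarts "
            f"(best log-likelihood {result.loglik:.6g})", result)
    return result


# ---------------------------------------------------------------------------
# MCMC


@dataclass
class PosteriorSample:
    """Thinned posterior draws plus chain metadata."""

    tree_indices: np.ndarray
    rates: np.ndarray                  # (n_draws, n_rates)
    tables: np.ndarray | None          # (n_draws, rows, focal) or None
    slices: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.tree_indices)


def effective_sample_size(x: np.ndarray) -> float:
    """ESS via Geyer's initial positive sequence estimator."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1:] / (np.arange(n, 0, -1) * np.var(x))
    tau = 1.0
    for t in range(1, n // 2):
        pair = acf[2 * t - 1] + acf[2 * t] if 2 * t < n else acf[2 * t - 1]
        if pair < 0:
            break
        tau += 2 * pair
    return float(n / max(tau, 1.0))


def mcmc_sample(tree_sample, chars, priors: PriorSpec,
                conditioned=None, focal_data=None, *,
                n_iter: int = 20000, burn_in: float = 0.25,
                n_draws: int = 1000, seed: int = 0, power: float = 1.0,
                step: float = 0.6, ess_floor: float = 100.0,
                init_rates: np.ndarray | None = None) -> PosteriorSample:
    """Metropolis-Hastings sampling of rates, tables and the tree index.

    Rates get multiplier (log-normal-walk) proposals with per-parameter step
    adaptation during burn-in; conditional-probability-table rows get
    conjugate Gibbs updates Dirichlet(1 + power*counts) when the conditioning
    tips are unambiguous (MH Dirichlet proposals otherwise); the tree index
    is resampled uniformly. ``power`` tempers the likelihood (stepping
    stone). Deterministic under ``seed``.
    """
    an = tree_sample if isinstance(tree_sample, Analysis) else \
        Analysis(tree_sample, chars, conditioned, focal_data)
    rng = np.random.default_rng(seed)
    nr = an.n_rates
    n_trees = len(an.tree_sample)

    rates = np.asarray(init_rates, dtype=float) if init_rates is not None \
        else priors.sample_rates(rng)
    table = None
    gibbs_table = False
    if an.conditioned is not None:
        rows, nf = an.conditioned.n_rows, len(an.conditioned.focal_alphabet)
        table = rng.dirichlet(np.ones(nf), size=rows)
        _t, _c, (tip_rows, ambiguous) = an._tree_cache(0)
        gibbs_table = not ambiguous
    ti = int(rng.integers(n_trees))

    cur_ll = an.loglik(rates, table, ti)
    cur_lp = priors.logpdf_rates(rates)
    steps = np.full(nr, step)
    acc = np.zeros(nr)
    prop = np.zeros(nr)
    acc_tree = prop_tree = 0
    n_burn = int(n_iter * burn_in)
    keep_at = np.unique(np.linspace(n_burn, n_iter - 1, n_draws).astype(int))
    out_ti, out_rates, out_tables = [], [], []

    counts_cache = an.table_counts(0) if gibbs_table else None

    for it in range(n_iter):
        # rate update (one random parameter, multiplier proposal)
        if nr > 0:
            j = int(rng.integers(nr))
            prop[j] += 1
            new = rates.copy()
            fac = math.exp(steps[j] * rng.normal())
            new[j] = rates[j] * fac
            if RATE_LO <= new[j] <= RATE_HI:
                new_ll = an.loglik(new, table, ti)
                new_lp = priors.logpdf_rates(new)
                # multiplier proposal Hastings term: log(new/old) = log(fac)
                logr = power * (new_ll - cur_ll) + (new_lp - cur_lp) + math.log(fac)
                if math.log(rng.random() + 1e-300) < logr:
                    rates, cur_ll, cur_lp = new, new_ll, new_lp
                    acc[j] += 1
            if it < n_burn and prop[j] > 0 and prop[j] % 50 == 0:
                r = acc[j] / prop[j]
                steps[j] *= math.exp(0.5 * (r - 0.3))
                steps[j] = min(max(steps[j], 0.01), 5.0)

        # table update
        if table is not None and rng.random() < 0.5:
            if gibbs_table:
                conc = 1.0 + power * counts_cache
                table = np.vstack([rng.dirichlet(conc[r]) for r in range(len(conc))])
                cur_ll = an.loglik(rates, table, ti)
            else:
                r = int(rng.integers(table.shape[0]))
                c0 = 100.0 * table[r] + 0.5
                newrow = rng.dirichlet(c0)
                c1 = 100.0 * newrow + 0.5
                newtab = table.copy()
                newtab[r] = newrow
                new_ll = an.loglik(rates, newtab, ti)
                logr = power * (new_ll - cur_ll) \
                    + scipy.stats.dirichlet.logpdf(np.clip(table[r], 1e-12, None) /
                                                   np.clip(table[r], 1e-12, None).sum(), c1) \
                    - scipy.stats.dirichlet.logpdf(np.clip(newrow, 1e-12, None) /
                                                   np.clip(newrow, 1e-12, None).sum(), c0)
                if math.log(rng.random() + 1e-300) < logr:
                    table, cur_ll = newtab, new_ll

        # tree index update
        if n_trees > 1:
            prop_tree += 1
            tj = int(rng.integers(n_trees))
            if tj != ti:
                new_ll = an.loglik(rates, table, tj)
                if math.log(rng.random() + 1e-300) < power * (new_ll - cur_ll):
                    ti, cur_ll = tj, new_ll
                    acc_tree += 1

        if it in keep_at:
            out_ti.append(ti)
            out_rates.append(rates.copy())
            if table is not None:
                out_tables.append(table.copy())

    rates_arr = np.array(out_rates) if out_rates else np.zeros((0, nr))
    ess = [effective_sample_size(rates_arr[:, j]) for j in range(nr)]
    meta = {
        "seed": seed, "n_iter": n_iter, "burn_in": n_burn,
        "acceptance": (acc / np.maximum(prop, 1)).tolist(),
        "tree_acceptance": acc_tree / max(prop_tree, 1),
        "ess": ess, "power": power,
        "warnings": ([f"ESS below floor {ess_floor}"]
                     if ess and min(ess) < ess_floor else []),
    }
    return PosteriorSample(np.array(out_ti, dtype=int), rates_arr,
                           np.array(out_tables) if out_tables else None,
                           an.slices, meta)


# ---------------------------------------------------------------------------
# Stepping stone


def stepping_stone_logml(tree_sample, chars, priors: PriorSpec,
                         conditioned=None, focal_data=None, *,
                         n_rungs: int = 32, samples_per_rung: int = 1000,
                         burn_per_rung: float = 0.25, alpha: float = 0.3,
                         seed: int = 0):
    """Stepping-stone estimate of log P(D | m) and its Monte-Carlo SE.

    Power ladder beta_k = (k/K)^(1/alpha) (quantiles of Beta(alpha, 1));
    rungs are sampled with short tempered chains warm-started from the
    previous rung; the beta=0 rung draws i.i.d. from the prior. The log
    marginal likelihood is the sum over rungs of the log mean importance
    ratio log mean_i L(theta_i)^(beta_{k+1} - beta_k).
    """
    if n_rungs < 8:
        raise ValueError("need at least 8 stepping-stone rungs")
    an = tree_sample if isinstance(tree_sample, Analysis) else \
        Analysis(tree_sample, chars, conditioned, focal_data)
    rng = np.random.default_rng(seed)
    betas = (np.arange(n_rungs + 1) / n_rungs) ** (1.0 / alpha)
    n_trees = len(an.tree_sample)

    logml = 0.0
    var_total = 0.0
    init = None
    for k in range(n_rungs):
        bk, bk1 = betas[k], betas[k + 1]
        lls = np.empty(samples_per_rung)
        if bk == 0.0:
            # i.i.d. prior draws (tree index uniform; table rows flat Dirichlet)
            for i in range(samples_per_rung):
                r = priors.sample_rates(rng)
                tab = None
                if an.conditioned is not None:
                    tab = rng.dirichlet(
                        np.ones(len(an.conditioned.focal_alphabet)),
                        size=an.conditioned.n_rows)
                ti = int(rng.integers(n_trees))
                lls[i] = an.loglik(r, tab, ti)
            init = priors.sample_rates(rng)
        else:
            n_iter = int(samples_per_rung / (1 - burn_per_rung)) + 2
            ps = mcmc_sample(an, None, priors, power=bk, n_iter=n_iter,
                             burn_in=burn_per_rung,
                             n_draws=samples_per_rung,
                             seed=int(rng.integers(2**31 - 1)),
                             init_rates=init)
            lls = np.array([an.loglik(ps.rates[i],
                                      ps.tables[i] if ps.tables is not None else None,
                                      int(ps.tree_indices[i]))
                            for i in range(len(ps))])
            init = ps.rates[-1] if len(ps.rates) else init
        db = bk1 - bk
        w = db * lls
        w = w[np.isfinite(w)]
        if len(w) == 0:
            raise RuntimeError(f"stepping-stone rung {k}: no finite samples")
        mx = w.max()
        ratios = np.exp(w - mx)
        mean_r = ratios.mean()
        logml += mx + math.log(mean_r)
        ess = effective_sample_size(ratios)
        var_total += float(np.var(ratios) / (mean_r ** 2 * max(ess, 1.0)))
    return float(logml), math.sqrt(var_total)


# ---------------------------------------------------------------------------
# Model weights and averaging


@dataclass
class ModelWeights:
    names: list
    logml: np.ndarray
    prior: np.ndarray
    posterior: np.ndarray
    aic: np.ndarray | None = None
    bic: np.ndarray | None = None
    aic_weights: np.ndarray | None = None
    bic_weights: np.ndarray | None = None
    warnings: list = field(default_factory=list)

    def blend(self, summaries) -> float | np.ndarray:
        """Model-averaged summary: sum_m w_m * summary_m."""
        summaries = np.asarray(summaries, dtype=float)
        return np.tensordot(self.posterior, summaries, axes=(0, 0))


def _ic_weights(scores: np.ndarray) -> np.ndarray:
    d = scores - np.min(scores)
    w = np.exp(-0.5 * d)
    return w / w.sum()


def information_criteria(loglik: np.ndarray, k: np.ndarray, n: int):
    """AIC = 2k - 2 lnL, BIC = k ln n - 2 lnL, and their weights."""
    loglik = np.asarray(loglik, dtype=float)
    k = np.asarray(k, dtype=float)
    aic = 2 * k - 2 * loglik
    bic = k * math.log(n) - 2 * loglik
    return aic, bic, _ic_weights(aic), _ic_weights(bic)


def model_weights_and_average(logmls, names=None, prior=None,
                              loglik=None, k=None, n=None) -> ModelWeights:
    """Posterior model probabilities P(m|D) ∝ exp(log ml) * P(m).

    Uniform model prior by default. Non-finite marginal likelihoods exclude
    the model (weight 0) with a warning. If ``loglik``/``k``/``n`` are given,
    AIC/BIC and their weights are also computed.
    """
    logmls = np.asarray(logmls, dtype=float)
    m = len(logmls)
    if m < 2:
        raise ValueError("model averaging needs at least 2 models")
    names = list(names) if names is not None else [f"m{i}" for i in range(m)]
    prior = np.full(m, 1.0 / m) if prior is None else np.asarray(prior, float) / np.sum(prior)
    warnings = []
    ok = np.isfinite(logmls)
    if not ok.all():
        warnings.append(f"excluded models with non-finite log-ml: "
                        f"{[names[i] for i in np.flatnonzero(~ok)]}")
    z = np.full(m, -np.inf)
    z[ok] = logmls[ok] + np.log(prior[ok])
    z -= z[ok].max()
    post = np.where(ok, np.exp(z), 0.0)
    post /= post.sum()
    mw = ModelWeights(names, logmls, prior, post, warnings=warnings)
    if loglik is not None and k is not None and n is not None:
        mw.aic, mw.bic, mw.aic_weights, mw.bic_weights = \
            information_criteria(loglik, k, n)
    return mw


# ---------------------------------------------------------------------------
# Rate-grid scan


def rate_grid_scan(tree, chars, grid1, grid2, *, nats=(2.0, 5.0, 10.0)):
    """Log-likelihood and root-state posterior over a 2-parameter log grid.

    ``chars`` must expose exactly 2 free rates. Returns a dict with the
    grids, the log-likelihood surface, the per-cell root posterior and
    boolean masks flagging cells within 2/5/10 natural-log units of the grid
    maximum.
    """
    an = Analysis(tree, chars)
    if an.n_rates != 2:
        raise ValueError("rate_grid_scan needs exactly 2 free parameters")
    g1 = np.asarray(grid1, dtype=float)
    g2 = np.asarray(grid2, dtype=float)
    ll = np.empty((len(g1), len(g2)))
    s = an.chars[0].model.space.size
    root = np.empty((len(g1), len(g2), s))
    for i, a in enumerate(g1):
        for j, b in enumerate(g2):
            l, rp = an.loglik(np.array([a, b]), return_root=True)
            ll[i, j] = l
            root[i, j] = rp[0]
    mx = np.nanmax(ll)
    flags = {f"within_{int(v)}": (ll >= mx - v) for v in nats}
    return {"grid1": g1, "grid2": g2, "loglik": ll, "root_posterior": root,
            "max_loglik": float(mx), **flags}
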