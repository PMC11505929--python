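# Methods

## Model

Each discrete character evolves along a rooted, dated tree under a
continuous-time Markov chain. Ages are in Ma before present (root oldest,
tips at 0), branch lengths in Myr, and all rates in events per Myr; these
units make an exponential prior with λ = 100 (mass concentrated below
0.05/Myr) a meaningful "rare transitions" prior on geological time scales.
The generator Q has non-negative off-diagonal rates and zero row sums.
Parameterizations: ER (one shared rate), SYM (one rate per unordered state
pair, (s²−s)/2 free parameters), ARD (one per ordered pair, s²−s), and UNI
(a single nonzero rate, used only for biologically one-way hypotheses).
Rates are assumed constant through time and across lineages — with one
observation per taxon per character there is no information to estimate
branch-specific rates.

Several binary genes of one biosynthetic pathway can be merged into a
supercharacter on the product state space, ordered lexicographically with
gene order as declared (for two genes: AA, AP, PA, PP — the gain/loss/
exchange rate classes index into this order). Independent blocks combine
as a Kronecker sum, so simultaneous changes have rate zero; dependent
blocks get a full ER/SYM/ARD parameterization of the product space,
allowing correlated gains and losses. Candidate model spaces enumerate the
set partitions of the genes into dependency blocks with one tag applied
uniformly across blocks; SYM is offered only when some block has more than
two states (on two states SYM coincides with ER). This yields 5 candidates
for 2 genes and 14 for 3.

The focal character (habitat preference) can instead be *conditioned*: it
has no rates of its own, and its state is drawn from a conditional
probability table π(focal | joint conditioning state). The likelihood then
factorizes into the Markov characters' pruning likelihoods times per-tip
table factors; when conditioning tip states are ambiguous the exact sum is
computed by pruning on the product chain, whose transition matrices are
Kronecker products of the per-character matrices (no large matrix
exponentials are needed).

## Inference

*Likelihood.* Felsenstein pruning with per-node rescaling. Transition
matrices use the closed form for two states and an eigendecomposition for
larger state spaces, falling back to scaling-and-squaring (Padé) `expm`
when the eigenreconstruction error exceeds 1e−8; rows are clipped to be
non-negative and renormalized (errors are at the 1e−12 level).

*Root prior.* Uniform over states by default; stationary or fixed vectors
are available (`RootPrior`). Deep-time ancestral-state estimates can be
sensitive to this choice, which is why it is exposed rather than fixed.

*Maximum likelihood.* Multi-start Nelder–Mead on log-rates (default 5
starts: one at a tree-length-scale heuristic, the rest log-uniform).
Bounds are [1e−9, 0.1] per Myr: on Ma-dated trees the likelihood is flat
above the saturation rate, and allowing the optimizer to wander up that
plateau would center the empirical-Bayes prior on a degenerate region
whose posterior draws produce astronomically long mapped histories. The
cap is overridable (`mle_fit(rate_max=...)`). Conditional-probability
tables have a closed-form MLE (row-wise multinomial proportions) when
conditioning tips are unambiguous; otherwise the rows are optimized
jointly via logits.

*Priors.* Empirical Bayes: LogNormal(log MLE, σ = 1) per rate — median at
the MLE, ≈98% of the mass within a factor of 10 either way — switching to
Exponential(λ = 100) when the MLE is ≤ 0.01/Myr (a rate that small is not
reliably located, and the exponential keeps mass near zero without pinning
the prior to noise). Flat Dirichlet on each table row.

*MCMC.* Metropolis–Hastings: multiplier proposals on one randomly chosen
rate per iteration with per-parameter step-size adaptation toward 30%
acceptance during burn-in (25%); conjugate Gibbs updates
Dirichlet(1 + β·counts) for table rows when conditioning tips are
unambiguous (MH Dirichlet proposals otherwise); and uniform resampling of
the tree index, treating the dated-tree sample as equally weighted draws
from the dating posterior, so all downstream summaries integrate over
divergence-time uncertainty. Chains are deterministic given the seed;
acceptance rates and Geyer initial-positive-sequence effective sample
sizes are reported in the chain metadata, with low ESS recorded as a
warning rather than a failure.

*Marginal likelihoods.* Stepping-stone sampling on the power ladder
β_k = (k/K)^(1/0.3) (quantiles of Beta(0.3, 1), concentrating rungs near
the prior), K = 32 rungs by default with 10⁴ samples per rung; the β = 0
rung is sampled i.i.d. from the prior and subsequent rungs warm-start from
the previous one. The estimator sums per-rung log mean importance ratios;
a delta-method Monte-Carlo SE (using the ratio ESS) is returned. For
independent multi-gene models the joint analysis's log marginal likelihood
equals the sum of the per-gene ones. Model posterior probabilities use a
uniform model prior; AIC/BIC and their weights are computed alongside
where ML fits exist.

## Stochastic mapping

Joint node states are drawn from the pruning partials (root ∝ prior ×
partial, then a pre-order descent); ambiguous tips are resolved jointly in
that draw rather than fixed beforehand. Branch paths are endpoint-
conditioned CTMC draws by uniformization with Ω = 1.05·max|q_ii| (small
virtual-jump overhead, numerically safe): the virtual-jump count is drawn
from its conditional law, the jump chain is sampled conditioned on the
endpoint, jump times are uniform order statistics, and self-jumps are
dropped. Two-state chains use closed-form powers of the uniformized matrix
in plain floats — this is the innermost loop of every analysis. A
forward-simulation rejection sampler provides an independent oracle and is
distribution-checked against uniformization in the tests.

The conditioned focal character is overlaid on the mapped conditioning
characters: the joint conditioning state is piecewise constant on the
tree; each maximal constant region receives one focal state drawn from the
matching table row (a region crossing a node keeps its drawn state), and
the segment abutting each tip is clamped to the observed focal state. The
exact path-level semantics between conditioning change-points is a
modeling choice — this one reproduces the factorized likelihood and gives
branch-wise focal posteriors — and it is isolated in one function
(`overlay_conditioned`) so alternatives can be swapped in.

## D-test

For each paired history draw, dwell-time fractions are computed by merging
segment boundaries branch-wise: A_ij is the fraction of total tree length
jointly spent in states (i, j), with marginals a_i, b_j. The reported
statistics are d_ij = mean over draws of (A_ij − a_i b_j), in percent, and
D = Σ_ij |d_ij|; positive d_ij means the states co-occur more than
expected under independence. For binary characters the zero-sum structure
forces d_11 = d_22 = −d_12 = −d_21, D = 4|d_11|, and identical per-cell
P-values — these identities are asserted in the tests.

Significance is posterior-predictive. Because the observed statistic
averages over map draws that share one observed dataset, a fair null
replicate must be built the same way: simulate a null dataset (both
characters evolving independently under one posterior parameter/tree
draw), re-map it conditioned on its own simulated tips, and average the
deviations of an inner sample of maps (default 8; 20 in the calibration
study). Comparing the averaged observed statistic against single
unconditioned simulations — the obvious simpler null — is badly
conservative: measured over 60 independent datasets its rejection rate at
the 5% level was 0%. With the nested null the measured rejection rate is
5.5% over 55 independent datasets, and strong coupling at 200 taxa is
detected (P < 5%) in 19/20 replicates. Raw P-values are reported with a
5% flag and no multiple-testing correction across characters; the ranking,
not the absolute level, drives the workflow.

## Summaries

Branches are matched across the tree sample by tip-set clade, so draws on
jittered or differing topologies aggregate correctly (a draw lacking a
clade simply does not contribute to it). Branch-time probabilities are
tabulated on a regular age grid (default 10 Myr) plus each node's own age,
so grid values at node ages equal the node posteriors exactly.
First-occurrence ages take, per draw, the oldest point at which any
lineage in scope satisfies a state predicate (the node age if satisfied at
the scope root; missing if never). Transition rates through time divide
direction-specific transition counts per age bin (default 100 Myr; the
binning itself is a presentation choice, and the width is exposed) by the
lineage-time in the bin expressed in lineage-Gyr. Gain/loss/exchange rate
sums are taken cell-wise from posterior generator draws after model
averaging; for 2-gene pathways G and L are anchored at the all-absent and
all-present states with E the exchange between incomplete states, while
3-gene pathways classify all cells by the functional-state predicate
(for the sucrose-like rule: the pathway is complete if the synthase gene
is present, or the phosphatase with the truncated synthase). HPD intervals
are the shortest contiguous window over sorted samples (defaults 89% and
95%), with a warning when the window is >10% shorter than the equal-mass
central interval — a crude multimodality flag that also fires on strongly
skewed unimodal samples, so it is advisory only.

## Synthetic data

The generator emulates a deep-time bacterial trait study: one birth–death
topology (default birth 1.0, death 0.3 — a moderately extinct clade)
conditioned on the taxon count and rescaled to a 3200-Ma root; replicate
trees by log-normal jitter of internal node ages (SD 0.05 log-units,
roughly ±10% age uncertainty) with the first tree kept unjittered as the
truth tree; characters simulated forward at rates near 10⁻³/Myr, the
scale implied by compatible-solute gene turnover on billion-year trees; a
conditioned focal character drawn from a known table (the coupled presets
use strong tables, 0.95/0.05, because the real habitat–glucosylglycerol
association this emulates is strong). Presets: `tiny` (8 taxa, 3 trees),
`small` (50 taxa, 10 trees, a 2-gene dependent pathway, two binary genes
and a coupled focal character), `study-scale` (189 taxa, 1000 trees, five
pathways and habitat). Tip data and the generating histories are both
returned; the true histories serve as oracles for the summary operations.

What passing tests on these data do *not* show: real gene-presence calls
carry genome-assembly noise and horizontal transfer violates the
tree-shaped model; real habitat assignments are coarse and sometimes
wrong; and real dating posteriors have correlated, calibration-driven age
errors rather than independent log-normal jitter. The synthetic results
validate the machinery, not the biology.

A note on identifiability at realistic scales: at ~10⁻³/Myr a binary
character is close to saturation on a 3200-Ma tree, so single 50-taxon
datasets can genuinely favor rates several-fold off the truth (we verified
by profiling the likelihood that these are true likelihood peaks, and
occasionally divergent MLEs). The recovery study therefore checks that the
*typical* posterior median across seeds is within a factor of 2 and that
credible intervals achieve nominal coverage, not that every dataset
recovers the rate.

## Workflow and reproducibility

The pipeline stages are: per-character analyses → D-test ranking against
the focal character → conditioned analysis including the top-ranked
characters (default 2, configurable; Bayesian sampling with up to 2
conditioning Markov characters, ML beyond that, since the joint model's
parameter count grows with the product state space) → summaries.
Combination weights for the conditioned analyses use exact stepping stone
when requested and feasible, and otherwise the per-character marginal-
likelihood differences, renormalized — justified by the near-additivity of
log marginal likelihoods across characters — with AIC/BIC weights reported
alongside. All stage seeds derive from one master seed; stages checkpoint
their numeric state to JSON so interrupted runs resume to byte-identical
reports. Default problem sizes for a full analysis are 5000 mapped
histories, up to 1000 trees, 32 stepping-stone rungs × 10⁴ samples; the
test suite and the examples scale these down (hundreds of histories, 8–24
rungs, tens of MCMC thousands) to keep runs in minutes on one core.
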