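# solutemap

Bayesian stochastic character mapping of habitat preference and
biosynthetic-pathway characters on dated phylogenies.

## The problem

Whether deep bacterial ancestors — cyanobacteria in particular — preferred
high-salinity (marine) or low-salinity (freshwater) habitats is hard to
infer from a single discrete "habitat" character: with realistic transition
rates the signal saturates over billions of years, and the answer depends
strongly on which transition model (equal-rates vs. all-rates-different)
and which priors are used. Habitat preference is, however, mechanistically
tied to the genes for compatible-solute biosynthesis (sucrose, trehalose,
glucosylglycerol, glucosylglycerate, glycine betaine): organisms that can
synthesize the stronger osmolytes can live in saltier water. This package
implements a workflow that exploits that link:

1. **Per-character analyses.** Each character (habitat, each pathway gene
   or gene block) evolves under a continuous-time Markov chain on a dated
   tree. Candidate parameterizations — equal-rates (ER), symmetrical
   (SYM), all-rates-different (ARD), unidirectional (UNI) — are fitted by
   maximum likelihood; empirical-Bayes priors (log-normal, centered on the
   MLE with σ = 1, or exponential with λ = 100 for MLEs ≤ 0.01) feed an
   MCMC sampler; marginal likelihoods from stepping-stone sampling give
   model posterior probabilities, and results are blended by Bayesian
   model averaging under a uniform model prior:

       P(H | D) = Σ_m P(H | D, m) · P(m | D)

2. **Multi-gene pathways.** Genes of one pathway can evolve independently
   (Kronecker-sum generator; no simultaneous changes) or as a dependent
   "supercharacter" on the product state space (5 candidate models for a
   2-gene pathway, 14 for a 3-gene pathway). Summed gain (G), loss (L) and
   exchange (E) rates and their ratios summarize the fitted generators.

3. **Correlation screening (D-test).** From paired stochastic maps, the
   deviation of joint dwell-time fractions from the independence
   expectation, d_ij = mean(A_ij − a_i·b_j), its total D = Σ|d_ij|, and
   posterior-predictive P-values rank candidate characters by the
   significance of their association with the focal character.

4. **Conditioned analysis.** The focal character is then modeled without
   rates of its own: its state is drawn from a conditional probability
   table π(focal | joint state of the conditioning characters), with a
   flat Dirichlet prior (or ML estimation for large joint models).
   Stochastic maps of the conditioning characters are overlaid with focal
   states segment by segment, clamped to observations at the tips.

5. **History post-processing.** Node and branch-time posterior state
   probabilities, the age of the first lineage in a given state (e.g. the
   first low-salinity lineage), transition rates through time (per lineage
   per Gyr) and highest-posterior-density intervals.

A synthetic-data module generates dated tree samples (birth–death topology,
Archean-scale root ages, log-normal node-age jitter emulating dating
uncertainty) and characters with known ground truth, so the whole pipeline
is testable end to end without any external data.

## Worked example

Analyze a synthetic habitat-preference character (true ER rate
3×10⁻⁴/Myr on an 8-taxon, 3-tree sample rooted near 3200 Ma):

```python
import numpy as np
from solutemap.synthetic_data import benchmark_dataset
from solutemap.pipeline import CharacterInput, PipelineConfig, single_character_pipeline
from solutemap.posterior_summaries import first_occurrence_ages

b = benchmark_dataset("tiny", seed=3)
ci = CharacterInput("habitat", {"habitat": b.matrices["habitat"]})
cfg = PipelineConfig(seed=1, n_mcmc_iter=5000, n_posterior_draws=300,
                     n_history_draws=500, ss_rungs=16, ss_samples=300)
res = single_character_pipeline(ci, b.tree_sample, cfg)
for c, lm, w, m in zip(res.candidates, res.logml,
                       res.weights.posterior, res.mle_rates):
    print(f"{c.describe():18s} logML={lm:8.3f}  mPP={w:.3f}  MLE={np.round(m, 5)}")
ev = first_occurrence_ages(res.histories, "habitat", lambda s: s == "H")
print("P(first high-salinity lineage predates 2460 Ma):",
      round(ev.prob_older_than(2460.0), 3))
```

prints

```
(habitat):ER       logML=  -4.742  mPP=0.678  MLE=[0.00092]
(habitat):ARD      logML=  -5.488  mPP=0.322  MLE=[0.00096 0.0009 ]
P(first high-salinity lineage predates 2460 Ma): 0.98
```

The simpler equal-rates model gets about two thirds of the model posterior
(the extra ARD rate buys too little likelihood to pay its marginal-
likelihood penalty); the model-averaged stochastic maps then say that in
98% of sampled histories some lineage already preferred high salinity
before 2460 Ma.

## Command line

```bash
solutemap simulate --preset small --seed 1 --out data/   # synthetic benchmark
solutemap validate data/trees.nwk                        # tree-sample checks
solutemap run config.yaml                                # full workflow
```

`solutemap run` executes the four workflow stages from a YAML config
(tree sample, character table, focal character, candidate characters) and
writes a JSON report plus TSV tables (node/branch posteriors, D-tests,
mapped histories); `--resume` reuses stage checkpoints.

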