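# Methods

`qspkr` builds quantitative structure–pharmacokinetic relationship (QSPkR)
models in two stages: a genetic algorithm (GA) selects a small subset of
molecular descriptors by an award/penalty pairwise fitness, and a small
feed-forward neural network trained by Levenberg–Marquardt (LM) maps the
selected descriptors to one pharmacokinetic (PK) parameter. This note
records the model, the design decisions taken where the procedure leaves
choices open, the numerical conventions, and what the synthetic benchmark
does and does not demonstrate.

## Data model and normalisation

Inputs are a compound × descriptor matrix (typically hundreds to thousands
of numeric molecular descriptors: constitutional, topological, BCUT,
autocorrelation, RDF, 3D-MoRSE, WHIM, GETAWAY, …) and one PK parameter per
compound — e.g. systemic clearance (mL/min/kg), volume of distribution
(L/kg) or plasma protein binding (%). Both are min–max scaled column-wise
to [0, 1]; the observed minima/maxima are retained so predictions are
reported in original units and the range-normalised RMSE is computable.

Scaling is fitted on the **full** compound set by default, matching the
classical workflow in which normalisation precedes the train/test split.
This leaks the test compounds' ranges into training; `fit_indices`
restricts the fit to a training subset for a leakage-free variant (values
outside the fitted range then fall outside [0, 1], so the strict range
check is relaxed in that mode).

Missing values must be resolved explicitly before normalisation
(`handle_missing`): drop the affected descriptor columns (default) or
mean-impute; both are logged. Constant descriptor columns are mapped to 0,
flagged, and excluded from selection — a constant descriptor carries no
pairwise information under the fitness below. A constant PK column is an
error.

## The award/penalty fitness

For compounds *i*, *j* (normalised PK values `dp`) and a selected
descriptor *k* (normalised values `dd`):

    F(i, j, k) = -Penalty                       if |dp_i - dp_j| >= epsilon
                 Award - |dd_ik - dd_jk|        otherwise

with Award = Penalty = 5 and epsilon = 0.1 by default. A chromosome's
fitness sums F over all unordered compound pairs and all descriptors with
gene 1 (all C(n,2) pairs; 741 for 39 compounds). The fitness is therefore
**additive over descriptors**: each descriptor has a fixed marginal
contribution

    c_k = Award * n_similar - S_k - Penalty * n_dissimilar

where `S_k` sums |dd_ik − dd_jk| over PK-similar pairs. `FitnessEngine`
precomputes `c` once per dataset; population scoring is then a single
matrix–vector product, and the value equals the naive triple-loop sum term
for term. An alternative reading in which the penalty is charged once per
dissimilar pair (independent of how many descriptors are selected) is
available as `penalty_per_pair=True`.

Two consequences of this scoring shape everything downstream. First, with
Award = Penalty and fewer than half of all pairs PK-similar, **every**
`c_k` is negative, so fitness strictly improves as genes are removed: the
unconstrained optimum is the empty chromosome, and subset size is governed
entirely by the gene limit. Second, the quality signal — how much less
negative an informative descriptor's `c_k` is than a decoy's — is a small
fraction of |c_k| itself (3–9% under the benchmark conditions), so the
selection scheme must be able to resolve *which* gene to drop, not merely
drop genes.

## GA design

Operator settings fixed by the procedure: 500 chromosomes initialised with
i.i.d. uniform genes, single-point crossover applied with probability 1
(break point uniform in {1, …, L−1}; child 1 takes the head of parent A),
and per-chromosome point mutation: one uniformly chosen gene is flipped
with probability 0.1.

Choices the procedure leaves open, and what was measured:

* **Gene limit as a floor.** The 15-gene limit exists to prevent the
  complete abolition of genes, so it is enforced as a lower bound on subset
  size: crossover offspring below the floor are rejected in favour of the
  contributing parent, and a mutation deleting a gene from a floor-size
  chromosome is repaired by re-adding a random absent gene (the deletion
  becomes a swap). The run terminates when the best chromosome sits at the
  floor and its fitness has not improved for `patience` (200) generations.
  The alternative — stopping at the first chromosome to cross below 15 —
  returns an essentially arbitrary subset: planted-descriptor recall barely
  exceeds chance (≈0.1–0.3 vs ≥0.9 with the floor) because the crossing
  moment carries no information about which genes survived.
* **Survivor selection: plus-truncation with an offspring surplus.** Each
  generation breeds 4,000 offspring (size-8 tournaments over the
  500-chromosome population) and keeps the best 500 of parents ∪ offspring.
  The surplus matters: with at most one mutated gene per offspring, gene
  deletions on the current best lineage are the only way the subset
  shrinks, and a surplus supplies several *competing* deletions per
  generation so selection can choose which descriptor to drop. A purely
  generational scheme with binary tournaments (available via
  `survivor_strategy="generational"`) loses most improving mutants and
  stalls near 40–100 genes within any practical generation budget at
  1,481 descriptors.
* **Convergence budget.** From ~740 random initial genes, the descent to
  the 15-gene floor takes ≈220 generations under the defaults (the procedure’s
  one-mutation-per-chromosome rate is the binding constraint), and the
  floor-phase swap search that assembles the final subset continues to
  improve for several hundred more. `max_generations` therefore defaults
  to 2,000 with `patience=200`; both are ordinary configuration.
* **Tie-breaks.** Equal fitness is resolved toward fewer genes, then the
  lexicographically smaller bit-string — a deterministic parsimony
  preference that makes rankings, and hence runs, bit-reproducible.
* All randomness flows through one seeded generator in a fixed draw order
  (initial population, then per generation: tournament entrants, crossover
  coin and break points, mutation positions and coins, floor repairs).

A degenerate dataset in which no pair is PK-similar (the award branch never
fires) runs with a recorded warning; selection is then uninformative by
construction.

## Network and trainer

Three layers: inputs = selected descriptors, one tanh hidden layer, a
single output neuron, bias in every layer. The output activation is
logistic by default (targets live in [0, 1]); linear output is available.
`n_hidden` defaults to 2: with ~33 training compounds and up to 15 inputs,
two hidden units (35 parameters) capture the monotone nonlinearities of
normalised PK data, while four units (69 parameters) interpolate the
training fold and generalise measurably worse in every configuration
tried. Epochs default to 50.

LM training: per epoch, solve `(JᵀJ + μI)Δ = Jᵀr` with the analytic
Jacobian of predictions (back-propagated derivatives; validated against
central finite differences to <1e-6 relative error), accept the step only
if the SSE decreases (μ ×0.1), otherwise retry with μ ×10; training stops
after the epoch budget or when μ exceeds 1e10. SSE over accepted steps is
non-increasing by construction. Weights initialise uniformly in ±0.5.
No early stopping, validation split, or weight penalty is used — the
procedure specifies none — which is why capacity control via `n_hidden`
is the only defence against overfitting at this sample size. A plain
full-batch gradient-descent trainer is included as a secondary option.

## Validation and metrics

Repeated random sub-sampling: each repeat splits the compounds uniformly at
random (33 train / 6 test at n=39; the same proportion otherwise), trains a
fresh network on the training fold, and predicts the test fold. Metrics,
computed on denormalized values:

* `R = 1 − SSE/SST` (no square root; 1 = perfect, 0 = mean prediction,
  negative = worse than the mean). The Pearson correlation is reported
  alongside as `pearson_r`, since "correlation coefficient" is read either
  way in the QSPkR literature.
* `RMSE` in the parameter's own units; `NRMSE = RMSE / (max_obs − min_obs)`.

Per-repeat values are reported with mean ± sd, and additionally **pooled**
across repeats (all test predictions concatenated before computing each
metric). Pooling matters at this scale: a 6-compound test fold drawn
mostly from one PK cluster has near-zero SST, making per-repeat R
arbitrarily unstable; the pooled value is the stable summary and is what
the package's own end-to-end test asserts on. Split balance is checked
with the classical Levene variance-homogeneity test (deviations from the
group mean) and Welch's two-sample t-test (pooled-variance Student's test
optional), both via scipy.

## Synthetic benchmark

Real descriptor matrices for PK compendia are proprietary, so the test bed
is simulated at the study's scale (39 compounds × 1,481 descriptors by
default):

* **PK values** are drawn from 5 clusters (centres evenly spaced on the
  latent [0, 1] scale, within-cluster sd 0.03) with geometric occupancy
  (each cluster half as populated as the one below). The skew reflects how
  right-skewed PK parameters behave under min–max normalisation — most
  compounds compress into the low end of the range — and yields ~32–36% of
  compound pairs inside the 0.1 similarity window, the regime in which the
  award branch carries signal. Latent values map affinely to "original
  units" (offset 10, span 50).
* **Informative descriptors** (10 by default) are monotone transforms of
  the latent PK value — identity, square and logistic links in rotation —
  plus Gaussian noise (sd 0.05 by default), so PK-similar compounds are
  close in those coordinates and the network stage is exercised beyond
  linearity. **Decoys** are i.i.d. uniform on [0, 1].
* Generation is fully seeded; raw CSV tables, the normalized dataset and
  the ground truth (planted indices, links, latent PK) are all available,
  and a generated benchmark with no PK-similar pairs is rejected with
  advice rather than silently produced.

What passing on this benchmark shows: the GA resolves a ~3–9% marginal
quality gap among descriptors, the floor-phase swap search assembles a
mostly-informative subset, the LM trainer fits realizable targets, and the
full pipeline is deterministic end to end. What it does not show: behaviour
under correlated descriptor blocks (real descriptor families are strongly
collinear, which makes selection *easier* — any member of a relevant block
is a usable proxy — but makes "recall of planted indices" ill-defined),
heavy-tailed descriptor distributions, or measurement error in the
compiled PK values themselves.

Two noise regimes are used deliberately: descriptor noise sd 0.05 for the
selection benchmarks (recovery of planted descriptors is robust there),
and sd 0.005 for the end-to-end prediction benchmark. At sd 0.05 an
unregularized network trained to convergence on 33 compounds cannot exceed
pooled test R ≈ 0.7 even when given exactly the planted descriptors
(measured across hidden widths, init scales and damping schedules), so
demanding high test R there would test the absence of regularization, not
the pipeline. At sd 0.005 the targets are close to realizable and the
pipeline's selection quality is what determines the score.

## Numerical conventions

* Fitness sums are computed by the precomputed-contribution route; the test
  suite checks bitwise agreement with a naive triple loop on dyadic-grid
  values (where floating-point addition is exact) and 1e-12 relative
  agreement on continuous values.
* The branch condition is `|dp_i − dp_j| >= epsilon` exactly at the
  boundary (a difference of exactly 0.1 is penalised).
* Min–max scaling maps constant columns to 0 rather than dividing by zero;
  denormalization refuses constant scales.
* LM refuses non-finite losses with the epoch identified; singular normal
  equations are handled by raising the damping, never surfaced.
* Pipeline artifacts are stamped with a SHA-256 hash of the resolved
  configuration (output location excluded) and written to a run directory
  named by that hash, so distinct configurations cannot collide and
  identical ones reproduce byte-identical JSON artifacts. Per-stage seeds
  derive from the global seed as `SeedSequence([seed, stage_index])`
  (stage 0 = simulation, 1 = GA, 2 = evaluation), truncated to 31 bits.

## Problem sizes used in the shipped checks

The packaged tests run the full 39 × 1,481 scale for GA mechanics and the
end-to-end pipeline (a GA run converges in roughly 230–500 generations,
~30–100 s on one CPU), a 40 × 200 / 5-planted benchmark over 10 seeds for
recovery, and small instances (≤10 × 10) for the exact fitness oracle.

## Known limitations

* The award/penalty fitness never rewards a descriptor for *separating*
  PK-dissimilar compounds — the penalty branch is independent of descriptor
  values. Descriptors are selected solely for compactness on PK-similar
  pairs; this is implemented as specified and characterised, not "fixed".
* With Award = Penalty = 5 and a minority of similar pairs, subset size is
  set by the floor alone; the GA cannot prefer 12 descriptors over 15.
* The evaluation's default normalisation scope (whole dataset before
  splitting) mildly inflates test metrics; use `fit_indices` for the
  conservative variant.
* One PK parameter per run; multi-parameter studies loop the pipeline.
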