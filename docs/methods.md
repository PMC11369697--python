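# Methods

## Problem and approach

`mpiflux` casts the identification of metabolite–protein interactions
(MPIs) as supervised classification. The premise: the flux of an
enzyme-catalyzed reaction factorizes as `v = kcat * E * eta(x, k)`, where
`E` is enzyme abundance, `kcat` the turnover number, and `eta in [0, 1]`
the fraction of catalytic capacity actually used — the term through which
metabolite concentrations (substrates, activators, inhibitors) act.
Modeling `eta` mechanistically requires kinetic parameters that are rarely
known; instead, the package derives *condition profiles* of two proxies
from matched fluxomics and proteomics data plus a genome-scale metabolic
model, and lets a classifier decide whether a (metabolite, reaction) pair
looks coupled:

* **Flux sum** `M[k, j] = 1/2 * sum_r |S[k, r]| * v[r, j]` — half the total
  absolute flux through metabolite `k` in condition `j`, a proxy for its
  turnover/concentration. Computed per cellular compartment; classifiers
  are trained within one compartment (default cytoplasm).
* **Capacity utilization** `eta[i, j] = |v[i, j]| / (E[i, j] * kcat[i])`,
  with the in-vivo turnover proxy `kcat[i] = max_j kapp[i, j]` and
  `kapp = |v| / E`. Because `kcat` is the per-reaction maximum of `kapp`,
  `eta` lies in [0, 1] with max exactly 1.

Fluxes come from parsimonious FBA (pFBA) under condition-specific
constraints (uptake bounds, measured flux bounds, gene knockouts, measured
growth fixed exactly), or are loaded directly from a TSV when estimated
externally.

Both profiles are max-normalized across conditions. Pairs in which either
profile is too flat to be informative are removed by a coefficient-of-
variation filter (CV = sample sd / mean, ddof = 1, computed on the
normalized profiles; a pair is kept iff both CVs reach the threshold).

Each retained pair is encoded as the upper triangle (diagonal excluded) of
the pairwise Euclidean distance matrix between its per-condition points
`(eta~[j], M~[j])` in the unit square — `J(J-1)/2` features for `J`
conditions, each in `[0, sqrt(2)]`. Two ablation encodings exist: the
constant-replacement variant `sqrt((d eta~)^2 + c^2)` (default `c = 0`) and
the plain concatenation `[eta~_1..J, M~_1..J]`.

## Gold standards

Positive pairs are interaction scores strictly above 500 on the 0–1000
STITCH-style confidence scale, or explicit 0/1 labels from a curated
table. Negatives are constructed four ways: PU-learning-style
*potential-negative* voting (partition the assumed negatives into
`t = floor(n_neg / n_pos)` subsets, train one RBF-SVM per subset against
all positives, keep pairs unanimously predicted negative by all `t - 1`
held-out classifiers); *random-stitch* (negative iff unscored/low-scored
but both members occur in some positive); *Tanimoto* (zero 64-bit
fingerprint similarity to a known binder of the protein nominates
negatives); and *direct* labels. A balanced *random-control* labeling
establishes the chance baseline.

## Classification protocol

Stratified fivefold cross-validation, repeated (package default 100
repetitions; the test suite and acceptance script use 20 to keep desk
runtimes in minutes). For every held-out fold the training set contains
*all* positives of the remaining folds plus an equal-size uniform random
subset of their negatives, so training is exactly balanced while the test
fold keeps its natural imbalance. Hyperparameters are tuned per training
set by an inner 3-fold grid search when the grid has more than one
candidate. Metrics: AUC (Mann–Whitney, ties at 0.5), AUPR (average
precision), weighted F1 and the confusion counts at the model's native
label output, averaged over folds x repetitions (confusion counts are
averaged, not summed). One master seed drives fold assignment, negative
subsampling and estimator seeds through a counter-based spawning scheme;
identical configurations are bit-identical.

Default grids (overridable per run): RF trees {100, 300}, depth {None,
10}, min leaf {1, 5}; SVM C {0.1, 1, 10}, kernel {rbf, linear} on
standardized inputs; MLP hidden {(64,), (128, 64)}, L2 {1e-4, 1e-2},
adaptive learning rate. The synthetic-study evaluations in the tests and
acceptance script fix RF at 300 trees / min leaf 2 (a single-candidate
grid): at the synthetic sample sizes the inner search mostly returns this
configuration anyway, and skipping it keeps each 20-repetition run under a
few minutes on one core.

Metabolites are finally ranked by the number of *distinct* reactions among
their predicted-positive triples; a pair counts as predicted positive when
its out-of-fold prediction is positive in at least half of the repetitions
(configurable).

## Synthetic study

The generator produces a complete, ground-truth-bearing study so every
stage runs without downloads.

**Network.** A single-compartment toy model: a main carbon source feeds a
6-step trunk ending in a hub; `n_branches = 4` parallel branches of
increasing length (12/14/16/18 steps) re-converge into a 3-step tail and a
biomass sink. Every internal reaction carries a GPR (80% single gene, 10%
two-gene complex, 10% two-gene isozyme pair; genes are reaction-unique).
All branches but the last have a finite entry capacity (2/4/8), so pFBA
fills the cheapest branches first. Each branch can also assimilate its own
auxiliary substrate: without this, every flux-sum profile would follow the
single shared uptake trend after normalization and profiles of different
metabolites would be nearly collinear — with it, branch usage varies
independently across conditions, as it does between real carbon-source
regimes.

**Conditions.** `J = 12` conditions; every uptake reaction gets an upper
bound drawn stratified log-uniformly over [0.5, 50] mmol/gDW/h (one draw
per log-spaced stratum, shuffled per source), and half of the conditions
carry one random single-gene knockout, retried until growth remains
possible. Growth is left free (stage-1 maximization).

**Planted truth.** 40 (metabolite, protein) interactions. Regulators are
drawn from a small pool of four hub-like metabolites — mirroring the
empirical pattern that a handful of currency metabolites regulate many
reactions each — and each regulated reaction responds to its single
regulator's normalized flux sum through a Hill curve
`M^a / (K^a + M^a)` (activation) or `K^a / (K^a + M^a)` (inhibition) with
`a ~ U(1.5, 3)` and `K ~ U(0.3, 0.7)`. Unregulated reactions draw
independent clipped log-normal profiles (median 0.15, log-sd 1.5) spiky
enough to pass the CV filter. True turnovers are log-uniform on
[10, 1000].

**Omics.** Reaction-level abundances invert the eta definition,
`E = |v| / (kcat * eta_true)`, with multiplicative log-normal noise
(`sigma = 0.2` by default); where a reaction is inactive, a basal
abundance (the mean of its active conditions) is used, since zero flux
carries no information about expression. Gene-level abundances invert the
min-over-complex / sum-over-isozymes aggregation policy (complex members
get `E`, isozyme units split `E` equally); because toy-model genes are
reaction-unique this inversion is exact, and at `sigma = 0` the pipeline
reproduces `eta_true` up to the per-reaction max rescaling inherent in the
kcat proxy, exactly, on every condition where the reaction carries flux —
the closed-loop identity the tests assert to 1e-9.

**Gold standard.** Truth pairs receive scores uniform on 501–1000; 400
decoy pairs (stratified so every positive's metabolite and protein also
occur among decoys) receive 100–500. Fingerprints are random 64-bit
vectors in two bit-disjoint clusters, so zero-similarity metabolite pairs
exist and Tanimoto labeling is exercised. A direct label table mirrors the
truth.

**What it does and does not emulate.** The bundle reproduces the *formal*
structure of the real inputs (flux-consistent model with GPRs,
condition-varying fluxes, eta-embedded interactions, abundances consistent
with the eta definition, score tables, fingerprints) and a recoverable
planted signal. It does not emulate genome-scale network complexity,
shared genes across reactions, measurement-driven flux bounds,
compartmentalization beyond the cytoplasm, thermodynamics, or the
identifier-mapping noise of real interaction databases. Passing tests
therefore demonstrate that the pipeline's machinery is correct and that it
recovers the kind of coupling the feature construction targets — not that
real-data performance numbers transfer.

## Numerical choices

* LP: scipy/HiGHS; feasibility tolerance 1e-6 (steady state and bounds),
  LP optimality 1e-9. `|v|` is handled by the standard non-negative
  forward/reverse split. pFBA alternative optima are broken by the solver;
  downstream code depends only on `sum |v|` and on flux sums, and the toy
  tests use networks with unique optima.
* `kapp` uses `|v|` so reversible reactions carrying negative flux yield
  positive turnover proxies.
* CV filter: sample standard deviation (ddof = 1); threshold 1 by default
  (the filter the real study conditions call for); the synthetic study
  uses 0.5 throughout, decoupling filter strictness from signal recovery —
  at threshold 1 the filter's purpose (removing flat profiles) is already
  served at 0.5 for the synthetic profiles, which are spiky by design.
* Pairs with an incomplete eta profile (undefined in some retained
  condition) are dropped: distance features need every coordinate.
* Tanimoto of two all-zero fingerprints is defined as 0.
* The assumed-negative partition distributes leftovers round-robin, so
  subset sizes differ by at most 1 and every pair is trained on exactly
  once (vote ceiling `t - 1`).
* Scores above the threshold are *strictly* above (a score of exactly 500
  is an assumed negative).

## Known limitations

* The pair universe is keyed by model identifiers; mapping external
  database identifiers onto model metabolite/gene ids is the caller's
  responsibility.
* Only the BiGG-style JSON subset documented in `model_io` is read; no
  SBML.
* Multi-objective models are supported in the LP but the biomass-fixing
  shortcut assumes a single objective reaction in the common case.
* The random-label control is evaluated on a 2000-pair subsample of the
  retained universe: small labeled sets show the usual anti-learning bias
  of cross-validation under label noise (mean AUC a few points below 0.5),
  which shrinks with sample size; 2000 pairs keep the control centered
  near 0.5 at desk-scale runtime.
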