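# Methods

## What the package models

Scientific knowledge is treated as a set of *research statements* — logical
expressions `PREDICATE(entity_i, entity_j)` combined with ∧, ∨, ¬, →, ↔ —
each carrying a probability of being true that changes as evidence arrives.
Three mechanisms operate on these probabilities:

1. **Trajectory recording.** Every probability is a timestamped record with
   a kind (prior/posterior), an estimation method (Bayesian inference,
   expert estimation, statistical calculation, deduction, abduction,
   induction, homological inference) and an optional evidence source.
   Trajectories are append-only: a revision is a new record, never an edit,
   so the full argument behind a current belief can be replayed.
2. **Hypothesis-set updating.** A hypothesis set is mutually exclusive and
   exhaustive, so its probabilities sum to 1. Updates are Bayes' rule
   (posterior ∝ prior × likelihood of the observed outcome) with
   elimination as the 0/1-likelihood special case, followed by explicit
   renormalization.
3. **Active k-optimization.** To find the k most active compounds in a
   library with few assays, a Gaussian-process QSAR surrogate is fitted to
   all measured activities; its per-compound Normal predictive feeds an
   acquisition strategy that picks the next compound to measure.

## Statement semantics and identity

Statements are immutable values with structural identity; equality ignores
operand order for the commutative connectives AND/OR but preserves it for
display. Quantified claims ("all genes with lactase activity…") are *not*
modelled; generality is expressed by substituting an entity with a parent
ontology class, which covers the intended uses without first-order
machinery. `evaluate_statement` implements ordinary propositional
semantics and is cross-checked in the tests against sympy's boolean algebra
on exhaustive truth tables of up-to-4-atom formulas.

## Homological inference rule

Belief transfer between hypotheses about homologous genes has no standard
quantitative form, so the package uses the simplest rule with the right
qualitative properties:

    p_target' = clip(p_target + w · (p_source_new − p_source_old), 0, 1)

with per-link weight `w ∈ [0, 1]`, default 0.5. It is linear, monotone
(the target never moves against the source), bounded, and every application
is recorded with method `homological_inference` and the triggering
evidence. The `disputes` relation is stored as metadata only and triggers
no numeric update, since no quantitative reading of it is established.
In the sirtuin fixture, the 2012 mouse result is routed through the
model-organism homology channel (h2 → h1): the fixture tracks a single
"sirtuins extend lifespan in a model organism" channel rather than one
hypothesis per species, which keeps the worked example at three statements.
Only the post-2001 expert value of 0.8 and the down-after-2011 /
up-after-2012 directions are load-bearing; the 2011/2012 magnitudes (0.55,
0.675) follow from the rule above with illustrative source moves 0.9→0.4→0.65.

## Experiment selection

The engine scores each candidate experiment by expected Shannon information
gain divided by cost (`gain / (cost + 1e-9)`, ties by candidate order).
Information gain is `H(set) − Σ_o P(o)·H(set | o)`; the tests verify it
equals the mutual information I(H; O) computed from the joint distribution.
Real closed-loop systems use richer multi-criteria policies; this one is a
stated, replaceable strategy object that uses exactly the three ingredients
such systems report: current probabilities, cost, and predicted gain.

## Gaussian-process surrogate

Kernel: squared-exponential `amp² · exp(−‖x−x′‖²/(2ℓ²))` with a constant
prior mean set to the training-target mean, observation noise `σ_n²` on the
diagonal plus jitter 1e-8 for numerical stability. Defaults `amp = 1`,
`ℓ = 0.2`, `σ_n = 0.1` suit features on the unit cube with bump widths
0.12–0.18 and match the default generator's noise; hyperparameters can
instead be fitted by marginal-likelihood maximization (`optimize=True`).
The implementation wraps scikit-learn's `GaussianProcessRegressor`; tests
compare its posterior against a direct linear-algebra solve to 1e-8 and
check noiseless interpolation and reversion to the prior far from data.

Acquisition functions use the exact Normal formulas with explicit σ = 0
point-mass limits (never division by zero):

* MPI: `Φ((μ − y_kbest)/σ)`; σ=0 → indicator `μ > y_kbest`.
* MEI: `(μ − y_kbest)·Φ(z) + σ·φ(z)`; σ=0 → `max(μ − y_kbest, 0)`.
* Optimistic: `μ + β·σ`, default β = 2. The cited confidence-bound
  criterion is phrased as a *lower* bound for minimization; activity is
  maximized here, so optimism under uncertainty adds the σ term.

`y_kbest` is the k-th largest among *measured* values so far, bootstrap
included. Acquisition argmax ties break toward the lowest compound index
for determinism.

## Synthetic library generator

The generator emulates a large anticancer screen at desk scale: features
uniform on [0,1]^d, latent activity a baseline of 5 plus a sum of Gaussian
bumps, additive N(0, noise_sd²) noise on the observed activity. The default
spec — 500 compounds, 2 features, 3 bumps (heights 1.5/2.5/1.0, widths
0.18/0.15/0.12), noise sd 0.1 — gives a smooth multimodal surface with one
global optimum near 7.5, where informed strategies separate from random
within a 60-measurement budget averaged over 20 repetitions.

What the generator does *not* emulate: real molecular feature spaces
(high-dimensional, discrete, correlated), heteroscedastic assay noise,
multiple cell lines, or compound-availability constraints. Passing the
strategy-ordering test therefore shows the machinery is correct and the
qualitative informed-beats-random result holds on smooth landscapes; it is
not a performance claim about any particular real screen.

## Problem sizes and numerical choices

The strategy comparison runs 20 repetitions × 4 strategies × 60-measurement
budgets on 500-compound libraries with fixed GP hyperparameters — about
3,000 small GP fits, a few seconds total; these sizes are the package's
default study conditions. Probability-vector renormalization happens after
every update with a sum-to-one tolerance of 1e-9. Timestamp ties in
trajectories break by insertion order. Degenerate inputs (empty hypothesis
sets, rejecting every hypothesis, outcomes impossible under all hypotheses,
σ < 0, budgets beyond the library) raise `ValidationError` rather than
propagating NaNs.

## Serialization

The working format is deterministic JSON (sorted keys, id-sorted arrays)
with a `helo_class` string per object naming its ontology class ("prior
probability", "expert estimation", "HAS-REFUTING-EVIDENCE", …) and an
`@context` IRI, so documents stay alignable with the OWL ontology without
making the reasoning engines depend on a description-logic file. Import
re-validates every invariant; unknown `helo_class` strings warn but are
preserved, while dangling references, out-of-range probabilities and
unknown relation names are hard errors.

## Known limitations

* Homological transfer weights are per-link constants; nothing estimates
  them from data.
* The propositional layer has no quantifiers and no consistency checking
  across statements.
* The hypothesis engine assumes the likelihood tables are given; it does
  not abduce hypotheses from a mechanistic model.
* The active-learning loop measures one compound per iteration (no batch
  acquisition) and assumes noiseless access to a scalar assay value.
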