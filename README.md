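# helo

Evidence-linked probabilistic research statements, with two reasoning
engines on top: hypothesis-set elimination/Bayesian updating, and
Gaussian-process active learning for compound screening.

Scientific claims are uncertain, and the uncertainty moves as evidence
arrives — yet most knowledge representations record at best a qualitative
evidence code. This package makes the probabilities first-class: a research
statement is a logical expression `PREDICATE(entity_i, entity_j)` (atoms
combinable with ∧ ∨ ¬ → ↔) that carries an append-only trajectory of
timestamped probability records, each tagged with how it was obtained
(Bayesian inference, expert estimation, statistical calculation, deduction,
abduction, induction, homological inference) and which evidence triggered
it. It is aimed at researchers building automated-discovery loops and at
anyone who wants the argument behind a belief to be replayable.

## The core machinery

* **Hypothesis sets** are mutually exclusive and exhaustive:
  Σ_i P(h_i) = 1. Observing an experiment outcome o updates
  P(h_i) ∝ P(h_i)·P(o | h_i); rejecting hypotheses is the 0/1-likelihood
  special case, with survivors renormalized. Experiments are chosen by
  expected Shannon information gain per unit cost.
* **Homological inference** transfers belief between hypotheses about
  homologous genes: p_target ← clip(p_target + w·Δp_source, 0, 1) with a
  per-link weight w.
* **Active k-optimization** finds the k most active compounds in a library
  with few assays. A GP surrogate with squared-exponential kernel gives a
  Normal predictive N(μ_i, σ_i²) per untested compound; the next
  measurement maximizes an acquisition score — Φ((μ−y_kbest)/σ) (MPI),
  (μ−y_kbest)Φ(z)+σφ(z) (MEI), or μ+βσ (optimistic confidence bound) —
  against the current k-th best measured activity y_kbest.

## A worked example

```sh
python examples/sirtuin_timeline.py
```

tracks the hypothesis h1 = `regulates(SIRT1, human_life_span)`, which is
impractical to test directly, through its model-organism homologs:

```
probability trajectory:
  2000-01-01  P=0.500  prior     expert_estimation
  2001-01-02  P=0.800  posterior expert_estimation  <- ev_tissenbaum_guarente_2001
  2011-01-01  P=0.550  posterior homological_inference  <- ev_burnett_2011
  2012-01-01  P=0.675  posterior homological_inference  <- ev_kanfi_2012
```

The 2001 nematode lifespan result lifts the expert estimate to 0.8; the
2011 failure to replicate in worm and fly pushes belief down through the
h2→h1 homology channel (weight 0.5); the 2012 mouse result pushes it back
up. Each line is a permanent record carrying its method and evidence.

`python examples/adam_elimination.py` replays the gene-deletion puzzle —
8 candidate genes at prior 1/8, five elimination cycles, survivor at
posterior 1 — and shows cost-aware experiment choice (a 1-bit assay at
cost 1 beats a 2-bit assay at cost 10). `python examples/active_screening.py`
compares the four selection strategies on a 500-compound synthetic library
(budget 60, 20 repetitions): informed strategies average a best-found
activity of 7.533 versus 7.308 for random selection.

There is also a thin CLI: `helo demo-adam`, `helo demo-sirtuin`,
`helo record-statement`, `helo attach-prob`, `helo trajectory h1`, and
`helo activelearn --library lib.csv --strategy mpi --k 1 --budget 60 --seed 7`.
Knowledge bases serialize to deterministic JSON whose objects carry
ontology class names (`helo_class`), and compound libraries are plain CSV
(`compound_id`, feature columns, optional `activity`).

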