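"""Hypothesis elimination for a gene-deletion puzzle.

A robot-scientist workflow abduces 8 candidate genes that could explain an
uncharacterized auxotrophic yeast strain, starts from a uniform prior of 1/8,
and runs experiment cycles that each reject one or more candidates.  The
replay prints the probability table cycle by cycle: survivors' probabilities
rise with every renormalization until the last hypothesis holds mass 1.
It also shows how the engine would pick between candidate experiments by
expected information gain per unit cost.
"""

from helo import (
    ExperimentSpec,
    aaa_fixture,
    entropy_bits,
    expected_information_gain,
    replay_aaa,
    select_experiment,
)

kb, hset, cycles = aaa_fixture()
print("hypotheses:", ", ".join(m.removeprefix("hyp_") for m in hset.members))
print(f"prior: {hset.probs[0]:.3f} each ({entropy_bits(hset):.1f} bits of uncertainty)\n")

for (date, rejected), state in zip(cycles, replay_aaa(kb, hset, cycles)):
    gone = ", ".join(r.removeprefix("hyp_") for r in rejected)
    probs = "  ".join(f"{m.removeprefix('hyp_')}={p:.3f}" for m, p in state.as_dict().items())
    print(f"{date}  reject [{gone}] -> {probs}")

survivor = state.members[0]
print(f"\nsurvivor: {survivor} at posterior {state.probs[0]:.0f};"
      f" its recorded trajectory in the knowledge base:")
for r in kb.trajectory(survivor):
    print(f"  {r.timestamp}  P={r.value:.3f}  ({r.kind.value}, {r.method.value})")

# Experiment choice: a cheap test that splits the set in half beats an
# expensive perfectly-discriminating one, per gain-per-cost.
members = ("h_a", "h_b", "h_c", "h_d")
half = ExperimentSpec(
    "halving_assay", cost=1.0, outcomes=("growth", "no_growth"),
    likelihood={m: {"growth": 1.0 if i < 2 else 0.0,
                    "no_growth": 0.0 if i < 2 else 1.0}
                for i, m in enumerate(members)},
)
full = ExperimentSpec(
    "exhaustive_assay", cost=10.0, outcomes=("a", "b", "c", "d"),
    likelihood={m: {o: 1.0 if o == m[-1] else 0.0 for o in "abcd"}
                for m in members},
)
from helo import uniform_set

hset4 = uniform_set(members)
for exp in (half, full):
    gain = expected_information_gain(hset4, exp)
    print(f"{exp.id}: gain {gain:.2f} bits at cost {exp.cost} "
          f"-> {gain / exp.cost:.2f} bits per unit")
print("chosen:", select_experiment(hset4, [half, full]))
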