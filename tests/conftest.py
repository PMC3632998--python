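import numpy as np
import pytest

from helo import Connective, Entity, combine, make_atomic


@pytest.fixture
def entities():
    return {name: Entity(id=name, label=name) for name in "abcdwxyz"}


@pytest.fixture
def atoms(entities):
    """Four distinct atomic statements to build formulas from."""
    e = entities
    return [
        make_atomic("p", e["a"], e["b"]),
        make_atomic("q", e["b"], e["c"]),
        make_atomic("r", e["c"], e["d"]),
        make_atomic("s", e["a"], e["d"]),
    ]


def random_formula(rng: np.random.Generator, atoms, depth: int):
    """Draw a random statement tree of bounded depth over the given atoms."""
    if depth <= 0 or rng.random() < 0.3:
        return atoms[rng.integers(len(atoms))]
    conn = list(Connective)[rng.integers(len(Connective))]
    if conn is Connective.NOT:
        n_ops = 1
    elif conn in (Connective.AND, Connective.OR):
        n_ops = int(rng.integers(2, 4))
    else:
        n_ops = 2
    return combine(conn, [random_formula(rng, atoms, depth - 1) for _ in range(n_ops)])
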