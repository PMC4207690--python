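import numpy as np
import pytest

from semtype import syndata


@pytest.fixture(scope="session")
def refdb():
    """Small shared reference: 6 genera x 2 species, 250 nt."""
    return syndata.make_reference(n_genera=6, species_per_genus=2, seq_len=250, seed=11)


@pytest.fixture(scope="session")
def default_refdb():
    """Full default reference panel (all 14 genera)."""
    return syndata.make_reference(seed=1)


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort for integration tests: 30 samples, 400 pairs each."""
    cfg = syndata.CohortConfig(
        group_sizes={"G1": 8, "G2": 16, "G3": 6}, n_pairs_per_sample=400
    )
    return syndata.simulate_cohort(cfg, seed=5)


def random_tree(rng: np.random.Generator, n_leaves: int) -> str:
    """Random rooted binary tree with uniform [0.1, 1] branch lengths (newick)."""
    nodes = [f"L{i}" for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        la, lb = rng.uniform(0.1, 1.0, size=2)
        merged = f"({a}:{la:.4f},{b}:{lb:.4f})"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return nodes[0] + ";"
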