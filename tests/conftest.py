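import numpy as np
import pytest

from stemglobin.simulate import SimParams, evolve_sequences, simulate_gene_family
from stemglobin.species import SpeciesTree


@pytest.fixture(scope="session")
def default_tree() -> SpeciesTree:
    return SpeciesTree.default()


@pytest.fixture(scope="session")
def default_truth(default_tree):
    """One default simulation run (seed 7) with sequences evolved."""
    params = SimParams(seed=7)
    truth = simulate_gene_family(default_tree, params)
    evolve_sequences(truth, params)
    return truth


def random_binary_newick(rng: np.random.Generator, n_leaves: int, supports=None) -> str:
    """Random rooted-binary Newick over leaves t0..t{n-1}; optional supports
    drawn uniformly when ``supports`` is a (low, high) tuple."""
    nodes = [f"t{i}:1" for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        label = ""
        if supports is not None:
            label = f"{rng.uniform(*supports):.2f}"
        nodes.append(f"({a},{b}){label}:1")
    return nodes[0] + ";"
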