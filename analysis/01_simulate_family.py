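#!/usr/bin/env python
"""Generate the default synthetic globin-family fixture.

Five stem lineages enter the root of the 12-species metazoan tree and evolve
by duplication and loss; sequences diverge from the 150-residue template with
five invariant anchors; lineage L1 carries a planted secretion signal and L2
a dual-acylation N-terminus.  Writes the full fixture bundle (proteomes with
decoys, reference set, loci, predictor tables, truth tables, Ct plate) under
results/fixture/.
"""

from pathlib import Path

from stemglobin.simulate import SimParams, emit_fixture, evolve_sequences, simulate_gene_family
from stemglobin.species import SpeciesTree

OUT = Path(__file__).resolve().parent.parent / "results" / "fixture"
SEED = 49


def main() -> None:
    tree = SpeciesTree.default()
    params = SimParams(seed=SEED)
    truth = simulate_gene_family(tree, params)
    sequences = evolve_sequences(truth, params)
    emit_fixture(truth, sequences, OUT)
    n = len(truth.clade_membership)
    print(f"simulated {n} surviving genes across {len(tree.species())} species")
    print("per-lineage gene counts:")
    print(truth.presence.sum(axis=1).to_string())
    print(f"duplications: {(truth.event_list.event == 'duplication').sum()}, "
          f"losses: {(truth.event_list.event == 'loss').sum()}")
    print(f"fixture written to {OUT}")


if __name__ == "__main__":
    main()
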