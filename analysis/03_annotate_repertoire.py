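#!/usr/bin/env python
"""Localize the simulated repertoire and map chromosomal clusters.

Classifies every gene as extracellular / membrane / cytoplasmic twice -- from
the external predictor tables (which encode planted truth) and from the
sequence-only fallback heuristics -- and groups gene loci into single-linkage
clusters, flagging overlapping gene pairs.  Requires the fixture from
01_simulate_family.py.
"""

from pathlib import Path

import pandas as pd

from stemglobin import annotate
from stemglobin.experiments import localization_experiment
from stemglobin.records import read_fasta, write_tsv

ROOT = Path(__file__).resolve().parent.parent
FIXTURE = ROOT / "results" / "fixture"
OUT = ROOT / "results" / "annotation"
SEED = 49


def main() -> None:
    res = localization_experiment(seed=SEED)
    print(f"localization accuracy: external tables "
          f"{100 * res['accuracy_external']:.1f}%, "
          f"fallback heuristics {100 * res['accuracy_fallback']:.1f}% "
          f"({res['n_genes']} genes)")

    seqs = {}
    for fa in sorted((FIXTURE / "proteomes").glob("*.fa")):
        for rec in read_fasta(fa):
            if "decoy" not in rec.id:
                seqs[rec.id] = rec.sequence
    preds = annotate.read_predictor_table(FIXTURE / "predictors.tsv")
    loc = annotate.annotate_localizations(seqs, preds)
    write_tsv(loc, OUT / "localizations.tsv")
    print(loc["localization"].value_counts().to_string())

    loci = annotate.read_gff3_loci(FIXTURE / "loci.gff3")
    clusters = annotate.map_gene_clusters(loci)
    multi = [c for c in clusters if len(c) > 1]
    print(f"{len(multi)} multi-gene clusters")
    for c in multi:
        note = f" (overlapping: {c.overlap_pairs})" if c.overlap_pairs else ""
        print(f"  {c.scaffold}: {', '.join(c.member_ids)}{note}")
    write_tsv(
        pd.DataFrame(
            [(c.scaffold, len(c), ";".join(c.member_ids),
              ";".join(f"{a}~{b}" for a, b in c.overlap_pairs)) for c in clusters],
            columns=["scaffold", "n_genes", "members", "overlaps"],
        ),
        OUT / "clusters.tsv",
    )
    print(f"annotation tables written to {OUT}")


if __name__ == "__main__":
    main()
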