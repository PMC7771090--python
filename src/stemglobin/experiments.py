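"""Desk-scale validation experiments run against the simulator's ground truth.

These drive the same library calls as the file-based pipeline but keep
everything in memory, so replicated runs (parameter-recovery rates, screening
sensitivity, localization accuracy) stay fast enough to repeat across many
seeds.  They are what the numbered analysis scripts and the acceptance
measurements execute.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from . import annotate, dollo, qpcr, screen, simulate, trees
from .records import ProteinRecord
from .simulate import SimParams
from .species import SpeciesTree
from .trees import Thresholds


def _clade_lineages(call: trees.CladeCall, membership: Dict[str, str]) -> set:
    return {membership[g] for g in call.leafset if g in membership}


def recover_lineages_once(
    seed: int,
    params: Optional[SimParams] = None,
    tree: Optional[SpeciesTree] = None,
    bootstrap_replicates: int = 100,
    thresholds: Optional[Thresholds] = None,
) -> Dict:
    """One simulate -> evolve -> NJ+bootstrap -> delineate -> Dollo trial.

    Returns the number of natural clades recovered, whether they map
    one-to-one onto the true stem lineages, and -- for every surviving
    lineage -- whether the Dollo reconstruction of its presence pattern
    matches the presence-level truth history (checked exactly where that
    history is itself a minimal single-gain scenario, i.e. when presence
    spans both sides of the root).
    """
    tree = tree or SpeciesTree.default()
    params = params or SimParams(seed=seed)
    th = thresholds or Thresholds()

    truth = simulate.simulate_gene_family(tree, params)
    simulate.evolve_sequences(truth, params)
    support_tree = trees.bootstrap_support(
        truth.core_sequences, replicates=bootstrap_replicates, seed=seed
    )
    natural = trees.delineate_natural_clades(support_tree, tree.taxon_groups, th)

    clade_lineage_sets = [
        _clade_lineages(c, truth.clade_membership) for c in natural
    ]
    pure = all(len(s) == 1 for s in clade_lineage_sets)
    covered = {next(iter(s)) for s in clade_lineage_sets if len(s) == 1}
    surviving = {
        lin for lin in params.lineages() if truth.presence.loc[lin].sum() > 0
    }
    exact = (
        pure
        and len(natural) == params.n_stem_lineages
        and covered == set(params.lineages())
    )

    root_children_leaves = [
        tree.leaves_under(c) for c in tree.root.child_nodes()
    ]
    dollo_eligible = 0
    dollo_exact = 0
    dollo_bounded = 0
    for lin in surviving:
        flags = truth.presence_flags(lin)
        present = {sp for sp, f in flags.items() if f}
        ev = dollo.dollo_reconstruct(tree, flags, clade=lin)
        hist = dollo.presence_history(tree, flags, clade=lin)
        spans_root = all(present & side for side in root_children_leaves)
        if spans_root:
            dollo_eligible += 1
            if ev.gain_edge == hist.gain_edge and sorted(ev.loss_edges) == sorted(
                hist.loss_edges
            ):
                dollo_exact += 1
        if ev.n_losses <= hist.n_losses:
            dollo_bounded += 1
    return {
        "seed": seed,
        "n_natural_clades": len(natural),
        "n_surviving_lineages": len(surviving),
        "exact_recovery": exact,
        "dollo_eligible": dollo_eligible,
        "dollo_exact": dollo_exact,
        "dollo_bounded": dollo_bounded,
    }


def recovery_experiment(
    seeds: Sequence[int], bootstrap_replicates: int = 100
) -> pd.DataFrame:
    """Repeat the recovery trial across seeds (the headline parameter-
    recovery measurement: how often exactly the planted number of
    single-ancestral-gene lineages is recovered)."""
    return pd.DataFrame(
        [
            recover_lineages_once(s, bootstrap_replicates=bootstrap_replicates)
            for s in seeds
        ]
    )


def screening_experiment(seed: int, params: Optional[SimParams] = None) -> Dict:
    """Screen every simulated proteome (globins + decoys) with the stem-probe
    and the stopping rule; measure sensitivity and decoy acceptances."""
    tree = SpeciesTree.default()
    params = params or SimParams(seed=seed)
    truth = simulate.simulate_gene_family(tree, params)
    sequences = simulate.evolve_sequences(truth, params)
    refs, labels_df = simulate.reference_set(truth, params)
    labels = dict(zip(labels_df["id"], labels_df["label"]))
    probe = screen.build_concatemer_probe(
        [r for r in refs if labels[r.id] == "globin"]
    )
    decoys = simulate.make_decoys(params, tree.species())
    decoys_by_sp: Dict[str, List[ProteinRecord]] = {}
    for d in decoys:
        decoys_by_sp.setdefault(d.species, []).append(d)

    n_true = len(truth.clade_membership)
    recovered = 0
    decoys_accepted = 0
    for sp in tree.species():
        proteome = [
            ProteinRecord(id=g, species=sp, sequence=sequences[g])
            for g in sorted(truth.clade_membership)
            if g.startswith(sp + "|")
        ] + decoys_by_sp.get(sp, [])
        _, calls = screen.screen_and_call(
            probe, proteome, refs, labels, species=sp
        )
        for g in calls.accepted:
            if g in truth.clade_membership:
                recovered += 1
            else:
                decoys_accepted += 1
    return {
        "seed": seed,
        "n_true_genes": n_true,
        "n_recovered": recovered,
        "sensitivity": recovered / n_true if n_true else float("nan"),
        "n_decoys": len(decoys),
        "decoys_accepted": decoys_accepted,
    }


def localization_experiment(seed: int, params: Optional[SimParams] = None) -> Dict:
    """Three-way localization accuracy against planted truth, with external
    predictor tables (which encode the truth exactly) and with the
    sequence-only fallback heuristics."""
    tree = SpeciesTree.default()
    params = params or SimParams(seed=seed)
    truth = simulate.simulate_gene_family(tree, params)
    sequences = simulate.evolve_sequences(truth, params)
    expected = {
        "secretion": "extracellular",
        "dual_acylation": "membrane",
        "none": "cytoplasmic",
    }
    external = {}
    for g, feat in truth.planted_features.items():
        external[g] = annotate.FeaturePrediction(
            gene_id=g,
            signal_peptide=feat == "secretion",
            myristoylation_sites=(simulate.MYRISTOYLATION_SITE,)
            if feat == "dual_acylation"
            else (),
            palmitoylation_sites=(simulate.PALMITOYLATION_SITE,)
            if feat == "dual_acylation"
            else (),
        )
    n = len(truth.clade_membership)
    ok_external = 0
    ok_fallback = 0
    for g in truth.clade_membership:
        want = expected[truth.planted_features[g]]
        got_ext = annotate.classify_localization(external[g])
        pred_fb = annotate.predict_features_fallback(g, sequences[g])
        got_fb = annotate.classify_localization(pred_fb)
        ok_external += int(got_ext == want)
        ok_fallback += int(got_fb == want)
    return {
        "seed": seed,
        "n_genes": n,
        "accuracy_external": ok_external / n,
        "accuracy_fallback": ok_fallback / n,
    }


def qpcr_experiment(seed: int) -> Dict:
    """Simulated plate: does the recovered profile show the planted life-cycle
    shape (rise to the metamorphosis-onset peak, collapse in the swarming
    adult), and how strong is the per-gene rank agreement?"""
    table, truth = simulate.simulate_ct_table(seed)
    out = qpcr.summarize_stage(table)
    peak = truth.loc[truth.level.idxmax(), "stage"]
    rhos = []
    shape_ok = True
    for gene, gene_truth in truth.groupby("gene"):
        got = out[out.gene == gene].set_index("stage")["median_level"]
        want = gene_truth.set_index("stage")["level"]
        stages = [s for s in simulate.QPCR_STAGES if s in got.index]
        rhos.append(float(spearmanr(got[stages], want[stages]).statistic))
        shape_ok &= got[stages].idxmax() == peak
        shape_ok &= bool(got["48hpf"] < got["6wk"] < got[peak])
        shape_ok &= bool(
            got["swarm"] < min(got["50seg"], got["metI"], got["metII"])
        )
    return {
        "seed": seed,
        "profile_shape_recovered": bool(shape_ok),
        "mean_rank_agreement": float(np.mean(rhos)),
        "n_genes": int(truth.gene.nunique()),
    }
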