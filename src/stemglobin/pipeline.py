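"""End-to-end pipeline: simulate -> screen -> annotate -> clades -> ancestral
-> qpcr, with files as stage boundaries so any stage can equally consume real
exports in place of synthetic fixtures.

The run is fully configured by a :class:`RunConfig` (strict keys, serialized
into the output directory for provenance) and is deterministic given the
seed: rerunning the same config reproduces every output byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd
import yaml

from . import annotate, dollo, qpcr, screen, simulate, trees
from .records import read_fasta, write_tsv
from .simulate import SimParams
from .species import SpeciesTree
from .trees import Thresholds

log = logging.getLogger("stemglobin")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Every knob of a pipeline run.  Unknown keys are rejected."""

    out_dir: str = "run"
    seed: int = 0
    # simulation
    n_stem_lineages: int = 5
    dup_rate: float = 0.01
    loss_rate: float = 0.01
    seq_length: int = 150
    n_invariant_anchors: int = 5
    subst_rate_scale: float = 1.0
    stem_divergence: float = 0.6
    n_decoys: int = 40
    planted_feature_spec: Dict[str, str] = field(
        default_factory=lambda: {"L1": "secretion", "L2": "dual_acylation"}
    )
    species_newick: Optional[str] = None
    taxon_groups: Optional[Dict[str, str]] = None
    # screening
    e_cutoff: float = 10.0
    reciprocal_e_cutoff: float = 1e-3
    stop_n: int = 10
    # annotation
    acylation_window: int = 25
    acylation_max_gap: int = 10
    cluster_max_distance: int = 50_000
    # tree analysis
    strong_support: float = 0.95
    moderate_support: float = 0.75
    min_species: int = 4
    min_superphyla: int = 2
    mono_min_genes: int = 3
    bootstrap_replicates: int = 100
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, data: Dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must hold a mapping")
        return cls.from_dict(data)

    def sim_params(self) -> SimParams:
        return SimParams(
            n_stem_lineages=self.n_stem_lineages,
            dup_rate=self.dup_rate,
            loss_rate=self.loss_rate,
            seq_length=self.seq_length,
            n_invariant_anchors=self.n_invariant_anchors,
            subst_rate_scale=self.subst_rate_scale,
            stem_divergence=self.stem_divergence,
            planted_feature_spec=dict(self.planted_feature_spec),
            n_decoys=self.n_decoys,
            seed=self.seed,
        )

    def thresholds(self) -> Thresholds:
        return Thresholds(
            strong_support=self.strong_support,
            moderate_support=self.moderate_support,
            min_species=self.min_species,
            min_superphyla=self.min_superphyla,
            mono_min_genes=self.mono_min_genes,
        )

    def species_tree(self) -> SpeciesTree:
        if self.species_newick:
            return SpeciesTree.from_newick(self.species_newick, self.taxon_groups or {})
        return SpeciesTree.default()


def run_pipeline(config: RunConfig) -> Dict:
    """Execute all stages in order; returns the machine-readable summary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    (out / "config.yaml").write_text(yaml.safe_dump(asdict(config), sort_keys=True))

    tree = config.species_tree()
    params = config.sim_params()
    th = config.thresholds()

    # -- simulate ---------------------------------------------------------
    log.info("stage simulate: seed=%d, %d lineages", config.seed, params.n_stem_lineages)
    truth = simulate.simulate_gene_family(tree, params)
    sequences = simulate.evolve_sequences(truth, params)
    fixture = out / "fixture"
    simulate.emit_fixture(truth, sequences, fixture)

    # -- screen -----------------------------------------------------------
    refs, ref_labels_df = simulate.reference_set(truth, params)
    ref_labels = dict(zip(ref_labels_df["id"], ref_labels_df["label"]))
    probe = screen.build_concatemer_probe([r for r in refs if ref_labels[r.id] == "globin"])
    log.info("stage screen: probe %d aa, %d components", len(probe), probe.n_components)
    accepted_ids: List[str] = []
    screen_rows = []
    for sp in tree.species():
        proteome = read_fasta(fixture / "proteomes" / f"{sp}.fa")
        hits, calls = screen.screen_and_call(
            probe,
            proteome,
            refs,
            ref_labels,
            species=sp,
            e_cutoff=config.e_cutoff,
            reciprocal_e_cutoff=config.reciprocal_e_cutoff,
            stop_n=config.stop_n,
        )
        table = screen.hits_table(hits, calls)
        table.insert(0, "query_species", sp)
        screen_rows.append(table)
        accepted_ids.extend(calls.accepted)
    hits_all = pd.concat(screen_rows, ignore_index=True)
    write_tsv(hits_all, out / "screen_hits.tsv")

    # -- annotate ---------------------------------------------------------
    log.info("stage annotate: %d accepted genes", len(accepted_ids))
    preds = annotate.read_predictor_table(fixture / "predictors.tsv")
    accepted_seqs = {g: sequences[g] for g in accepted_ids if g in sequences}
    loc = annotate.annotate_localizations(
        accepted_seqs,
        preds,
        window=config.acylation_window,
        max_gap=config.acylation_max_gap,
    )
    write_tsv(loc, out / "localizations.tsv")
    loci = annotate.read_gff3_loci(fixture / "loci.gff3")
    clusters = annotate.map_gene_clusters(loci, max_distance=config.cluster_max_distance)
    cluster_df = pd.DataFrame(
        [
            (c.scaffold, len(c), ";".join(c.member_ids), ";".join(
                f"{a}~{b}" for a, b in c.overlap_pairs
            ))
            for c in clusters
        ],
        columns=["scaffold", "n_genes", "members", "overlaps"],
    )
    write_tsv(cluster_df, out / "clusters.tsv")

    # -- clades -----------------------------------------------------------
    core = truth.core_sequences or {}
    aln = {g: core[g] for g in accepted_ids if g in core}
    log.info("stage clades: NJ + %d bootstrap replicates on %d genes",
             config.bootstrap_replicates, len(aln))
    support_tree = trees.bootstrap_support(
        aln, replicates=config.bootstrap_replicates, seed=config.seed
    )
    (out / "gene_tree_supports.nwk").write_text(support_tree.write() + "\n")
    taxon_map = tree.taxon_groups
    natural = trees.delineate_natural_clades(support_tree, taxon_map, th)
    anchor_table = {}
    for lin in params.lineages():
        for g in truth.genes_of(lin):
            anchor_table[g] = lin
    natural = trees.assign_clade_labels(natural, anchor_table)
    write_tsv(trees.clade_report(natural), out / "clades.tsv")

    # -- ancestral --------------------------------------------------------
    recovered = _recovered_presence(natural, tree)
    events_df, summary_events = dollo.event_table(tree, recovered)
    write_tsv(events_df, out / "gain_loss.tsv")

    # -- qpcr -------------------------------------------------------------
    ct = pd.read_csv(fixture / "ct_table.tsv", sep="\t")
    profile = qpcr.summarize_stage(ct)
    write_tsv(profile, out / "qpcr_profile.tsv")

    loc_counts = loc["localization"].value_counts().to_dict()
    summary = {
        "seed": config.seed,
        "n_species": len(tree.species()),
        "n_simulated_genes": len(truth.clade_membership),
        "n_accepted_globins": len(accepted_ids),
        "localization_counts": {k: int(v) for k, v in sorted(loc_counts.items())},
        "n_natural_clades": len(natural),
        "clade_labels": sorted(c.label for c in natural),
        "gain_loss": summary_events,
        "per_species_accepted": {
            sp: int(sum(1 for g in accepted_ids if g.startswith(sp + "|")))
            for sp in tree.species()
        },
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    log.info("pipeline done: %d natural clades, %d accepted genes",
             len(natural), len(accepted_ids))
    return summary


def _recovered_presence(natural: List[trees.CladeCall], tree: SpeciesTree) -> pd.DataFrame:
    """Presence matrix of the recovered clades (gene counts per species)."""
    species = tree.species()
    index = [c.label if c.label != "unclassified" else f"clade{i+1}"
             for i, c in enumerate(natural)]
    mat = pd.DataFrame(0, index=index, columns=species, dtype=int)
    for name, call in zip(index, natural):
        for g in call.leafset:
            sp = g.split("|")[0]
            if sp in mat.columns:
                mat.loc[name, sp] += 1
    return mat
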