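"""Synthetic gene-family generator with known ground truth.

A small number of stem gene lineages (default five, echoing the five
ancestral bilaterian globins) enter the root of a species tree and evolve by
a birth--death process: along every branch each gene copy draws Poisson
numbers of duplication and loss events (rates per unit branch length),
applied in random order at uniform positions.  Surviving copies become the
genes of the extant proteomes.

Protein sequences evolve down the resulting gene tree from a fixed 150-residue
globin-like template.  A configurable set of anchor positions is never
substituted, mirroring the handful of invariant residues that anchor real
globin alignments.  Selected lineages carry planted N-terminal features: a
cleavable-style secretion signal (extracellular globins) or a
dual-acylation motif (membrane-bound globins).  Decoy proteins with shuffled
template composition provide a null model for screening specificity.

All randomness flows from one integer seed; identical seeds give identical
fixtures, byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .records import ProteinRecord, qualified_id, write_fasta, write_tsv
from .species import SpeciesTree

# ---------------------------------------------------------------------------
# Fixed sequence material

#: 150-residue synthetic globin-like template (alpha-helical-biased
#: composition, Met start, His pair at the proximal/distal anchor positions).
TEMPLATE_SEQUENCE = (
    "MSDLTAEQKALVKESWELLKPDLPGHGVKFFTRLFEIAPSAKQLFSFLRDSDVPLEQNP"
    "KLKAHAGKVFKLTYEAAIQLEVNGAVASDATLKSLGSVHVSKGVVDAHFPVVKEAILKT"
    "IKEVVGDKWSEELNTAWTIAYDELAIIIKKEM"
)

#: Anchor (never-substituted) positions, 0-based, in template coordinates.
#: Clear of the first 8 residues so planted N-terminal motifs never touch them.
ANCHOR_POSITIONS = (17, 46, 69, 104, 137)

#: Planted secretion signal: short n-region, 10-residue hydrophobic h-region,
#: small-residue c-region ending in a cleavage-style Ala-Ser-Ala.
SIGNAL_PEPTIDE = "MKFLLVLAVLILAASQASA"

#: Planted dual-acylation N-terminus: Gly-2 myristoylation site and Cys-3
#: palmitoylation site.
ACYLATION_MOTIF = "MGCFLSKV"
MYRISTOYLATION_SITE = 2  # 1-based residue index (Gly)
PALMITOYLATION_SITE = 3  # 1-based residue index (Cys)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

FEATURES = ("secretion", "dual_acylation", "none")

#: qPCR stage axis and planted relative-expression profile: negligible in the
#: early larva, rising through juvenile growth, peaking at the onset of sexual
#: metamorphosis and collapsing in the swarming adult.
QPCR_STAGES = ("48hpf", "6wk", "50seg", "metI", "metII", "swarm")
QPCR_STAGE_PROFILE = (0.001, 0.02, 0.40, 1.20, 0.30, 0.005)
QPCR_REFERENCE_GENES = {"rps9": 18.0, "sams": 20.0}


class SimulationError(ValueError):
    pass


@dataclass
class SimParams:
    """Parameters of the gene-family simulation.

    Rates are events per unit branch length (branch lengths are expected
    substitutions per site, so the rates are scaled to the molecular clock of
    the species tree).  ``stem_divergence`` is the length of the private stem
    branch each lineage evolves along before the species-tree radiation; it
    controls how separable the lineages are in sequence space.
    """

    n_stem_lineages: int = 5
    dup_rate: float = 0.01
    loss_rate: float = 0.01
    seq_length: int = 150
    n_invariant_anchors: int = 5
    subst_rate_scale: float = 1.0
    stem_divergence: float = 0.6
    planted_feature_spec: Dict[str, str] = field(
        default_factory=lambda: {"L1": "secretion", "L2": "dual_acylation"}
    )
    n_decoys: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dup_rate < 0 or self.loss_rate < 0:
            raise SimulationError("duplication and loss rates must be >= 0")
        if self.subst_rate_scale < 0 or self.stem_divergence < 0:
            raise SimulationError("substitution scales must be >= 0")
        if self.n_invariant_anchors >= self.seq_length:
            raise SimulationError("n_invariant_anchors must be < seq_length")
        if self.n_stem_lineages < 1:
            raise SimulationError("need at least one stem lineage")
        for lin, feat in self.planted_feature_spec.items():
            if feat not in FEATURES:
                raise SimulationError(f"unknown planted feature {feat!r} for {lin}")

    def lineages(self) -> List[str]:
        return [f"L{i + 1}" for i in range(self.n_stem_lineages)]

    def template(self) -> str:
        if self.seq_length <= len(TEMPLATE_SEQUENCE):
            return TEMPLATE_SEQUENCE[: self.seq_length]
        reps = -(-self.seq_length // len(TEMPLATE_SEQUENCE))
        return (TEMPLATE_SEQUENCE * reps)[: self.seq_length]

    def anchors(self) -> Tuple[int, ...]:
        fixed = [p for p in ANCHOR_POSITIONS if p < self.seq_length]
        if self.n_invariant_anchors <= len(fixed):
            return tuple(fixed[: self.n_invariant_anchors])
        # spread extra anchors evenly over the tail of the sequence
        extra = self.n_invariant_anchors - len(fixed)
        taken = set(fixed)
        pos = [
            int(round(8 + i * (self.seq_length - 9) / max(extra, 1)))
            for i in range(extra)
        ]
        for p in pos:
            while p in taken or p >= self.seq_length:
                p = (p + 1) % self.seq_length
                if p < 8:
                    p = 8
            taken.add(p)
        return tuple(sorted(taken))

    def feature_of(self, lineage: str) -> str:
        return self.planted_feature_spec.get(lineage, "none")


class GeneNode:
    """Node of a simulated gene tree (lengths in species-tree branch units)."""

    __slots__ = ("name", "length", "children", "kind")

    def __init__(self, name=None, length=0.0, children=None, kind="speciation"):
        self.name = name
        self.length = length
        self.children = children or []
        self.kind = kind  # speciation | duplication | leaf | root

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> List["GeneNode"]:
        if self.is_leaf():
            return [self]
        out: List[GeneNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def newick(self) -> str:
        return self._nwk() + ";"

    def _nwk(self) -> str:
        if self.is_leaf():
            return f"{self.name}:{self.length:.6g}"
        inner = ",".join(c._nwk() for c in self.children)
        label = self.name or ""
        return f"({inner}){label}:{self.length:.6g}"


@dataclass
class SimTruth:
    """Ground truth of one simulation run."""

    params: SimParams
    species_tree: SpeciesTree
    gene_roots: Dict[str, GeneNode]  # lineage -> gene-tree root (may be extinct)
    event_list: pd.DataFrame  # columns: lineage, branch, event
    clade_membership: Dict[str, str]  # gene id -> lineage
    presence: pd.DataFrame  # lineage x species gene counts
    planted_features: Dict[str, str]  # gene id -> feature
    node_counts: Dict[Tuple[str, str], int]  # (lineage, node label) -> copy count
    core_sequences: Optional[Dict[str, str]] = None  # set by evolve_sequences
    stem_sequences: Optional[Dict[str, str]] = None  # lineage -> stem sequence

    def genes(self) -> List[str]:
        return sorted(self.clade_membership)

    def genes_of(self, lineage: str) -> List[str]:
        return sorted(g for g, l in self.clade_membership.items() if l == lineage)

    def gene_tree_newick(self) -> str:
        """One Newick for the whole family: lineage subtrees joined at a root
        by stem branches of length ``stem_divergence``."""
        parts = []
        for lin in self.params.lineages():
            root = self.gene_roots.get(lin)
            if root is None:
                continue
            sub = root._nwk()
            # re-head the lineage subtree with the stem branch length
            base, _, _ = sub.rpartition(":")
            parts.append(f"{base}:{self.params.stem_divergence:.6g}")
        if not parts:
            return ";"
        if len(parts) == 1:
            return f"({parts[0]});"
        return "(" + ",".join(parts) + ");"

    def presence_flags(self, lineage: str) -> Dict[str, bool]:
        row = self.presence.loc[lineage]
        return {sp: bool(row[sp] > 0) for sp in self.presence.columns}


# ---------------------------------------------------------------------------
# Birth--death simulation


def simulate_gene_family(tree: SpeciesTree, params: SimParams) -> SimTruth:
    """Run the per-lineage birth--death process along the species tree."""
    rng = np.random.default_rng([params.seed, 11])
    events: List[Tuple[str, str, str]] = []
    membership: Dict[str, str] = {}
    features: Dict[str, str] = {}
    node_counts: Dict[Tuple[str, str], int] = {}
    roots: Dict[str, GeneNode] = {}
    species = tree.species()

    for lineage in params.lineages():
        counters: Dict[str, int] = {}
        ctx = _SimContext(tree, params, rng, lineage, counters, events, node_counts)
        root_label = tree.root.label
        node_counts[(lineage, root_label)] = 1
        children = []
        for child in tree.root.child_nodes():
            sub = _copy_into_branch(ctx, child, child.edge.length or 0.0)
            if sub is not None:
                children.append(sub)
        if not children:
            roots[lineage] = None  # lineage extinct everywhere
            continue
        root = GeneNode(name=f"{lineage}_root", length=0.0, children=children, kind="root")
        roots[lineage] = root
        for leaf in root.leaves():
            membership[leaf.name] = lineage
            features[leaf.name] = params.feature_of(lineage)

    presence = pd.DataFrame(
        0, index=params.lineages(), columns=species, dtype=int
    )
    for gene, lin in membership.items():
        sp = gene.split("|")[0]
        presence.loc[lin, sp] += 1

    event_df = pd.DataFrame(events, columns=["lineage", "branch", "event"])
    return SimTruth(
        params=params,
        species_tree=tree,
        gene_roots=roots,
        event_list=event_df,
        clade_membership=membership,
        presence=presence,
        planted_features=features,
        node_counts=node_counts,
    )


class _SimContext:
    __slots__ = ("tree", "params", "rng", "lineage", "counters", "events", "node_counts")

    def __init__(self, tree, params, rng, lineage, counters, events, node_counts):
        self.tree = tree
        self.params = params
        self.rng = rng
        self.lineage = lineage
        self.counters = counters
        self.events = events
        self.node_counts = node_counts


def _copy_into_branch(ctx: _SimContext, species_child, t: float) -> Optional[GeneNode]:
    """One gene copy enters the branch above ``species_child``; draw its
    Poisson event counts for the branch and play them out in random order."""
    p = ctx.params
    n_dup = int(ctx.rng.poisson(p.dup_rate * t)) if t > 0 else 0
    n_loss = int(ctx.rng.poisson(p.loss_rate * t)) if t > 0 else 0
    n_ev = n_dup + n_loss
    if n_ev:
        positions = np.sort(ctx.rng.uniform(0.0, t, size=n_ev))
        kinds = np.array(["D"] * n_dup + ["L"] * n_loss)
        ctx.rng.shuffle(kinds)
        queue = list(zip(positions.tolist(), kinds.tolist()))
    else:
        queue = []
    return _play_events(ctx, species_child, t, 0.0, queue)


def _play_events(ctx, species_child, t, offset, queue) -> Optional[GeneNode]:
    """Play the remaining event queue for a copy born at ``offset`` on a
    branch of total length ``t``; returns the gene subtree from that point."""
    branch = species_child.label
    for i, (pos, kind) in enumerate(queue):
        if kind == "L":
            ctx.events.append((ctx.lineage, branch, "loss"))
            return None
        # duplication: the new copy explores the rest of the branch with
        # fresh draws; the current copy keeps its remaining queued events
        ctx.events.append((ctx.lineage, branch, "duplication"))
        right = _copy_into_branch(ctx, species_child, t - pos)
        left = _play_events(ctx, species_child, t, pos, queue[i + 1 :])
        if left is None and right is None:
            return None
        if left is None or right is None:
            survivor = left if right is None else right
            survivor.length += pos - offset
            return survivor
        # both children are measured from the duplication point already
        node = GeneNode(length=pos - offset, children=[left, right], kind="duplication")
        return node
    # reached the species node at the end of the branch
    _record_arrival(ctx, species_child)
    if species_child.is_leaf():
        sp = species_child.label
        k = ctx.counters.get(sp, 0) + 1
        ctx.counters[sp] = k
        name = qualified_id(sp, f"{ctx.lineage}.g{k}")
        return GeneNode(name=name, length=t - offset, kind="leaf")
    children = []
    for grandchild in species_child.child_nodes():
        sub = _copy_into_branch(ctx, grandchild, grandchild.edge.length or 0.0)
        if sub is not None:
            children.append(sub)
    if not children:
        return None
    if len(children) == 1:
        only = children[0]
        only.length += t - offset
        return only
    return GeneNode(length=t - offset, children=children, kind="speciation")


def _record_arrival(ctx, species_node) -> None:
    key = (ctx.lineage, species_node.label)
    ctx.node_counts[key] = ctx.node_counts.get(key, 0) + 1


# ---------------------------------------------------------------------------
# Sequence evolution


def _mutate(seq: str, t: float, anchors: set, rng) -> str:
    """Per-site substitution: each non-anchor site is replaced with
    probability 1 - exp(-t) by a uniform draw from the 19 other residues."""
    if t <= 0:
        return seq
    p_sub = 1.0 - math.exp(-t)
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < p_sub)[0]
    for i in hits:
        if i in anchors:
            continue
        old = chars[i]
        choices = AMINO_ACIDS.replace(old, "")
        chars[i] = choices[int(rng.integers(len(choices)))]
    return "".join(chars)


def evolve_sequences(truth: SimTruth, params: SimParams) -> Dict[str, str]:
    """Evolve core sequences down each lineage's gene tree, then apply the
    lineage's planted N-terminal feature.  Returns gene id -> full sequence.

    Core (template-coordinate) sequences are also retained on the truth
    object as ``truth.core_sequences`` for alignment-based steps: planted
    secretion signals are N-terminal extensions, so the core is always the
    trailing ``seq_length`` residues of the emitted protein.
    """
    rng = np.random.default_rng([params.seed, 23])
    anchors = set(params.anchors())
    template = params.template()
    scale = params.subst_rate_scale
    core: Dict[str, str] = {}
    stems: Dict[str, str] = {}

    for lineage in params.lineages():
        root = truth.gene_roots.get(lineage)
        root_seq = _mutate(template, params.stem_divergence * scale, anchors, rng)
        stems[lineage] = root_seq
        if root is None:
            continue
        _evolve_node(root, root_seq, anchors, scale, rng, core)

    full: Dict[str, str] = {}
    for gene, seq in core.items():
        feat = truth.planted_features.get(gene, "none")
        if feat == "secretion":
            full[gene] = SIGNAL_PEPTIDE + seq
        elif feat == "dual_acylation":
            full[gene] = ACYLATION_MOTIF + seq[len(ACYLATION_MOTIF) :]
        else:
            full[gene] = seq
    truth.core_sequences = core
    truth.stem_sequences = stems
    return full


def _evolve_node(node: GeneNode, seq: str, anchors, scale, rng, out) -> None:
    for child in node.children:
        child_seq = _mutate(seq, child.length * scale, anchors, rng)
        if child.is_leaf():
            out[child.name] = child_seq
        else:
            _evolve_node(child, child_seq, anchors, scale, rng, out)


def make_decoys(params: SimParams, species: Sequence[str]) -> List[ProteinRecord]:
    """Shuffled-composition decoy proteins, ``n_decoys`` per species."""
    rng = np.random.default_rng([params.seed, 37])
    template = params.template()
    out = []
    for sp in species:
        for k in range(params.n_decoys):
            letters = np.array(list(template))
            rng.shuffle(letters)
            out.append(
                ProteinRecord(
                    id=qualified_id(sp, f"decoy{k + 1:03d}"),
                    species=sp,
                    sequence="".join(letters.tolist()),
                )
            )
    return out


def reference_set(
    truth: SimTruth, params: SimParams
) -> Tuple[List[ProteinRecord], pd.DataFrame]:
    """Labelled reference database for reciprocal validation: the lineage
    stem sequences plus the template as globins, and independently shuffled
    sequences as non-globins.  Requires ``evolve_sequences`` to have run."""
    if truth.stem_sequences is None:
        raise SimulationError("evolve_sequences must run before reference_set")
    rng = np.random.default_rng([params.seed, 41])
    template = params.template()
    refs: List[ProteinRecord] = []
    labels = []
    for lineage in params.lineages():
        stem = truth.stem_sequences[lineage]
        refs.append(ProteinRecord(id=f"ref|{lineage}", species="ref", sequence=stem))
        labels.append((f"ref|{lineage}", "globin"))
    refs.append(ProteinRecord(id="ref|template", species="ref", sequence=template))
    labels.append(("ref|template", "globin"))
    for k in range(6):
        letters = np.array(list(template))
        rng.shuffle(letters)
        rid = f"ref|nonglobin{k + 1}"
        refs.append(ProteinRecord(id=rid, species="ref", sequence="".join(letters.tolist())))
        labels.append((rid, "non-globin"))
    table = pd.DataFrame(labels, columns=["id", "label"])
    return refs, table


# ---------------------------------------------------------------------------
# qPCR plate generator


def simulate_ct_table(
    seed: int,
    genes: Sequence[str] = ("Egb-A1a", "Egb-A2", "Egb-B1"),
    gene_scale: Optional[Dict[str, float]] = None,
    n_bio: int = 3,
    n_tech: int = 2,
    noise_sd: float = 0.3,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a qPCR Ct table with reference genes and replicate structure.

    Target Cts are anchored to the reference-gene mean so the planted relative
    level of gene g at stage s is ``profile[s] * gene_scale[g]``; biological
    noise is shared by the two technical replicates of a sample and technical
    noise (one tenth of the biological spread) is added on top.

    Returns the long-format Ct table (stage, gene, bio_rep, tech_rep, Ct) and
    the planted per-gene stage profile for comparison with recovered values.
    """
    rng = np.random.default_rng([seed, 53])
    gene_scale = gene_scale or {g: 1.0 / (i + 1) for i, g in enumerate(genes)}
    rows = []
    truth_rows = []
    for stage, base_level in zip(QPCR_STAGES, QPCR_STAGE_PROFILE):
        for b in range(1, n_bio + 1):
            ref_cts = {}
            for ref, base_ct in QPCR_REFERENCE_GENES.items():
                ct0 = base_ct + rng.normal(0.0, noise_sd / 2)
                ref_cts[ref] = ct0
                for t in range(1, n_tech + 1):
                    rows.append((stage, ref, b, t, ct0 + rng.normal(0.0, noise_sd / 10)))
            ref_mean = float(np.mean(list(ref_cts.values())))
            for gene in genes:
                level = base_level * gene_scale[gene]
                ct0 = ref_mean - math.log2(level) + rng.normal(0.0, noise_sd)
                for t in range(1, n_tech + 1):
                    rows.append((stage, gene, b, t, ct0 + rng.normal(0.0, noise_sd / 10)))
        for gene in genes:
            truth_rows.append((stage, gene, base_level * gene_scale[gene]))
    table = pd.DataFrame(rows, columns=["stage", "gene", "bio_rep", "tech_rep", "Ct"])
    truth = pd.DataFrame(truth_rows, columns=["stage", "gene", "level"])
    return table, truth


# ---------------------------------------------------------------------------
# Fixture emission


def emit_fixture(truth: SimTruth, sequences: Dict[str, str], out_dir) -> Dict[str, Path]:
    """Write the complete fixture bundle for one simulation run.

    Layout::

        proteomes/<species>.fa   globins + decoys, shuffled record order
        reference_set.fa / reference_labels.tsv
        loci.gff3                gene loci; secretion-lineage genes clustered
        predictors.tsv           signal/acylation calls consistent with truth
        gene_tree.nwk            true gene tree (all lineages)
        truth_genes.tsv          gene, species, lineage, feature
        truth_presence.tsv       lineage x species gene counts
        events.tsv               simulated duplication/loss events
        ct_table.tsv / ct_truth.tsv
    """
    params = truth.params
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([params.seed, 67])
    species = truth.species_tree.species()
    paths: Dict[str, Path] = {}

    decoys = make_decoys(params, species)
    decoys_by_sp: Dict[str, List[ProteinRecord]] = {}
    for d in decoys:
        decoys_by_sp.setdefault(d.species, []).append(d)

    proteome_dir = out / "proteomes"
    for sp in species:
        recs = [
            ProteinRecord(id=g, species=sp, sequence=sequences[g])
            for g in sorted(truth.clade_membership)
            if g.startswith(sp + "|")
        ]
        recs.extend(decoys_by_sp.get(sp, []))
        order = rng.permutation(len(recs))
        write_fasta([recs[i] for i in order], proteome_dir / f"{sp}.fa")
    paths["proteomes"] = proteome_dir

    refs, labels = reference_set(truth, params)
    write_fasta(refs, out / "reference_set.fa")
    write_tsv(labels, out / "reference_labels.tsv")
    paths["reference_set"] = out / "reference_set.fa"
    paths["reference_labels"] = out / "reference_labels.tsv"

    paths["loci"] = _emit_loci(truth, sequences, out / "loci.gff3")
    paths["predictors"] = _emit_predictors(truth, sequences, out / "predictors.tsv")

    (out / "gene_tree.nwk").write_text(truth.gene_tree_newick() + "\n")
    paths["gene_tree"] = out / "gene_tree.nwk"

    genes = pd.DataFrame(
        [
            (g, g.split("|")[0], lin, truth.planted_features[g])
            for g, lin in sorted(truth.clade_membership.items())
        ],
        columns=["gene", "species", "lineage", "feature"],
    )
    write_tsv(genes, out / "truth_genes.tsv")
    paths["truth_genes"] = out / "truth_genes.tsv"

    presence = truth.presence.copy()
    presence.index.name = "lineage"
    write_tsv(presence.reset_index(), out / "truth_presence.tsv")
    paths["truth_presence"] = out / "truth_presence.tsv"

    write_tsv(truth.event_list, out / "events.tsv")
    paths["events"] = out / "events.tsv"

    ct, ct_truth = simulate_ct_table(params.seed)
    write_tsv(ct, out / "ct_table.tsv")
    write_tsv(ct_truth, out / "ct_truth.tsv")
    paths["ct_table"] = out / "ct_table.tsv"
    paths["ct_truth"] = out / "ct_truth.tsv"
    return paths


def _emit_loci(truth: SimTruth, sequences: Dict[str, str], path: Path) -> Path:
    """Place genes on scaffolds: secretion-lineage genes form one compact
    cluster per species (with the last two genes overlapping when there are
    at least two, emulating a nested-exon gene pair); all other genes sit on
    their own scaffolds."""
    lines = ["##gff-version 3"]
    for sp in truth.species_tree.species():
        genes = sorted(g for g in truth.clade_membership if g.startswith(sp + "|"))
        clustered = [g for g in genes if truth.planted_features[g] == "secretion"]
        isolated = [g for g in genes if g not in set(clustered)]
        cursor = 1001
        scaffold = f"{sp}_scaf1"
        prev_end = None
        for i, g in enumerate(clustered):
            length = 3 * len(sequences[g]) + 400  # coding length plus introns
            if i == len(clustered) - 1 and prev_end is not None and len(clustered) >= 2:
                start = prev_end - 150  # overlap the previous gene's tail
            else:
                start = cursor
            end = start + length - 1
            strand = "+" if i % 2 == 0 else "-"
            lines.append(_gff_line(scaffold, start, end, strand, g))
            prev_end = end
            cursor = end + 2000
        for j, g in enumerate(isolated):
            length = 3 * len(sequences[g]) + 400
            lines.append(
                _gff_line(f"{sp}_scaf{j + 2}", 5001, 5000 + length, "+", g)
            )
    path.write_text("\n".join(lines) + "\n")
    return path


def _gff_line(scaffold: str, start: int, end: int, strand: str, gene_id: str) -> str:
    return "\t".join(
        [
            scaffold,
            "stemglobin_sim",
            "gene",
            str(start),
            str(end),
            ".",
            strand,
            ".",
            f"ID={gene_id}",
        ]
    )


def _emit_predictors(truth: SimTruth, sequences: Dict[str, str], path: Path) -> Path:
    rows = []
    for g in sorted(truth.clade_membership):
        feat = truth.planted_features[g]
        rows.append(
            (
                g,
                feat == "secretion",
                str(MYRISTOYLATION_SITE) if feat == "dual_acylation" else "",
                str(PALMITOYLATION_SITE) if feat == "dual_acylation" else "",
                "external",
            )
        )
    df = pd.DataFrame(
        rows, columns=["gene", "signal_peptide", "myr_sites", "palm_sites", "source"]
    )
    write_tsv(df, path)
    return path


def read_presence_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df.set_index("lineage")
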