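"""Unrooted gene-tree analysis: supported bipartitions, clade classification,
root exclusion, alignment statistics, and a neighbour-joining stand-in tree
builder for synthetic tests.

The clade-delineation procedure works on an *unrooted* tree with branch
supports in [0, 1] (aLRT-style or bootstrap proportions; values on a 0-100
scale are rescaled with a warning).  A "natural clade" is a well-supported
bipartition side whose species composition spans several bilaterian
superphyla (pan-bilaterian: no non-bilaterian species; pan-metazoan: at least
one non-bilaterian metazoan group as well) and which does not itself contain
two disjoint well-supported sub-clades each broadly sampling the bilaterians
-- the single-ancestral-gene criterion.  Because every bipartition has two
sides and natural clades nest, the delineation keeps only maximal qualifying
sides.  Root placement is then constrained negatively: no edge strictly
inside a natural clade or a supported mono-species radiation can carry the
root.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import dendropy
import numpy as np
import pandas as pd

from .records import split_id
from .species import BILATERIAN_GROUPS, NON_BILATERIAN_GROUPS


class TreeError(ValueError):
    pass


class TreeParseError(TreeError):
    pass


#: Canonical identifier of an unrooted edge: the frozenset of its two sides.
EdgeKey = FrozenSet[FrozenSet[str]]


def edge_key(side: FrozenSet[str], all_leaves: FrozenSet[str]) -> EdgeKey:
    return frozenset({side, all_leaves - side})


@dataclass(frozen=True)
class Bipartition:
    side_a: FrozenSet[str]
    side_b: FrozenSet[str]
    support: Optional[float]

    @property
    def key(self) -> EdgeKey:
        return frozenset({self.side_a, self.side_b})

    @property
    def sides(self) -> Tuple[FrozenSet[str], FrozenSet[str]]:
        return (self.side_a, self.side_b)


@dataclass
class Thresholds:
    strong_support: float = 0.95
    moderate_support: float = 0.75
    min_species: int = 4
    min_superphyla: int = 2
    mono_min_genes: int = 3

    def __post_init__(self) -> None:
        if not 0 <= self.moderate_support <= self.strong_support <= 1:
            raise TreeError("need 0 <= moderate <= strong <= 1")


@dataclass
class CladeCall:
    leafset: FrozenSet[str]
    support: Optional[float]
    species: FrozenSet[str]
    category: str  # pan-bilaterian | pan-metazoan | mono-species | spiralian-only | other
    single_ancestral_gene: bool = True
    label: str = "unclassified"
    diagnostics: List[str] = field(default_factory=list)


class SupportTree:
    """An unrooted gene tree with per-bipartition supports.

    Backed by a (conventionally rooted) dendropy tree; every analysis here is
    a function of the bipartition set only, so results do not depend on the
    arbitrary rooting of the Newick text.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        self._rescale_supports()

    # -- construction ------------------------------------------------------

    @classmethod
    def parse(cls, text: str) -> "SupportTree":
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several error types
            raise TreeParseError(f"malformed Newick: {exc}") from exc
        if len(tree.leaf_nodes()) < 2:
            raise TreeParseError("tree needs at least two leaves")
        return cls(tree)

    def _rescale_supports(self) -> None:
        vals = []
        for node in self.tree.preorder_internal_node_iter():
            s = _label_to_support(node.label)
            if s is not None:
                vals.append(s)
        if vals and max(vals) > 1.0:
            warnings.warn(
                "supports look like percentages (max > 1); rescaling by 1/100",
                stacklevel=2,
            )
            for node in self.tree.preorder_internal_node_iter():
                s = _label_to_support(node.label)
                if s is not None:
                    node.label = f"{s / 100.0:g}"
        for node in self.tree.preorder_internal_node_iter():
            s = _label_to_support(node.label)
            if s is not None and not 0 <= s <= 1:
                raise TreeError(f"support {s} outside [0, 1]")

    # -- basic queries -----------------------------------------------------

    def leaf_names(self) -> FrozenSet[str]:
        return frozenset(
            (leaf.taxon.label if leaf.taxon else leaf.label)
            for leaf in self.tree.leaf_node_iter()
        )

    def species_of(self, leaf: str) -> str:
        return split_id(leaf)[0]

    def bipartitions(self, include_trivial: bool = False) -> List[Bipartition]:
        """All distinct unrooted bipartitions; non-trivial ones (both sides
        with >= 2 leaves) unless ``include_trivial``."""
        all_leaves = self.leaf_names()
        by_key: Dict[EdgeKey, Optional[float]] = {}
        for node in self.tree.preorder_node_iter():
            if node is self.tree.seed_node:
                continue
            side = frozenset(
                (l.taxon.label if l.taxon else l.label) for l in node.leaf_iter()
            )
            if len(side) == len(all_leaves):
                continue
            key = edge_key(side, all_leaves)
            support = None
            if not node.is_leaf():
                support = _label_to_support(node.label)
            if key in by_key:
                prev = by_key[key]
                by_key[key] = max(
                    (x for x in (prev, support) if x is not None), default=None
                )
            else:
                by_key[key] = support
        out = []
        for key, support in by_key.items():
            a, b = tuple(key)
            if not include_trivial and min(len(a), len(b)) < 2:
                continue
            out.append(Bipartition(side_a=a, side_b=b, support=support))
        return out

    def all_edge_keys(self) -> Set[EdgeKey]:
        return {bp.key for bp in self.bipartitions(include_trivial=True)}

    def write(self) -> str:
        return self.tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        ).strip()


def _label_to_support(label) -> Optional[float]:
    if label is None or label == "":
        return None
    try:
        return float(label)
    except (TypeError, ValueError):
        return None


def parse_support_newick(text: str) -> SupportTree:
    return SupportTree.parse(text)


# ---------------------------------------------------------------------------
# Clade classification


def supported_clades(tree: SupportTree, threshold: float) -> List[Bipartition]:
    """All bipartitions with support >= threshold (unsupported edges never
    qualify)."""
    return [
        bp
        for bp in tree.bipartitions()
        if bp.support is not None and bp.support >= threshold
    ]


def _species_and_groups(
    leafset: Iterable[str], taxon_map: Dict[str, str]
) -> Tuple[FrozenSet[str], FrozenSet[str]]:
    species = set()
    for leaf in leafset:
        sp = split_id(leaf)[0]
        species.add(sp)
        if sp not in taxon_map:
            raise TreeError(f"species {sp!r} missing from taxon map")
    groups = frozenset(taxon_map[sp] for sp in species)
    return frozenset(species), groups


def classify_clade(
    leafset: FrozenSet[str],
    taxon_map: Dict[str, str],
    thresholds: Optional[Thresholds] = None,
) -> str:
    """Category from species composition alone."""
    th = thresholds or Thresholds()
    species, groups = _species_and_groups(leafset, taxon_map)
    bilat = groups & BILATERIAN_GROUPS
    non_bilat_metazoan = groups & NON_BILATERIAN_GROUPS
    has_non_bilaterian = bool(groups - BILATERIAN_GROUPS)  # incl. outgroups
    if len(species) == 1 and len(leafset) >= th.mono_min_genes:
        return "mono-species"
    if len(bilat) >= th.min_superphyla and not has_non_bilaterian:
        return "pan-bilaterian"
    if len(bilat) >= th.min_superphyla and non_bilat_metazoan:
        return "pan-metazoan"
    if groups == {"Spiralia"} and len(species) >= th.min_species:
        return "spiralian-only"
    return "other"


def is_broadly_sampled(
    leafset: FrozenSet[str],
    taxon_map: Dict[str, str],
    thresholds: Optional[Thresholds] = None,
) -> bool:
    """A "large panel of metazoan species": spans >= min_superphyla bilaterian
    superphyla and >= min_species species (non-bilaterian presence ignored)."""
    th = thresholds or Thresholds()
    species, groups = _species_and_groups(leafset, taxon_map)
    return (
        len(groups & BILATERIAN_GROUPS) >= th.min_superphyla
        and len(species) >= th.min_species
    )


def single_ancestral_gene_check(
    leafset: FrozenSet[str],
    tree: SupportTree,
    taxon_map: Dict[str, str],
    thresholds: Optional[Thresholds] = None,
) -> bool:
    """False iff the clade contains two or more disjoint, well-supported
    sub-clades that are each broadly sampled -- evidence the grouping unites
    the descendants of several ancestral genes."""
    th = thresholds or Thresholds()
    subsides = []
    for bp in supported_clades(tree, th.strong_support):
        for side in bp.sides:
            if side < leafset and is_broadly_sampled(side, taxon_map, th):
                subsides.append(side)
    for i, a in enumerate(subsides):
        for b in subsides[i + 1 :]:
            if not (a & b):
                return False
    return True


def delineate_natural_clades(
    tree: SupportTree,
    taxon_map: Dict[str, str],
    thresholds: Optional[Thresholds] = None,
) -> List[CladeCall]:
    """The paper-style clade inventory: maximal well-supported bipartition
    sides that are pan-bilaterian or pan-metazoan, broadly sampled, and pass
    the single-ancestral-gene criterion."""
    th = thresholds or Thresholds()
    candidates: List[CladeCall] = []
    for bp in supported_clades(tree, th.strong_support):
        for side in bp.sides:
            category = classify_clade(side, taxon_map, th)
            if category not in {"pan-bilaterian", "pan-metazoan"}:
                continue
            if not is_broadly_sampled(side, taxon_map, th):
                continue
            if not single_ancestral_gene_check(side, tree, taxon_map, th):
                continue
            species, _ = _species_and_groups(side, taxon_map)
            candidates.append(
                CladeCall(
                    leafset=side,
                    support=bp.support,
                    species=species,
                    category=category,
                    single_ancestral_gene=True,
                )
            )
    maximal = [
        c
        for c in candidates
        if not any(c.leafset < other.leafset for other in candidates)
    ]
    maximal.sort(key=lambda c: sorted(c.leafset))
    return maximal


def call_clades(
    tree: SupportTree,
    taxon_map: Dict[str, str],
    thresholds: Optional[Thresholds] = None,
) -> List[CladeCall]:
    """Classify every well-supported bipartition side (the full report the
    delineation draws from)."""
    th = thresholds or Thresholds()
    calls = []
    for bp in supported_clades(tree, th.strong_support):
        for side in bp.sides:
            species, _ = _species_and_groups(side, taxon_map)
            calls.append(
                CladeCall(
                    leafset=side,
                    support=bp.support,
                    species=species,
                    category=classify_clade(side, taxon_map, th),
                    single_ancestral_gene=single_ancestral_gene_check(
                        side, tree, taxon_map, th
                    ),
                )
            )
    return calls


def mono_species_clades(
    tree: SupportTree,
    taxon_map: Dict[str, str],
    thresholds: Optional[Thresholds] = None,
) -> List[FrozenSet[str]]:
    th = thresholds or Thresholds()
    out = []
    for bp in supported_clades(tree, th.strong_support):
        for side in bp.sides:
            if classify_clade(side, taxon_map, th) == "mono-species":
                out.append(side)
    return out


# ---------------------------------------------------------------------------
# Root exclusion


def allowed_root_edges(
    tree: SupportTree,
    accepted_clades: Sequence[FrozenSet[str]],
    mono_species: Sequence[FrozenSet[str]] = (),
) -> Set[EdgeKey]:
    """Edges that could still carry the root: everything except edges
    strictly inside an accepted natural clade or a supported mono-species
    clade.  A clade's own defining edge remains allowed."""
    all_leaves = tree.leaf_names()
    excluded_within = list(accepted_clades) + list(mono_species)
    allowed: Set[EdgeKey] = set()
    for key in tree.all_edge_keys():
        sides = tuple(key)
        inside = any(
            any(side < clade for side in sides) for clade in excluded_within
        )
        if not inside:
            allowed.add(key)
    if not allowed:
        raise TreeError(
            "no admissible root edge: accepted clades cover the whole tree"
        )
    return allowed


# ---------------------------------------------------------------------------
# Clade labels from reference anchors


def assign_clade_labels(
    clade_calls: Sequence[CladeCall], anchor_table: Dict[str, str]
) -> List[CladeCall]:
    """A clade is named L iff it contains at least one anchor gene of label L
    and no anchor of any other label; conflicting anchors leave the clade
    unclassified with a diagnostic."""
    for call in clade_calls:
        labels = {anchor_table[g] for g in call.leafset if g in anchor_table}
        if len(labels) == 1:
            call.label = labels.pop()
        elif len(labels) > 1:
            call.label = "unclassified"
            call.diagnostics.append(
                f"conflicting anchors: {', '.join(sorted(labels))}"
            )
    return list(clade_calls)


# ---------------------------------------------------------------------------
# Alignment statistics


def count_informative_sites(
    alignment: Dict[str, str], count_gaps_as_state: bool = False
) -> Tuple[int, int, int]:
    """(n_sequences, n_informative, n_invariant) for an aligned set of rows.

    A column is parsimony-informative when at least two states each occur in
    at least two sequences; invariant when a single state occurs (gaps are
    missing data by default)."""
    seqs = list(alignment.values())
    if not seqs:
        raise TreeError("empty alignment")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise TreeError("ragged alignment")
    n_informative = 0
    n_invariant = 0
    for col in range(length):
        counts: Dict[str, int] = {}
        for s in seqs:
            ch = s[col]
            if ch in {"-", "."} and not count_gaps_as_state:
                continue
            counts[ch] = counts.get(ch, 0) + 1
        if len(counts) == 1:
            n_invariant += 1
        if sum(1 for v in counts.values() if v >= 2) >= 2:
            n_informative += 1
    return len(seqs), n_informative, n_invariant


# ---------------------------------------------------------------------------
# Neighbour-joining + bootstrap stand-in tree builder


def _encode_alignment(alignment: Dict[str, str]) -> Tuple[List[str], np.ndarray]:
    names = sorted(alignment)
    length = len(alignment[names[0]])
    if any(len(alignment[n]) != length for n in names):
        raise TreeError("ragged alignment")
    arr = np.frombuffer(
        "".join(alignment[n] for n in names).encode("ascii"), dtype=np.uint8
    ).reshape(len(names), length)
    return names, arr


def poisson_distances(arr: np.ndarray, cap_p: float = 0.95) -> np.ndarray:
    """Poisson-corrected pairwise distances d = -ln(1 - p); p-distances at or
    above ``cap_p`` (saturation) are capped with a warning."""
    diff = arr[:, None, :] != arr[None, :, :]
    p = diff.mean(axis=2)
    if (p >= cap_p).any():
        warnings.warn("saturated p-distances capped before log correction", stacklevel=2)
    p = np.minimum(p, cap_p)
    d = -np.log1p(-p)
    np.fill_diagonal(d, 0.0)
    return d


def _nj_from_matrix(d: np.ndarray, names: List[str]) -> dendropy.Tree:
    import io

    from skbio import DistanceMatrix
    from skbio.tree import nj

    dm = DistanceMatrix(d, names)
    sk = nj(dm)
    buf = io.StringIO()
    sk.write(buf)
    newick = buf.getvalue()
    return dendropy.Tree.get(
        data=newick,
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )


def nj_tree(alignment: Dict[str, str]) -> SupportTree:
    """Neighbour-joining tree on Poisson-corrected distances (no supports)."""
    if len(alignment) < 4:
        raise TreeError("need at least 4 sequences")
    names, arr = _encode_alignment(alignment)
    d = poisson_distances(arr)
    return SupportTree(_nj_from_matrix(d, names))


def _bipartition_keys_from_tree(tree: dendropy.Tree, all_leaves: FrozenSet[str]) -> Set[EdgeKey]:
    keys: Set[EdgeKey] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(
            (l.taxon.label if l.taxon else l.label) for l in node.leaf_iter()
        )
        if 2 <= len(side) <= len(all_leaves) - 2:
            keys.add(edge_key(side, all_leaves))
    return keys


def bootstrap_support(
    alignment: Dict[str, str], replicates: int = 100, seed: int = 0
) -> SupportTree:
    """NJ tree with bootstrap-proportion supports from column resampling.

    Deterministic given the seed; supports are attached to the internal nodes
    of the tree built from the full alignment.
    """
    if len(alignment) < 4:
        raise TreeError("need at least 4 sequences")
    names, arr = _encode_alignment(alignment)
    all_leaves = frozenset(names)
    base = _nj_from_matrix(poisson_distances(arr), names)
    rng = np.random.default_rng([seed, 71])
    counts: Dict[EdgeKey, int] = {}
    n_cols = arr.shape[1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # saturation warnings repeat per replicate
        for _ in range(replicates):
            cols = rng.integers(0, n_cols, size=n_cols)
            rep_tree = _nj_from_matrix(poisson_distances(arr[:, cols]), names)
            for key in _bipartition_keys_from_tree(rep_tree, all_leaves):
                counts[key] = counts.get(key, 0) + 1
    for node in base.preorder_node_iter():
        if node is base.seed_node or node.is_leaf():
            continue
        side = frozenset(
            (l.taxon.label if l.taxon else l.label) for l in node.leaf_iter()
        )
        if 2 <= len(side) <= len(all_leaves) - 2:
            key = edge_key(side, all_leaves)
            node.label = f"{counts.get(key, 0) / replicates:g}"
        else:
            node.label = None
    return SupportTree(base)


def clade_report(calls: Sequence[CladeCall]) -> pd.DataFrame:
    rows = [
        (
            i + 1,
            c.support if c.support is not None else float("nan"),
            c.category,
            c.single_ancestral_gene,
            c.label,
            len(c.leafset),
            len(c.species),
            ";".join(sorted(c.leafset)),
        )
        for i, c in enumerate(calls)
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "clade",
            "support",
            "category",
            "single_ancestral_gene",
            "label",
            "n_genes",
            "n_species",
            "members",
        ],
    )
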