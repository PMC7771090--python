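"""Rooted species trees with taxonomic group annotations.

The analyses in this package run on a fixed metazoan species topology: a set
of non-bilaterian outgroups (sponge, ctenophore, placozoan, cnidarian, plus a
choanoflagellate-grade outgroup) and the three bilaterian superphyla
(Deuterostomia, Ecdysozoa, Spiralia).  Branch lengths are expected amino-acid
substitutions per site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterator, List, Optional

import dendropy

#: Recognised taxonomic groups for species annotations.
TAXON_GROUPS = (
    "Porifera",
    "Ctenophora",
    "Placozoa",
    "Cnidaria",
    "Deuterostomia",
    "Ecdysozoa",
    "Spiralia",
    "Outgroup",
)

#: The three bilaterian superphyla.
BILATERIAN_GROUPS = frozenset({"Deuterostomia", "Ecdysozoa", "Spiralia"})
NON_BILATERIAN_GROUPS = frozenset({"Porifera", "Ctenophora", "Placozoa", "Cnidaria"})

#: Default 12-species metazoan topology used by the simulator and the
#: reconstruction examples.  Internal node labels name the usual ancestors.
DEFAULT_SPECIES_NEWICK = (
    "(Monosiga:0.50,(Mnemiopsis:0.45,(Amphimedon:0.40,(Trichoplax:0.35,"
    "(Nematostella:0.30,((Homo:0.20,Branchiostoma:0.20)Deuterostomia:0.10,"
    "((Drosophila:0.18,Caenorhabditis:0.22)Ecdysozoa:0.08,"
    "((Platynereis:0.12,Capitella:0.14)Annelida:0.05,Lottia:0.16)Spiralia:0.08)"
    "Protostomia:0.05)Bilateria:0.10)Eumetazoa:0.05)Parahoxozoa:0.05)"
    "Metazoa:0.05)Animalia:0.00)root;"
)

DEFAULT_TAXON_GROUPS: Dict[str, str] = {
    "Monosiga": "Outgroup",
    "Mnemiopsis": "Ctenophora",
    "Amphimedon": "Porifera",
    "Trichoplax": "Placozoa",
    "Nematostella": "Cnidaria",
    "Homo": "Deuterostomia",
    "Branchiostoma": "Deuterostomia",
    "Drosophila": "Ecdysozoa",
    "Caenorhabditis": "Ecdysozoa",
    "Platynereis": "Spiralia",
    "Capitella": "Spiralia",
    "Lottia": "Spiralia",
}


class SpeciesTreeError(ValueError):
    pass


@dataclass
class SpeciesTree:
    """A rooted species tree plus a total species -> taxon group mapping.

    Edges are named after their child node: internal nodes keep their Newick
    labels (auto-generated ``nodeNN`` labels are assigned where missing), so
    an edge such as the vertebrate stem can be reported unambiguously as the
    edge above node ``Deuterostomia``.
    """

    tree: dendropy.Tree
    taxon_groups: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        counter = 0
        for node in self.tree.preorder_node_iter():
            if node.is_leaf():
                name = node.taxon.label if node.taxon else node.label
                if not name:
                    raise SpeciesTreeError("unnamed leaf in species tree")
                node.label = name
            elif not node.label:
                node.label = f"node{counter}"
                counter += 1
            if node.edge.length is None:
                node.edge.length = 0.0
            if node.edge.length < 0:
                raise SpeciesTreeError(
                    f"negative branch length above {node.label!r}"
                )
        missing = [s for s in self.species() if s not in self.taxon_groups]
        if missing:
            raise SpeciesTreeError(f"species without taxon group: {missing}")
        bad = {g for g in self.taxon_groups.values() if g not in TAXON_GROUPS}
        if bad:
            raise SpeciesTreeError(f"unknown taxon groups: {sorted(bad)}")

    @classmethod
    def from_newick(
        cls, newick: str, taxon_groups: Optional[Dict[str, str]] = None
    ) -> "SpeciesTree":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls(tree=tree, taxon_groups=dict(taxon_groups or {}))

    @classmethod
    def default(cls) -> "SpeciesTree":
        return cls.from_newick(DEFAULT_SPECIES_NEWICK, DEFAULT_TAXON_GROUPS)

    # -- basic queries -----------------------------------------------------

    def species(self) -> List[str]:
        return [leaf.label for leaf in self.tree.leaf_node_iter()]

    def group_of(self, species: str) -> str:
        return self.taxon_groups[species]

    @property
    def root(self) -> dendropy.Node:
        return self.tree.seed_node

    def node(self, label: str) -> dendropy.Node:
        for n in self.tree.preorder_node_iter():
            if n.label == label:
                return n
        raise KeyError(label)

    def preorder(self) -> Iterator[dendropy.Node]:
        return self.tree.preorder_node_iter()

    def leaves_under(self, node: dendropy.Node) -> FrozenSet[str]:
        return frozenset(leaf.label for leaf in node.leaf_iter())

    def mrca(self, species: List[str]) -> dendropy.Node:
        labels = set(species)
        node = self.tree.mrca(
            taxa=[t for t in self.tree.taxon_namespace if t.label in labels]
        )
        if node is None:
            raise SpeciesTreeError(f"no MRCA for {sorted(labels)}")
        return node

    def to_newick(self) -> str:
        return self.tree.as_string(
            schema="newick", suppress_rooting=True
        ).strip()
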