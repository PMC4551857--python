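"""Labelled gene sets, disjointness enforcement, and ontology propagation.

The immune-system (IS) and neurological-system (NS) gene sets used throughout
the analysis are made disjoint by dropping genes annotated to both, so that
cross-set co-expression is never inflated by shared members. Gene → GO
annotations are propagated child → parent along is_a edges so that a gene
annotated to a specific term also counts for every ancestor term in the
table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import networkx as nx
import pandas as pd

__all__ = [
    "GeneSetCollection",
    "AnnotationTable",
    "Ontology",
    "enforce_disjoint",
    "propagate_annotations",
    "load_tnf_upregulated_fixture",
    "read_gmt",
    "write_gmt",
    "TNF_FIXTURE_CATEGORIES",
]

#: GO categories of the packaged TNF-alpha up-regulated gene fixture.
TNF_FIXTURE_CATEGORIES: dict[str, str] = {
    "GO:0002376": "immune system process",
    "GO:0006955": "immune response",
    "GO:0050900": "leukocyte migration",
    "GO:0002682": "regulation of immune system process",
    "GO:0002684": "positive regulation of immune system process",
    "GO:0002253": "activation of immune response",
}


def enforce_disjoint(set_a, set_b) -> tuple[frozenset, frozenset]:
    """Remove genes shared by both sets from each.

    Returns the two reduced sets; their intersection is empty by
    construction. Genes outside the intersection are untouched.
    """
    a, b = frozenset(set_a), frozenset(set_b)
    shared = a & b
    return a - shared, b - shared


@dataclass
class GeneSetCollection:
    """Named gene sets over a background universe.

    Every set must be a subset of ``background``.
    """

    sets: dict[str, frozenset]
    background: frozenset

    def __post_init__(self) -> None:
        self.background = frozenset(self.background)
        self.sets = {k: frozenset(v) for k, v in self.sets.items()}
        for name, genes in self.sets.items():
            stray = genes - self.background
            if stray:
                raise ValueError(
                    f"set {name!r} contains genes outside the background: "
                    f"{sorted(stray)[:5]}"
                )

    def make_disjoint(self, name_a: str, name_b: str) -> "GeneSetCollection":
        """Return a collection where the two named sets share no genes."""
        a, b = enforce_disjoint(self.sets[name_a], self.sets[name_b])
        new = dict(self.sets)
        new[name_a], new[name_b] = a, b
        return GeneSetCollection(new, self.background)

    def __getitem__(self, name: str) -> frozenset:
        return self.sets[name]


@dataclass
class Ontology:
    """is_a edges of an ontology as a child → parent DAG."""

    graph: nx.DiGraph  # edge child -> parent

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise ValueError(f"ontology is_a graph contains a cycle: {cycle}")

    @classmethod
    def from_edges(cls, is_a_edges) -> "Ontology":
        g = nx.DiGraph()
        for child, parent in is_a_edges:
            g.add_edge(child, parent)
        return cls(g)

    @classmethod
    def from_obo(cls, path, include_part_of: bool = False) -> "Ontology":
        """Read an OBO file, keeping is_a (and optionally part_of) relations."""
        import obonet

        raw = obonet.read_obo(path)
        g = nx.DiGraph()
        g.add_nodes_from(raw.nodes)
        for child, parent, key in raw.edges(keys=True):
            if key == "is_a" or (include_part_of and key == "part_of"):
                g.add_edge(child, parent)
        return cls(g)

    def ancestors(self, term: str) -> frozenset:
        """All terms reachable from ``term`` along child → parent edges."""
        if term not in self.graph:
            return frozenset()
        return frozenset(nx.descendants(self.graph, term))


@dataclass
class AnnotationTable:
    """Gene × GO-category incidence over a fixed background universe.

    ``incidence`` is a boolean DataFrame indexed by the background genes with
    category identifiers as columns; ``category_names`` maps identifiers to
    readable names.
    """

    incidence: pd.DataFrame
    category_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.incidence = self.incidence.astype(bool)
        if self.incidence.index.has_duplicates:
            raise ValueError("duplicate genes in annotation background")
        if self.incidence.columns.has_duplicates:
            raise ValueError("duplicate category identifiers")

    @property
    def background_genes(self) -> list[str]:
        return list(self.incidence.index)

    @property
    def categories(self) -> list[str]:
        return list(self.incidence.columns)

    def genes_in(self, category: str) -> frozenset:
        if category not in self.incidence.columns:
            raise KeyError(f"unknown category {category!r}")
        col = self.incidence[category]
        return frozenset(col.index[col])

    def category_sizes(self) -> pd.Series:
        return self.incidence.sum(axis=0)

    @classmethod
    def from_pairs(cls, background, gene_category_pairs, category_names=None) -> "AnnotationTable":
        """Build from (gene, category) pairs over an explicit background."""
        background = list(dict.fromkeys(background))
        cats = list(dict.fromkeys(c for _, c in gene_category_pairs))
        inc = pd.DataFrame(False, index=background, columns=cats)
        for gene, cat in gene_category_pairs:
            if gene not in inc.index:
                raise ValueError(f"annotated gene {gene!r} not in background")
            inc.loc[gene, cat] = True
        return cls(inc, dict(category_names or {}))

    @classmethod
    def read_tsv(cls, path, background=None) -> "AnnotationTable":
        """Read long-format TSV with columns gene, category[, name]."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        genes = df.iloc[:, 0]
        cats = df.iloc[:, 1]
        names = {}
        if df.shape[1] >= 3:
            names = dict(zip(cats, df.iloc[:, 2]))
        bg = background if background is not None else genes.unique()
        return cls.from_pairs(bg, list(zip(genes, cats)), names)

    def write_tsv(self, path) -> None:
        rows = [
            (g, c, self.category_names.get(c, ""))
            for c in self.categories
            for g in sorted(self.genes_in(c))
        ]
        pd.DataFrame(rows, columns=["gene_id", "category_id", "category_name"]).to_csv(
            path, sep="\t", index=False
        )


def propagate_annotations(annot: AnnotationTable, ontology: Ontology) -> AnnotationTable:
    """Propagate annotations child → parent along is_a edges.

    A gene annotated to a term becomes annotated to every ancestor of that
    term that appears in the table; multiple paths to the same ancestor count
    once. The operation is idempotent and never removes a mark.
    """
    inc = annot.incidence.copy()
    present = set(inc.columns)
    for term in annot.categories:
        targets = [a for a in ontology.ancestors(term) if a in present]
        for anc in targets:
            inc[anc] = inc[anc] | inc[term]
    return AnnotationTable(inc, dict(annot.category_names))


def load_tnf_upregulated_fixture() -> AnnotationTable:
    """Load the packaged 31-gene × 6-category membership table.

    These are the immune-system-associated genes significantly up-regulated
    in TNF-alpha-stimulated sympathetic neuron cultures, with their
    memberships in six immune-system GO categories.
    """
    ref = resources.files("neurocoex.data").joinpath("tnf_upregulated_is_genes.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", dtype=str)
    pairs = [
        (row.gene_id, cat)
        for row in df.itertuples()
        for cat in str(row.categories).split(",")
    ]
    return AnnotationTable.from_pairs(df["gene_id"], pairs, TNF_FIXTURE_CATEGORIES)


def read_gmt(path, background=None) -> GeneSetCollection:
    """Read gene sets from a GMT file (set name, description, members...)."""
    sets: dict[str, frozenset] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            sets[parts[0]] = frozenset(g for g in parts[2:] if g)
    bg = background if background is not None else frozenset().union(*sets.values())
    return GeneSetCollection(sets, frozenset(bg))


def write_gmt(collection: GeneSetCollection, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, description, *sorted(genes)]) + "\n")
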