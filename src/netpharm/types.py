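"""Domain containers shared across the pipeline.

Light dataclasses around the field's standard in-memory objects: the
interaction network wraps a :class:`networkx.Graph`, the GO DAG keeps
explicit ``is_a`` parent links next to a child index for fast downward
traversal, and docking records mirror one row of a PatchDock-style result
table.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

from .errors import ValidationError

#: Allowed GO namespaces.
GO_NAMESPACES = ("biological_process", "molecular_function", "cellular_component")

#: STRING-style integer confidence scale (0-1000) vs normalized reals (0-1).
SCORE_SCALES = ("string", "unit")


@dataclass
class TargetEvidence:
    """A candidate drug target with its two evidence flags.

    ``in_literature`` records support from literature mining (LM);
    ``in_pharmacophore`` support from pharmacophore mapping (PMR), with the
    mapping fit score when one was reported.
    """

    target_id: str
    in_literature: bool = False
    in_pharmacophore: bool = False
    pharmacophore_fit: Optional[float] = None
    source_note: str = ""

    def __post_init__(self) -> None:
        if not self.target_id:
            raise ValidationError("target_id must be non-empty")
        if not (self.in_literature or self.in_pharmacophore):
            raise ValidationError(
                f"target {self.target_id!r}: at least one evidence flag must be set"
            )
        if self.pharmacophore_fit is not None and self.pharmacophore_fit < 0:
            raise ValidationError(
                f"target {self.target_id!r}: pharmacophore fit must be nonnegative"
            )


class InteractionNetwork:
    """Undirected weighted protein/gene interaction network.

    Wraps an undirected :class:`networkx.Graph` whose edges carry a
    ``weight`` attribute on the declared score scale: ``"string"`` for
    integer combined scores in [0, 1000], ``"unit"`` for reals in [0, 1].
    Self-loops are rejected; duplicate edges collapse onto the first weight.
    """

    def __init__(self, score_scale: str = "unit", source: str = "") -> None:
        if score_scale not in SCORE_SCALES:
            raise ValidationError(f"unknown score scale {score_scale!r}")
        self.graph = nx.Graph()
        self.score_scale = score_scale
        self.source = source

    # -- construction -------------------------------------------------
    def add_node(self, node: str) -> None:
        self.graph.add_node(node)

    def add_edge(self, u: str, v: str, weight: float) -> bool:
        """Add an undirected edge; returns False if it was a duplicate.

        Raises :class:`ValidationError` on self-loops or out-of-scale
        weights.
        """
        if u == v:
            raise ValidationError(f"self-loop on {u!r} not allowed")
        hi = 1000.0 if self.score_scale == "string" else 1.0
        if not (0.0 <= weight <= hi):
            raise ValidationError(
                f"edge ({u!r}, {v!r}): weight {weight} outside [0, {hi:g}] "
                f"for scale {self.score_scale!r}"
            )
        if self.graph.has_edge(u, v):
            return False
        self.graph.add_edge(u, v, weight=float(weight))
        return True

    # -- accessors ----------------------------------------------------
    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    def number_of_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()

    def __contains__(self, node: str) -> bool:
        return node in self.graph

    def weight(self, u: str, v: str) -> float:
        return self.graph.edges[u, v]["weight"]

    def normalized_weight(self, u: str, v: str) -> float:
        """Edge weight mapped onto [0, 1] regardless of declared scale."""
        w = self.weight(u, v)
        return w / 1000.0 if self.score_scale == "string" else w

    def neighbors(self, node: str) -> Iterable[str]:
        if node not in self.graph:
            raise KeyError(f"node {node!r} not in network")
        return self.graph.neighbors(node)

    def degree(self, node: str) -> int:
        if node not in self.graph:
            raise KeyError(f"node {node!r} not in network")
        return self.graph.degree[node]

    def strength(self, node: str) -> float:
        """Sum of incident edge weights (normalized scale)."""
        return sum(self.normalized_weight(node, nb) for nb in self.neighbors(node))


@dataclass
class GoDag:
    """Gene Ontology DAG restricted to ``is_a`` links.

    ``terms`` maps a term id to ``(name, namespace)``; ``parents`` maps a
    child id to its set of ``is_a`` parents. The child index is derived
    lazily for downward traversal (descendant enumeration).
    """

    terms: dict = field(default_factory=dict)  # id -> (name, namespace)
    parents: dict = field(default_factory=dict)  # id -> set of parent ids

    def __post_init__(self) -> None:
        self._children: Optional[dict] = None

    def add_term(self, term_id: str, name: str, namespace: str) -> None:
        if namespace not in GO_NAMESPACES:
            raise ValidationError(
                f"term {term_id}: unknown namespace {namespace!r}"
            )
        self.terms[term_id] = (name, namespace)
        self.parents.setdefault(term_id, set())
        self._children = None

    def add_is_a(self, child: str, parent: str) -> None:
        for t in (child, parent):
            if t not in self.terms:
                raise ValidationError(f"is_a link references undeclared term {t!r}")
        self.parents.setdefault(child, set()).add(parent)
        self._children = None

    def validate(self) -> None:
        """Check acyclicity and referential integrity."""
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for child, ps in self.parents.items():
            for p in ps:
                if p not in self.terms:
                    raise ValidationError(
                        f"term {child} has undeclared parent {p!r}"
                    )
                g.add_edge(child, p)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            return
        path = " -> ".join(str(u) for u, _ in cycle)
        raise ValidationError(f"cyclic is_a chain: {path} -> {cycle[0][0]}")

    @property
    def children(self) -> Mapping[str, set]:
        if self._children is None:
            idx = defaultdict(set)
            for t in self.terms:
                idx[t]  # ensure key exists
            for child, ps in self.parents.items():
                for p in ps:
                    idx[p].add(child)
            self._children = dict(idx)
        return self._children

    def namespace(self, term_id: str) -> str:
        return self.terms[term_id][1]

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms


@dataclass
class GoAnnotation:
    """Gene-to-GO-term assignments with duplicates collapsed."""

    assignments: set = field(default_factory=set)  # {(gene, term)}

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple], dag: GoDag) -> "GoAnnotation":
        ann = cls()
        for gene, term in pairs:
            if term not in dag:
                raise ValidationError(
                    f"annotation of {gene!r} to unknown term {term!r}"
                )
            ann.assignments.add((gene, term))
        return ann

    def gene_counts(self, genes: Optional[set] = None) -> dict:
        """gp(g): number of distinct genes directly annotated to each term.

        Restricted to ``genes`` when given.
        """
        counts: dict = defaultdict(set)
        for gene, term in self.assignments:
            if genes is None or gene in genes:
                counts[term].add(gene)
        return {t: len(gs) for t, gs in counts.items()}

    def genes(self) -> set:
        return {g for g, _ in self.assignments}


@dataclass
class PathwayGeneSet:
    """One GMT record: a named pathway with its member genes."""

    pathway_id: str
    description: str
    members: frozenset

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"pathway {self.pathway_id!r} has no members")


@dataclass(frozen=True)
class DockingRecord:
    """One row of a PatchDock-style docking result table.

    ``geom_score`` is the geometric shape complementarity score (higher is
    better), ``ace`` the atomic contact energy in kcal/mol-like units
    (lower, i.e. more negative, is better), ``transform`` the rigid-body
    placement (three rotations, three translations).
    """

    pdb_id: str
    uniprot: str
    geom_score: int
    area: float
    ace: float
    transform: tuple

    def __post_init__(self) -> None:
        if len(self.pdb_id) != 4:
            raise ValidationError(f"PDB id {self.pdb_id!r} must be 4 characters")
        if self.geom_score <= 0:
            raise ValidationError(
                f"{self.pdb_id}: geometric score must be positive"
            )
        if len(self.transform) != 6:
            raise ValidationError(
                f"{self.pdb_id}: transform must have 6 components, "
                f"got {len(self.transform)}"
            )
        if self.area <= 0:
            raise ValidationError(f"{self.pdb_id}: area must be positive")


@dataclass
class NodeMetrics:
    """Per-node graph statistics."""

    node: str
    degree: int
    clustering: float
    betweenness: float
    strength: float


@dataclass
class NetworkSummary:
    """Network-level statistics: degree distribution and assortativity."""

    degree_distribution: dict
    assortativity_pcc: Optional[float]
    assortativity_scc: Optional[float]


@dataclass
class ScreenedTarget:
    """A target classified as primary / secondary / predicted."""

    target_id: str
    klass: str
    evidence: TargetEvidence


@dataclass
class CoexpressionModule:
    """A seed target with its top-k interaction partners by confidence."""

    seed: str
    members: Sequence  # [(gene, edge score)], weight-desc, ties lexicographic
    k: int

    @property
    def genes(self) -> list:
        return [g for g, _ in self.members]


@dataclass
class McWeights:
    """Weights of the five module-construction score components."""

    w_ces: float = 1.0
    w_gos: float = 1.0
    w_clc: float = 1.0
    w_bwc: float = 1.0
    w_don: float = 1.0

    def __post_init__(self) -> None:
        vals = (self.w_ces, self.w_gos, self.w_clc, self.w_bwc, self.w_don)
        if any(w < 0 for w in vals):
            raise ValidationError("MC weights must be nonnegative")
        if not any(w > 0 for w in vals):
            raise ValidationError("at least one MC weight must be positive")


@dataclass
class ModuleScore:
    """Raw and normalized component values plus the combined MC score."""

    node: str
    ces: float
    gos: float
    clc: float
    bwc: float
    don: float
    norm: dict  # component name -> normalized value in [0, 1]
    mc: float


@dataclass
class PathwayHit:
    """A module-to-pathway overlap with its hypergeometric statistics."""

    pathway_id: str
    module_seed: str
    overlap_genes: frozenset
    overlap_size: int
    pathway_size: int
    module_size: int
    universe_size: int
    p_value: float
    q_value: float


@dataclass
class DockingRanking:
    """Docking records with per-key and combined ranks."""

    records: list  # DockingRecord
    geom_rank: dict  # record index -> rank (1 = highest geometric score)
    ace_rank: dict  # record index -> rank (1 = most negative ACE)
    combined_order: list  # record indices sorted by (geom+ace rank, pdb_id)
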