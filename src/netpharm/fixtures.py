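"""Seeded generators for every input the pipeline consumes.

Everything is driven by a :class:`FixtureSpec` and a single integer seed;
the same spec always produces identical objects (and, written through
:mod:`netpharm.io`, byte-identical files). Two graph models are provided:
a homogeneous uniform random graph and a heavy-tailed preferential
attachment graph. ``gen_planted`` adds a dense, high-confidence module on
a background graph — the recoverability benchmark for the MC ranking.

``table1_fixture`` loads the package's verbatim transcription of the
published PatchDock result table (panel A: Picroside-I, 12 complexes;
panel B: Picroside-II, 14 complexes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import List, Set, Tuple

import numpy as np
from scipy.stats import truncnorm

from . import io
from .errors import ValidationError
from .types import (
    DockingRecord,
    GoAnnotation,
    GoDag,
    InteractionNetwork,
    TargetEvidence,
    GO_NAMESPACES,
)


@dataclass
class FixtureSpec:
    """Parameters of all synthetic inputs.

    Graph: ``n_nodes`` nodes; uniform model with edge probability
    ``edge_prob`` or preferential attachment with ``attachment`` edges per
    new node. Planted module: ``planted_size`` nodes wired with
    ``planted_edge_prob`` and weight mean ``planted_weight_mean`` against
    a background of ``edge_prob`` / ``background_weight_mean``. Weights are
    truncated-normal with ``weight_sd`` on the unit scale.

    GO DAG: per namespace, ``dag_layers`` layers with ``dag_branching``
    children per term; each non-root term draws 1-2 parents from the layer
    above. Each (gene, term) pair is annotated with probability
    ``annotation_rate``.

    Evidence: ``n_literature`` / ``n_pharmacophore`` targets with exactly
    ``n_overlap`` in common; pharmacophore fit scores are uniform on
    ``fit_range``.
    """

    seed: int = 0
    # graph
    n_nodes: int = 50
    edge_prob: float = 0.05
    model: str = "uniform"  # or "preferential"
    attachment: int = 2
    background_weight_mean: float = 0.3
    weight_sd: float = 0.05
    # planted module
    planted_size: int = 8
    planted_edge_prob: float = 0.9
    planted_weight_mean: float = 0.9
    # GO DAG + annotations
    dag_layers: int = 3
    dag_branching: int = 2
    annotation_rate: float = 0.08
    n_genes: int = 20
    # evidence
    n_literature: int = 12
    n_pharmacophore: int = 15
    n_overlap: int = 6
    fit_range: Tuple[float, float] = (10.0, 100.0)

    def __post_init__(self) -> None:
        for p in (self.edge_prob, self.planted_edge_prob, self.annotation_rate):
            if not (0 <= p <= 1):
                raise ValidationError(f"probability {p} outside [0, 1]")
        if self.planted_size > self.n_nodes:
            raise ValidationError("planted module larger than the network")
        if self.n_overlap > min(self.n_literature, self.n_pharmacophore):
            raise ValidationError("overlap exceeds an evidence stream size")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _node_names(n: int) -> List[str]:
    return [f"G{i:03d}" for i in range(n)]


def _weight(rng: np.random.Generator, mean: float, sd: float) -> float:
    """One truncated-normal confidence on [0, 1]."""
    a, b = (0.0 - mean) / sd, (1.0 - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def gen_network(spec: FixtureSpec) -> InteractionNetwork:
    """A background interaction network without a planted module."""
    rng = spec.rng()
    names = _node_names(spec.n_nodes)
    net = InteractionNetwork(score_scale="unit", source="synthetic")
    for name in names:
        net.add_node(name)
    if spec.model == "uniform":
        for i in range(spec.n_nodes):
            for j in range(i + 1, spec.n_nodes):
                if rng.random() < spec.edge_prob:
                    net.add_edge(
                        names[i],
                        names[j],
                        _weight(rng, spec.background_weight_mean, spec.weight_sd),
                    )
    elif spec.model == "preferential":
        # Barabási–Albert style growth from a small seed clique
        m = max(1, spec.attachment)
        targets = list(range(m))
        repeated: List[int] = []
        for new in range(m, spec.n_nodes):
            chosen: Set[int] = set()
            pool = repeated if repeated else targets
            while len(chosen) < min(m, new):
                chosen.add(int(pool[rng.integers(len(pool))]))
            for t in chosen:
                net.add_edge(
                    names[new],
                    names[t],
                    _weight(rng, spec.background_weight_mean, spec.weight_sd),
                )
            repeated.extend(chosen)
            repeated.extend([new] * len(chosen))
    else:
        raise ValidationError(f"unknown graph model {spec.model!r}")
    return net


def gen_planted(spec: FixtureSpec) -> Tuple[InteractionNetwork, Set[str]]:
    """Background network plus a dense high-confidence planted module.

    Returns the network and the planted node set. Within-module pairs are
    wired with ``planted_edge_prob`` and weight mean
    ``planted_weight_mean``; every other pair follows the background
    parameters.
    """
    rng = spec.rng()
    names = _node_names(spec.n_nodes)
    planted = set(
        names[i] for i in rng.choice(spec.n_nodes, spec.planted_size, replace=False)
    )
    net = InteractionNetwork(score_scale="unit", source="synthetic-planted")
    for name in names:
        net.add_node(name)
    for i in range(spec.n_nodes):
        for j in range(i + 1, spec.n_nodes):
            u, v = names[i], names[j]
            inside = u in planted and v in planted
            p = spec.planted_edge_prob if inside else spec.edge_prob
            mean = spec.planted_weight_mean if inside else spec.background_weight_mean
            if rng.random() < p:
                net.add_edge(u, v, _weight(rng, mean, spec.weight_sd))
    return net, planted


def gen_dag(spec: FixtureSpec) -> Tuple[GoDag, GoAnnotation]:
    """A layered random ontology over all three namespaces, plus annotations.

    Each namespace gets one root and ``dag_layers - 1`` further layers; a
    term in layer L draws one or two parents from layer L-1, so the graph
    is acyclic by construction. Genes are the spec's ``n_genes`` synthetic
    gene names; each (gene, term) pair is annotated independently with
    probability ``annotation_rate``.
    """
    rng = spec.rng()
    dag = GoDag()
    prefix = {"biological_process": "BP", "molecular_function": "MF",
              "cellular_component": "CC"}
    for ns in GO_NAMESPACES:
        layers: List[List[str]] = []
        root = f"GO:{prefix[ns]}0000"
        dag.add_term(root, f"{ns} root", ns)
        layers.append([root])
        count = 1
        for layer in range(1, spec.dag_layers):
            width = len(layers[-1]) * spec.dag_branching
            ids = []
            for _ in range(width):
                tid = f"GO:{prefix[ns]}{count:04d}"
                count += 1
                dag.add_term(tid, f"{ns} term {tid}", ns)
                n_parents = 1 if len(layers[-1]) == 1 else int(rng.integers(1, 3))
                parents = rng.choice(
                    len(layers[-1]), min(n_parents, len(layers[-1])), replace=False
                )
                for p in parents:
                    dag.add_is_a(tid, layers[-1][int(p)])
                ids.append(tid)
            layers.append(ids)
    dag.validate()

    genes = _node_names(spec.n_genes)
    pairs = [
        (g, t)
        for g in genes
        for t in sorted(dag.terms)
        if rng.random() < spec.annotation_rate
    ]
    return dag, GoAnnotation.from_pairs(pairs, dag)


def gen_evidence(
    spec: FixtureSpec,
) -> Tuple[List[TargetEvidence], List[TargetEvidence]]:
    """Literature and pharmacophore evidence with an exact overlap count.

    Returns two single-stream record lists whose target-id intersection has
    exactly ``n_overlap`` members. Pharmacophore fits are uniform on
    ``fit_range``.
    """
    rng = spec.rng()
    total = spec.n_literature + spec.n_pharmacophore - spec.n_overlap
    ids = [f"T{i:03d}" for i in range(total)]
    order = [ids[i] for i in rng.permutation(total)]
    shared = order[: spec.n_overlap]
    lit_only = order[spec.n_overlap : spec.n_literature]
    pmr_only = order[spec.n_literature :]

    lit = [
        TargetEvidence(t, in_literature=True, source_note="literature")
        for t in sorted(shared + lit_only)
    ]
    lo, hi = spec.fit_range
    pmr = [
        TargetEvidence(
            t,
            in_pharmacophore=True,
            pharmacophore_fit=float(np.round(rng.uniform(lo, hi), 2)),
            source_note="pharmacophore",
        )
        for t in sorted(shared + pmr_only)
    ]
    return lit, pmr


def gen_pathways(spec: FixtureSpec, planted: Set[str]) -> List["PathwayGeneSet"]:
    """Reference gene sets over the synthetic gene universe.

    One pathway contains the planted module (so module-to-pathway mapping
    has a true positive); the rest are random draws from the node names.
    """
    from .types import PathwayGeneSet

    rng = spec.rng()
    names = _node_names(spec.n_nodes)
    sets = [
        PathwayGeneSet(
            "pw_planted", "synthetic pathway containing the planted module",
            frozenset(planted),
        )
    ]
    for i in range(4):
        size = int(rng.integers(5, 13))
        members = frozenset(
            names[j] for j in rng.choice(spec.n_nodes, size, replace=False)
        )
        sets.append(PathwayGeneSet(f"pw_{i:02d}", f"synthetic pathway {i}", members))
    return sets


def emit_fixture_files(spec: FixtureSpec, outdir) -> dict:
    """Write one complete synthetic input set and return its path map.

    Emits the same dialects the readers consume: evidence TSVs, edge TSV,
    OBO, annotation TSV, GMT and a docking table (the shipped panel-A
    transcription). Target ids for the evidence are drawn from the network
    node names so the screened primaries exist in the graph; the planted
    module nodes are preferred so downstream stages have signal.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    net, planted = gen_planted(spec)

    # evidence over network node names, planted nodes first
    rng = spec.rng()
    names = sorted(planted) + [n for n in _node_names(spec.n_nodes) if n not in planted]
    total = spec.n_literature + spec.n_pharmacophore - spec.n_overlap
    ids = names[:total]
    shared = ids[: spec.n_overlap]
    lit_ids = shared + ids[spec.n_overlap : spec.n_literature]
    pmr_ids = shared + ids[spec.n_literature :]
    lo, hi = spec.fit_range
    lit = [TargetEvidence(t, in_literature=True) for t in sorted(lit_ids)]
    pmr = [
        TargetEvidence(
            t, in_pharmacophore=True,
            pharmacophore_fit=float(np.round(rng.uniform(lo, hi), 2)),
        )
        for t in sorted(pmr_ids)
    ]

    dag_spec = FixtureSpec(
        seed=spec.seed + 1, n_genes=spec.n_nodes,
        dag_layers=spec.dag_layers, dag_branching=spec.dag_branching,
        annotation_rate=spec.annotation_rate,
    )
    dag, ann = gen_dag(dag_spec)
    pathways = gen_pathways(spec, planted)

    paths = {
        "literature": outdir / "literature.tsv",
        "pharmacophore": outdir / "pharmacophore.tsv",
        "edges": outdir / "edges.tsv",
        "obo": outdir / "go.obo",
        "annotations": outdir / "annotations.tsv",
        "gmt": outdir / "pathways.gmt",
        "docking": outdir / "docking.tsv",
    }
    io.write_target_evidence(lit, paths["literature"])
    io.write_target_evidence(pmr, paths["pharmacophore"])
    io.write_network(net, paths["edges"], format="tsv")
    io.write_obo(dag, paths["obo"])
    io.write_annotations(ann, paths["annotations"])
    io.write_gmt(pathways, paths["gmt"])
    io.write_docking_table(table1_fixture("A"), paths["docking"])
    return {name: str(p) for name, p in paths.items()}


_TABLE1_FILES = {"A": "table1_picroside1.tsv", "B": "table1_picroside2.tsv"}


def table1_fixture(panel: str) -> List[DockingRecord]:
    """The shipped transcription of the published docking result table.

    ``panel="A"`` is the Picroside-I screen (12 protein complexes),
    ``panel="B"`` the Picroside-II screen (14 complexes).
    """
    if panel not in _TABLE1_FILES:
        raise ValueError("panel must be 'A' or 'B'")
    ref = resources.files("netpharm.data") / _TABLE1_FILES[panel]
    with resources.as_file(ref) as path:
        return io.read_docking_table(path)
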