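"""Readers and writers for every external file the pipeline touches.

All tabular dialects are plain TSV with a header row; the OBO reader is a
thin validated layer over :mod:`obonet`. Readers fail loudly with
:class:`~netpharm.errors.FormatError` (naming the offending column or line)
or :class:`~netpharm.errors.ValidationError`; recoverable oddities (empty
files, dropped self-loops) emit :class:`UserWarning`.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import List, Optional

import networkx as nx
import obonet

from .errors import FormatError, ValidationError
from .types import (
    DockingRecord,
    GoAnnotation,
    GoDag,
    InteractionNetwork,
    PathwayGeneSet,
    TargetEvidence,
)

_EVIDENCE_STREAMS = ("literature", "pharmacophore")


def _split_header(line: str) -> List[str]:
    return line.rstrip("\n").split("\t")


# ---------------------------------------------------------------------------
# target evidence
# ---------------------------------------------------------------------------

def read_target_evidence(path, stream_label: str) -> List[TargetEvidence]:
    """Read a one-stream target list (TSV: ``target_id`` [, ``score``]).

    ``stream_label`` chooses which evidence flag the records carry:
    ``"literature"`` for literature-mining output, ``"pharmacophore"`` for a
    pharmacophore-mapping result table. Duplicate ids merge, keeping the
    maximum score.
    """
    if stream_label not in _EVIDENCE_STREAMS:
        raise ValueError(f"stream_label must be one of {_EVIDENCE_STREAMS}")
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].strip():
        warnings.warn(f"{path}: empty evidence file", stacklevel=2)
        return []
    header = _split_header(lines[0])
    if "target_id" not in header:
        raise FormatError(f"{path}: missing required column 'target_id'")
    id_col = header.index("target_id")
    score_col = header.index("score") if "score" in header else None

    best: dict = {}
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) <= id_col:
            raise FormatError(f"{path}:{ln}: too few columns")
        tid = fields[id_col].strip()
        if not tid:
            raise FormatError(f"{path}:{ln}: empty target_id")
        score: Optional[float] = None
        if score_col is not None and len(fields) > score_col and fields[score_col].strip():
            try:
                score = float(fields[score_col])
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: non-numeric score {fields[score_col]!r}") from exc
        if tid in best:
            old = best[tid]
            if score is not None and (old is None or score > old):
                best[tid] = score
        else:
            best[tid] = score

    is_lit = stream_label == "literature"
    return [
        TargetEvidence(
            target_id=tid,
            in_literature=is_lit,
            in_pharmacophore=not is_lit,
            pharmacophore_fit=None if is_lit else score,
            source_note=stream_label,
        )
        for tid, score in best.items()
    ]


def write_target_evidence(records: List[TargetEvidence], path) -> None:
    """Write one evidence stream back to its two-column TSV dialect."""
    with open(path, "w") as fh:
        fh.write("target_id\tscore\n")
        for r in records:
            score = "" if r.pharmacophore_fit is None else repr(r.pharmacophore_fit)
            fh.write(f"{r.target_id}\t{score}\n")


# ---------------------------------------------------------------------------
# interaction networks
# ---------------------------------------------------------------------------

def read_string_edges(path, score_scale: str = "string") -> InteractionNetwork:
    """Read a STRING-style edge list (protein1, protein2, combined_score).

    Columns may be tab- or whitespace-separated. ``score_scale`` declares
    the weight dialect: ``"string"`` for 0-1000 integer combined scores,
    ``"unit"`` for 0-1 reals. Reciprocal duplicates collapse onto the first
    weight; self-loops are dropped with a counted warning.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    net = InteractionNetwork(score_scale=score_scale, source=str(path))
    if not lines or not lines[0].strip():
        warnings.warn(f"{path}: empty edge file", stacklevel=2)
        return net
    header = lines[0].split()
    required = ("protein1", "protein2", "combined_score")
    for col in required:
        if col not in header:
            raise FormatError(f"{path}: missing required column {col!r}")
    c1, c2, cs = (header.index(col) for col in required)

    self_loops = 0
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) < len(header):
            raise FormatError(f"{path}:{ln}: expected {len(header)} columns")
        u, v, raw = fields[c1], fields[c2], fields[cs]
        try:
            w = float(raw)
        except ValueError as exc:
            raise FormatError(f"{path}:{ln}: non-numeric score {raw!r}") from exc
        if u == v:
            self_loops += 1
            continue
        try:
            net.add_edge(u, v, w)
        except ValidationError as exc:
            raise FormatError(f"{path}:{ln}: {exc}") from exc
    if self_loops:
        warnings.warn(f"{path}: dropped {self_loops} self-loop(s)", stacklevel=2)
    return net


def write_network(net: InteractionNetwork, path, format: str = "tsv") -> None:
    """Export a network as an edge TSV (weights preserved exactly) or SIF.

    The TSV format round-trips through :func:`read_string_edges`; SIF keeps
    topology only (``node1 pp node2``).
    """
    if format not in ("tsv", "sif"):
        raise ValueError(f"unknown network format {format!r}")
    with open(path, "w") as fh:
        if format == "tsv":
            fh.write("protein1\tprotein2\tcombined_score\n")
            for u, v in sorted(map(tuple, map(sorted, net.edges))):
                fh.write(f"{u}\t{v}\t{net.weight(u, v)!r}\n")
        else:
            for u, v in sorted(map(tuple, map(sorted, net.edges))):
                fh.write(f"{u}\tpp\t{v}\n")


# ---------------------------------------------------------------------------
# ontology and annotations
# ---------------------------------------------------------------------------

def read_obo_subset(path) -> GoDag:
    """Read an OBO 1.2 subset: ``[Term]`` stanzas with id/name/namespace/is_a.

    Only ``is_a`` links are kept (``part_of`` and other relationships are
    ignored). A cyclic ``is_a`` chain raises :class:`ValidationError`
    naming one cycle.
    """
    graph = obonet.read_obo(str(path))
    dag = GoDag()
    for term_id, data in graph.nodes(data=True):
        name = data.get("name", "")
        namespace = data.get("namespace")
        if namespace is None:
            raise FormatError(f"{path}: term {term_id} lacks a namespace")
        try:
            dag.add_term(term_id, name, namespace)
        except ValidationError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    # obonet edges point child -> parent, keyed by relationship type
    for child, parent, key in graph.edges(keys=True):
        if key != "is_a":
            continue
        dag.add_is_a(child, parent)
    dag.validate()
    return dag


def write_obo(dag: GoDag, path) -> None:
    """Write a GoDag back to the minimal OBO dialect the reader consumes."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: go-subset\n")
        for term_id in sorted(dag.terms):
            name, namespace = dag.terms[term_id]
            fh.write(f"\n[Term]\nid: {term_id}\nname: {name}\nnamespace: {namespace}\n")
            for parent in sorted(dag.parents.get(term_id, ())):
                pname = dag.terms[parent][0]
                fh.write(f"is_a: {parent} ! {pname}\n")


def read_annotations(path, dag: GoDag) -> GoAnnotation:
    """Read gene-to-term assignments: 2-column TSV or GAF-lite.

    Lines starting with ``!`` are comments. Rows with five or more tab
    fields are treated as GAF-lite (object id in column 2, GO id in column
    5); otherwise the first two columns are (gene, term). Annotations to
    terms absent from ``dag`` raise :class:`ValidationError`.
    """
    path = Path(path)
    pairs = []
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("!"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) >= 5:
            gene, term = fields[1], fields[4]
        elif len(fields) >= 2:
            gene, term = fields[0], fields[1]
        else:
            raise FormatError(f"{path}:{ln}: expected at least 2 tab-separated columns")
        if not gene or not term:
            raise FormatError(f"{path}:{ln}: empty gene or term id")
        pairs.append((gene, term))
    try:
        return GoAnnotation.from_pairs(pairs, dag)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_annotations(ann: GoAnnotation, path) -> None:
    with open(path, "w") as fh:
        for gene, term in sorted(ann.assignments):
            fh.write(f"{gene}\t{term}\n")


# ---------------------------------------------------------------------------
# pathway gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gmt(path) -> List[PathwayGeneSet]:
    """Read a GMT file: name TAB description TAB gene1 TAB gene2 ..."""
    path = Path(path)
    sets = []
    seen = set()
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(
                f"{path}:{ln}: GMT line needs name, description and >=1 gene"
            )
        name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
        if name in seen:
            raise ValidationError(f"{path}:{ln}: duplicate pathway id {name!r}")
        seen.add(name)
        if not genes:
            raise FormatError(f"{path}:{ln}: pathway {name!r} has no genes")
        sets.append(PathwayGeneSet(name, desc, frozenset(genes)))
    return sets


def write_gmt(sets: List[PathwayGeneSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            genes = "\t".join(sorted(s.members))
            fh.write(f"{s.pathway_id}\t{s.description}\t{genes}\n")


# ---------------------------------------------------------------------------
# docking tables
# ---------------------------------------------------------------------------

_DOCKING_COLS = ("pdb_id", "uniprot", "geom_score", "area", "ace", "transform")


def read_docking_table(path) -> List[DockingRecord]:
    """Read a docking result table in the PatchDock layout.

    TSV columns: pdb_id, uniprot, geom_score, area, ace, transform — where
    ``transform`` holds exactly six space-separated floats (three rotations,
    three translations of the rigid-body ligand placement).
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty docking table")
    header = _split_header(lines[0])
    for col in _DOCKING_COLS:
        if col not in header:
            raise FormatError(f"{path}: missing required column {col!r}")
    idx = {col: header.index(col) for col in _DOCKING_COLS}

    records = []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < len(header):
            raise FormatError(f"{path}:{ln}: expected {len(header)} columns")
        try:
            geom = int(fields[idx["geom_score"]])
            area = float(fields[idx["area"]])
            ace = float(fields[idx["ace"]])
            transform = tuple(float(x) for x in fields[idx["transform"]].split())
        except ValueError as exc:
            raise FormatError(f"{path}:{ln}: {exc}") from exc
        if len(transform) != 6:
            raise FormatError(
                f"{path}:{ln}: transform must have 6 floats, got {len(transform)}"
            )
        try:
            records.append(
                DockingRecord(
                    pdb_id=fields[idx["pdb_id"]],
                    uniprot=fields[idx["uniprot"]],
                    geom_score=geom,
                    area=area,
                    ace=ace,
                    transform=transform,
                )
            )
        except ValidationError as exc:
            raise FormatError(f"{path}:{ln}: {exc}") from exc
    return records


def write_docking_table(records: List[DockingRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_DOCKING_COLS) + "\n")
        for r in records:
            transform = " ".join(f"{x:.5f}" for x in r.transform)
            fh.write(
                f"{r.pdb_id}\t{r.uniprot}\t{r.geom_score}\t{r.area:g}\t{r.ace:g}\t{transform}\n"
            )
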