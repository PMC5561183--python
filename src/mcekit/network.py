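"""Sequence-similarity network construction and representative clustering.

Representative selection reproduces the greedy incremental (CD-HIT-style)
semantics over a caller-supplied identity table: proteins are processed
longest-first and join the first existing representative at or above the
identity cut-off.  The network itself keeps edges at or below an e-value
threshold (default 1e-15) and is exported as GraphML / SIF for Cytoscape.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .io import AlignmentEdge, ProteinRecord

__all__ = [
    "RepresentativeSet",
    "greedy_identity_clustering",
    "build_network",
    "connected_components",
    "write_graphml",
    "write_sif",
]

E_VALUE_THRESHOLD_DEFAULT = 1e-15


@dataclass(frozen=True)
class RepresentativeSet:
    """Partition of proteins into clusters keyed by their representative."""

    clusters: Mapping[str, tuple[str, ...]]
    identity_threshold: float

    @property
    def representatives(self) -> tuple[str, ...]:
        return tuple(self.clusters)

    def members(self) -> set[str]:
        return {m for ms in self.clusters.values() for m in ms}


def _identity_lookup(identities: Iterable[AlignmentEdge]) -> dict[frozenset, float]:
    table: dict[frozenset, float] = {}
    for e in identities:
        key = frozenset((e.query_id, e.subject_id))
        if len(key) < 2:
            continue
        table[key] = max(table.get(key, 0.0), e.pct_identity)
    return table


def greedy_identity_clustering(
    proteins: Sequence[ProteinRecord],
    identities: Iterable[AlignmentEdge],
    threshold: float = 0.5,
) -> RepresentativeSet:
    """Greedy longest-first clustering at a fractional identity cut-off.

    Proteins are visited in descending length (ties: lexicographic id); each
    joins the first existing representative with identity/100 >= *threshold*,
    else founds a new cluster.  Pairs absent from the identity table count
    as identity 0.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"identity threshold must be in (0, 1], got {threshold}")
    lookup = _identity_lookup(identities)
    order = sorted(proteins, key=lambda p: (-p.length, p.protein_id))
    clusters: dict[str, list[str]] = {}
    for p in order:
        home = None
        for rep in clusters:  # founding order
            ident = lookup.get(frozenset((rep, p.protein_id)), 0.0)
            if ident / 100.0 >= threshold:
                home = rep
                break
        if home is None:
            clusters[p.protein_id] = [p.protein_id]
        else:
            clusters[home].append(p.protein_id)
    return RepresentativeSet(
        clusters={rep: tuple(ms) for rep, ms in clusters.items()},
        identity_threshold=threshold,
    )


def build_network(
    edges: Iterable[AlignmentEdge],
    annotations: Mapping[str, Mapping[str, str]],
    e_threshold: float = E_VALUE_THRESHOLD_DEFAULT,
) -> nx.Graph:
    """Build the undirected similarity graph.

    *annotations* maps protein_id -> {"phylum": ..., "type_label": ...}; every
    annotated protein becomes a node (so edgeless representatives are kept as
    singletons).  An edge is kept iff its minimum directional e-value is
    <= *e_threshold* (inclusive); reciprocal hits collapse to one edge
    carrying the minimum e-value and maximum bit score.
    """
    graph = nx.Graph(e_threshold=e_threshold)
    for pid in sorted(annotations):
        ann = annotations[pid]
        graph.add_node(pid, phylum=ann["phylum"], type_label=ann["type_label"])

    missing: set[str] = set()
    for e in edges:
        if e.query_id == e.subject_id:
            continue
        if e.e_value > e_threshold:
            continue
        for endpoint in (e.query_id, e.subject_id):
            if endpoint not in annotations:
                missing.add(endpoint)
        if missing:
            continue
        u, v = e.query_id, e.subject_id
        if graph.has_edge(u, v):
            data = graph.edges[u, v]
            data["e_value"] = min(data["e_value"], e.e_value)
            data["bit_score"] = max(data["bit_score"], e.bit_score)
        else:
            graph.add_edge(u, v, e_value=e.e_value, bit_score=e.bit_score)
    if missing:
        raise KeyError(
            f"alignment edges reference unannotated proteins: {sorted(missing)}"
        )
    return graph


def connected_components(graph: nx.Graph) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label nodes with component ids and summarise composition.

    Components are numbered 0.. by descending size (ties: smallest member
    id).  Returns ``(labels, summary)``: per-node component assignment and a
    per-component row with size and phylum / type composition.
    """
    comps = sorted(
        (sorted(c) for c in nx.connected_components(graph)),
        key=lambda c: (-len(c), c[0]),
    )
    label_rows = []
    summary_rows = []
    for cid, members in enumerate(comps):
        phyla: dict[str, int] = {}
        types: dict[str, int] = {}
        for node in members:
            label_rows.append({"protein_id": node, "component_id": cid})
            attrs = graph.nodes[node]
            phyla[attrs.get("phylum", "?")] = phyla.get(attrs.get("phylum", "?"), 0) + 1
            types[attrs.get("type_label", "?")] = (
                types.get(attrs.get("type_label", "?"), 0) + 1
            )
        summary_rows.append(
            {
                "component_id": cid,
                "size": len(members),
                "phylum_counts": ";".join(
                    f"{k}={v}" for k, v in sorted(phyla.items())
                ),
                "type_counts": ";".join(f"{k}={v}" for k, v in sorted(types.items())),
            }
        )
    labels = pd.DataFrame(label_rows, columns=["protein_id", "component_id"])
    summary = pd.DataFrame(
        summary_rows, columns=["component_id", "size", "phylum_counts", "type_counts"]
    )
    return labels, summary


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)


def write_sif(graph: nx.Graph, path, interaction: str = "sim") -> None:
    """Cytoscape SIF export; singleton nodes appear on their own line."""
    with open(path, "w") as fh:
        for u, v in sorted(map(lambda e: tuple(sorted(e)), graph.edges())):
            fh.write(f"{u}\t{interaction}\t{v}\n")
        for node in sorted(graph.nodes):
            if graph.degree[node] == 0:
                fh.write(f"{node}\n")
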