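"""Gene-neighbourhood extraction, centre-weighted similarity and clustering.

A neighbourhood is the slot-indexed (-10..-1, +1..+10) vector of neighbour
architectures around a focal MCE gene, orientation-normalized so negative
slots are upstream of the focal gene's reading direction.  Similarity
between two neighbourhoods down-weights outer slots with an exponential
decay w(i) = r^(|i|-1), and neighbourhoods are grouped by agglomerative
(nearest-neighbour joining) clustering until the best inter-cluster
similarity drops below a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .architecture import Architecture, architecture_string, merge_synonyms
from .io import GeneLocus

__all__ = [
    "Neighbourhood",
    "NeighbourhoodWeights",
    "NeighbourhoodClustering",
    "extract_neighbourhood",
    "neighbourhood_similarity",
    "cluster_neighbourhoods",
    "summarise_neighbourhoods",
]

WINDOW_BP_DEFAULT = 10_000
MAX_GENES_DEFAULT = 10
SLOT_RANGE = tuple(i for i in range(-10, 11) if i != 0)


@dataclass(frozen=True)
class Neighbourhood:
    """Slot index -> canonical architecture string; absent slots omitted."""

    focal_gene: str
    focal_type: str
    slots: Mapping[int, str]
    orientation_normalized: bool = True


@dataclass(frozen=True)
class NeighbourhoodWeights:
    """Exponential centre weighting w(i) = r^(|i|-1), r in (0, 1]."""

    r: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.r <= 1.0):
            raise ValueError(f"decay ratio r must be in (0, 1], got {self.r}")

    def weight(self, slot: int) -> float:
        return self.r ** (abs(slot) - 1)


@dataclass(frozen=True)
class NeighbourhoodClustering:
    labels: Mapping[str, int]  # focal_gene -> cluster id
    trace: tuple[tuple[str, str, float], ...]  # (rep_a, rep_b, similarity)
    tau: float


def _gene_distance(focal: GeneLocus, other: GeneLocus) -> int:
    """Gap in bp between nearest gene boundaries (0 when intervals touch/overlap)."""
    if other.end < focal.start:
        return focal.start - other.end
    if other.start > focal.end:
        return other.start - focal.end
    return 0


def extract_neighbourhood(
    loci: Sequence[GeneLocus],
    focal: GeneLocus,
    architectures: Mapping[str, Architecture],
    window_bp: int = WINDOW_BP_DEFAULT,
    max_genes: int = MAX_GENES_DEFAULT,
    synonym_map: Optional[Mapping[str, str]] = None,
) -> Neighbourhood:
    """Fill slots -max_genes..+max_genes around *focal* from the gene table.

    Genes on each side are taken in order of increasing boundary distance, up
    to *max_genes* per side, discarding genes whose nearest boundary lies
    more than *window_bp* from the focal gene's nearest boundary.  Side is
    decided by midpoint.  When the focal strand is '-', the sides are swapped
    so that negative slots are upstream in reading direction.  Neighbour
    genes without a classified architecture (or with no significant domain)
    get the matchable string ``NONE``.
    """
    synonym_map = synonym_map or {}
    if focal.gene_id not in {g.gene_id for g in loci}:
        raise ValueError(f"focal gene {focal.gene_id} not present in gene table")
    focal_arch = architectures.get(focal.protein_id) if focal.protein_id else None
    focal_type = focal_arch.type_label if focal_arch else "?"

    left: list[tuple[int, str, GeneLocus]] = []
    right: list[tuple[int, str, GeneLocus]] = []
    for g in loci:
        if g.gene_id == focal.gene_id:
            continue
        if g.genome_id != focal.genome_id or g.contig != focal.contig:
            continue
        dist = _gene_distance(focal, g)
        if dist > window_bp:
            continue
        entry = (dist, g.gene_id, g)
        if g.midpoint < focal.midpoint:
            left.append(entry)
        else:
            right.append(entry)
    left.sort()
    right.sort()

    def arch_label(g: GeneLocus) -> str:
        arch = architectures.get(g.protein_id) if g.protein_id else None
        label = architecture_string(arch) if arch else "NONE"
        return merge_synonyms(label, synonym_map)

    slots: dict[int, str] = {}
    for rank, (_, _, g) in enumerate(left[:max_genes], start=1):
        slots[-rank] = arch_label(g)
    for rank, (_, _, g) in enumerate(right[:max_genes], start=1):
        slots[+rank] = arch_label(g)
    if focal.strand == "-":
        slots = {-i: label for i, label in slots.items()}
    return Neighbourhood(
        focal_gene=focal.gene_id,
        focal_type=focal_type,
        slots=slots,
        orientation_normalized=True,
    )


def neighbourhood_similarity(
    a: Neighbourhood, b: Neighbourhood, weights: NeighbourhoodWeights
) -> float:
    """Weighted fraction of agreeing slots over slots occupied in either input.

    S(a, b) = sum_{i in D} w(i) * [a_i == b_i] / sum_{i in D} w(i) with D the
    slots occupied in a or b; a slot occupied in only one of the two counts
    as a mismatch.  Empty-vs-empty neighbourhoods score 0.
    """
    if not (a.orientation_normalized and b.orientation_normalized):
        raise ValueError("neighbourhoods must be orientation-normalized")
    occupied = set(a.slots) | set(b.slots)
    if not occupied:
        return 0.0
    total = 0.0
    agree = 0.0
    for i in occupied:
        w = weights.weight(i)
        total += w
        if i in a.slots and i in b.slots and a.slots[i] == b.slots[i]:
            agree += w
    return agree / total


def cluster_neighbourhoods(
    neighbourhoods: Sequence[Neighbourhood],
    weights: NeighbourhoodWeights,
    tau: float = 0.5,
    linkage: str = "single",
) -> NeighbourhoodClustering:
    """Agglomerate neighbourhoods until best inter-cluster similarity < tau.

    Repeatedly merges the pair of clusters with the highest linkage
    similarity (single by default; "complete" and "average" available),
    recording each merge.  Ties break on the lexicographically smallest
    (min id, max id) pair of cluster representatives.
    """
    if not (0.0 <= tau <= 1.0):
        raise ValueError(f"stop threshold tau must be in [0, 1], got {tau}")
    if linkage not in ("single", "complete", "average"):
        raise ValueError(f"unknown linkage {linkage!r}")
    if not neighbourhoods:
        raise ValueError("need at least one neighbourhood")

    ids = [n.focal_gene for n in neighbourhoods]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate focal gene ids")
    sim = {
        frozenset((x.focal_gene, y.focal_gene)): neighbourhood_similarity(
            x, y, weights
        )
        for idx, x in enumerate(neighbourhoods)
        for y in neighbourhoods[idx + 1 :]
    }
    clusters: dict[str, list[str]] = {i: [i] for i in sorted(ids)}

    def cluster_sim(a: str, b: str) -> float:
        values = [
            sim[frozenset((x, y))] for x in clusters[a] for y in clusters[b]
        ]
        if linkage == "single":
            return max(values)
        if linkage == "complete":
            return min(values)
        return sum(values) / len(values)

    trace: list[tuple[str, str, float]] = []
    while len(clusters) > 1:
        best: Optional[tuple[float, str, str]] = None
        reps = sorted(clusters)
        for ia, a in enumerate(reps):
            for b in reps[ia + 1 :]:
                s = cluster_sim(a, b)
                if best is None or s > best[0]:
                    best = (s, a, b)
        assert best is not None
        s, a, b = best
        if s < tau:
            break
        trace.append((a, b, s))
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
        clusters = {min(ms): ms for ms in clusters.values()}

    labels: dict[str, int] = {}
    for cid, rep in enumerate(sorted(clusters, key=lambda r: (-len(clusters[r]), r))):
        for member in clusters[rep]:
            labels[member] = cid
    return NeighbourhoodClustering(labels=labels, trace=tuple(trace), tau=tau)


def summarise_neighbourhoods(
    clustering: NeighbourhoodClustering,
    neighbourhoods: Sequence[Neighbourhood],
    focal_type: str,
) -> pd.DataFrame:
    """Per-cluster consensus pattern and percentage of all focal genes.

    The consensus takes, for each slot, the majority architecture among
    members occupying that slot (ties: lexicographically smallest).  The
    percentage divides cluster size by the total number of neighbourhoods of
    *focal_type*; including singletons, percentages sum to <= 100.
    """
    by_id = {n.focal_gene: n for n in neighbourhoods}
    total = sum(1 for n in neighbourhoods if n.focal_type == focal_type)
    members_by_cluster: dict[int, list[str]] = {}
    for gene, cid in clustering.labels.items():
        if by_id[gene].focal_type == focal_type:
            members_by_cluster.setdefault(cid, []).append(gene)

    rows = []
    for cid in sorted(members_by_cluster, key=lambda c: (-len(members_by_cluster[c]), c)):
        members = members_by_cluster[cid]
        occupied_slots = sorted({s for g in members for s in by_id[g].slots})
        consensus: dict[int, str] = {}
        for slot in occupied_slots:
            counts: dict[str, int] = {}
            for gene in members:
                label = by_id[gene].slots.get(slot)
                if label is not None:
                    counts[label] = counts.get(label, 0) + 1
            if counts:
                consensus[slot] = min(
                    counts, key=lambda k: (-counts[k], k)
                )
        rows.append(
            {
                "cluster_id": cid,
                "focal_type": focal_type,
                "size": len(members),
                "percentage": 100.0 * len(members) / total if total else 0.0,
                "consensus": "|".join(
                    f"{slot:+d}:{consensus[slot]}" for slot in sorted(consensus)
                ),
                "members": ";".join(sorted(members)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["cluster_id", "focal_type", "size", "percentage", "consensus", "members"],
    )
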