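"""Per-protein domain architectures and the four-type classification.

The pipeline here is: significance filtering against per-family bit-score
thresholds, resolution of overlapping same-clan predictions (keeping the
most significant, with MCE hits immune to removal), ordering by start
position, and classification into types I-IV / other_mce / non_mce.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .io import DomainHit

__all__ = [
    "ThresholdTable",
    "Architecture",
    "filter_significant",
    "resolve_clan_overlaps",
    "build_architecture",
    "classify_type",
    "merge_synonyms",
    "validate_synonym_map",
    "architectures_from_hits",
    "architecture_string",
]

MCE_FAMILY_DEFAULT = "MCE"
DUF3407_FAMILY_DEFAULT = "DUF3407"

TYPE_I = "I"
TYPE_II = "II"
TYPE_III = "III"
TYPE_IV = "IV"
TYPE_OTHER = "other_mce"
TYPE_NONE = "non_mce"

TYPE_LABELS = (TYPE_I, TYPE_II, TYPE_III, TYPE_IV, TYPE_OTHER, TYPE_NONE)


@dataclass(frozen=True)
class ThresholdTable:
    """Per-family minimum bit scores (gathering thresholds)."""

    thresholds: Mapping[str, float] = field(default_factory=dict)
    default_threshold: float = 25.0

    def min_for(self, domain_name: str) -> float:
        return self.thresholds.get(domain_name, self.default_threshold)


@dataclass(frozen=True)
class Architecture:
    """Ordered domain-name sequence of one protein plus its type label."""

    protein_id: str
    domains: tuple[str, ...]
    mce_count: int
    type_label: str


def filter_significant(
    hits: Iterable[DomainHit], thresholds: ThresholdTable
) -> list[DomainHit]:
    """Keep hits with bit score >= the gathering threshold of their family."""
    return [h for h in hits if h.bit_score >= thresholds.min_for(h.domain_name)]


def resolve_clan_overlaps(hits: Sequence[DomainHit]) -> list[DomainHit]:
    """Resolve overlapping same-clan predictions for a single protein.

    A non-MCE hit is removed iff it overlaps (by >= 1 residue) a retained
    same-clan hit of higher bit score; MCE hits are never removed.  This is
    the fixpoint of repeated pairwise "keep the most significant" resolution,
    computed by a single pass in descending bit-score order.  Ties break on
    smaller start, then lexicographic domain name.

    Raises ``ValueError`` when hits span more than one protein.
    """
    hits = list(hits)
    if not hits:
        return []
    protein_ids = {h.protein_id for h in hits}
    if len(protein_ids) > 1:
        raise ValueError(
            f"resolve_clan_overlaps expects hits from one protein, "
            f"got {sorted(protein_ids)}"
        )
    ranked = sorted(hits, key=lambda h: (-h.bit_score, h.start, h.domain_name))
    kept: list[DomainHit] = []
    for h in ranked:
        if h.is_mce:
            kept.append(h)
            continue
        shadowed = any(
            k.clan_id is not None
            and k.clan_id == h.clan_id
            and k.overlaps(h)
            for k in kept
            if k is not h
        )
        if not shadowed:
            kept.append(h)
    kept.sort(key=lambda h: (h.start, -h.bit_score, h.domain_name))
    return kept


def build_architecture(
    hits: Sequence[DomainHit],
    protein_id: str,
    mce_family: str = MCE_FAMILY_DEFAULT,
    duf3407_family: str = DUF3407_FAMILY_DEFAULT,
) -> Architecture:
    """Order resolved hits by start position and classify the result.

    Ties on start break by descending bit score, then name.  Zero hits give
    an empty architecture with type ``non_mce``.
    """
    ordered = sorted(hits, key=lambda h: (h.start, -h.bit_score, h.domain_name))
    domains = tuple(h.domain_name for h in ordered)
    mce_count = sum(1 for d in domains if d == mce_family)
    arch = Architecture(protein_id, domains, mce_count, TYPE_NONE)
    label = classify_type(arch, mce_family=mce_family, duf3407_family=duf3407_family)
    return Architecture(protein_id, domains, mce_count, label)


def classify_type(
    arch: Architecture,
    mce_family: str = MCE_FAMILY_DEFAULT,
    duf3407_family: str = DUF3407_FAMILY_DEFAULT,
) -> str:
    """Classify an ordered architecture into I / II / III / IV / other / none.

    I: exactly one MCE domain and nothing else.  II: one MCE followed by one
    DUF3407, nothing else.  III / IV: exactly three / seven MCE domains in
    tandem (consecutive, no intervening domain) and nothing else.  Any other
    architecture containing >= 1 MCE is ``other_mce``; zero MCE is
    ``non_mce``.
    """
    domains = arch.domains
    n_mce = sum(1 for d in domains if d == mce_family)
    if n_mce == 0:
        return TYPE_NONE
    if domains == (mce_family,):
        return TYPE_I
    if domains == (mce_family, duf3407_family):
        return TYPE_II
    if domains == (mce_family,) * 3:
        return TYPE_III
    if domains == (mce_family,) * 7:
        return TYPE_IV
    return TYPE_OTHER


def validate_synonym_map(synonym_map: Mapping[str, str]) -> Mapping[str, str]:
    """Reject maps whose values are themselves remapped (chains / cycles)."""
    for key, value in synonym_map.items():
        if value in synonym_map and synonym_map[value] != value:
            raise ValueError(
                f"synonym map is not idempotent: {key!r} -> {value!r} -> "
                f"{synonym_map[value]!r}"
            )
    return synonym_map


def merge_synonyms(arch_name: str, synonym_map: Mapping[str, str]) -> str:
    """Map an architecture string to its canonical form (idempotent)."""
    return synonym_map.get(arch_name, arch_name)


def architecture_string(arch: Architecture) -> str:
    """Comma-joined domain list; ``NONE`` for a domain-less architecture."""
    return ", ".join(arch.domains) if arch.domains else "NONE"


def architectures_from_hits(
    hits: Iterable[DomainHit],
    protein_ids: Optional[Iterable[str]] = None,
    thresholds: Optional[ThresholdTable] = None,
    mce_family: str = MCE_FAMILY_DEFAULT,
    duf3407_family: str = DUF3407_FAMILY_DEFAULT,
) -> dict[str, Architecture]:
    """Run filter -> overlap resolution -> ordering for every protein.

    *protein_ids*, when given, guarantees an (empty, ``non_mce``)
    architecture for proteins without any significant hit.
    """
    thresholds = thresholds or ThresholdTable()
    per_protein: dict[str, list[DomainHit]] = {}
    for h in filter_significant(hits, thresholds):
        per_protein.setdefault(h.protein_id, []).append(h)
    if protein_ids is not None:
        for pid in protein_ids:
            per_protein.setdefault(pid, [])
    result: dict[str, Architecture] = {}
    for pid, protein_hits in per_protein.items():
        resolved = resolve_clan_overlaps(protein_hits)
        result[pid] = build_architecture(
            resolved, pid, mce_family=mce_family, duf3407_family=duf3407_family
        )
    return result
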