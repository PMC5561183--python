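"""Phylum-level prevalence of architecture types.

One genome per species is chosen at random (seeded, unlike the original
manual selection), a species counts as positive for a type when its
representative genome encodes at least one protein of that type, and
percentages are aggregated per phylum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .architecture import Architecture, TYPE_I, TYPE_II, TYPE_III, TYPE_IV
from .io import ProteinRecord

__all__ = [
    "PrevalenceMatrix",
    "select_representative_genomes",
    "compute_prevalence",
    "flag_suspect_eukaryote_hits",
]

DEFAULT_TYPES = (TYPE_I, TYPE_II, TYPE_III, TYPE_IV)


@dataclass(frozen=True)
class PrevalenceMatrix:
    """Phylum x type percentage matrix with per-phylum species totals."""

    percentages: pd.DataFrame  # index: phylum; columns: type labels
    species_total: pd.Series  # index: phylum

    def to_frame(self) -> pd.DataFrame:
        out = self.percentages.copy()
        out.insert(0, "species_total", self.species_total)
        return out

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="phylum")


def select_representative_genomes(
    proteins: Iterable[ProteinRecord], seed: int
) -> dict[str, str]:
    """Pick one genome per species uniformly at random (deterministic per seed)."""
    genomes: dict[str, set[str]] = {}
    for p in proteins:
        genomes.setdefault(p.species_id, set()).add(p.genome_id)
    rng = np.random.default_rng(seed)
    mapping: dict[str, str] = {}
    for species in sorted(genomes):
        candidates = sorted(genomes[species])
        mapping[species] = candidates[rng.integers(len(candidates))]
    return mapping


def compute_prevalence(
    architectures: Mapping[str, Architecture],
    proteins: Sequence[ProteinRecord],
    representative_map: Mapping[str, str],
    types: Sequence[str] = DEFAULT_TYPES,
) -> PrevalenceMatrix:
    """Aggregate per-species type presence into phylum percentages.

    A species is positive for a type iff its representative genome encodes
    >= 1 protein of that type.  Species without MCE proteins still count in
    the denominator.  Raises ``KeyError`` if an architecture references a
    protein absent from the metadata table.
    """
    by_id = {p.protein_id: p for p in proteins}
    unknown = [pid for pid in architectures if pid not in by_id]
    if unknown:
        raise KeyError(
            f"architectures reference proteins with no metadata record: "
            f"{sorted(unknown)[:5]}{'...' if len(unknown) > 5 else ''}"
        )

    species_phylum: dict[str, str] = {}
    for p in proteins:
        species_phylum[p.species_id] = p.phylum

    positive: dict[str, set[str]] = {s: set() for s in species_phylum}
    for pid, arch in architectures.items():
        rec = by_id[pid]
        if representative_map.get(rec.species_id) != rec.genome_id:
            continue
        if arch.type_label in types:
            positive[rec.species_id].add(arch.type_label)

    phyla = sorted(set(species_phylum.values()))
    totals = pd.Series(
        {ph: sum(1 for s, p in species_phylum.items() if p == ph) for ph in phyla},
        name="species_total",
    )
    data = pd.DataFrame(0.0, index=phyla, columns=list(types))
    for species, phylum in species_phylum.items():
        for t in positive[species]:
            data.loc[phylum, t] += 1
    data = data.div(totals, axis=0) * 100.0
    return PrevalenceMatrix(percentages=data, species_total=totals)


def flag_suspect_eukaryote_hits(
    architectures: Mapping[str, Architecture],
    proteins: Sequence[ProteinRecord],
) -> pd.DataFrame:
    """List MCE-containing proteins whose record is non-bacterial.

    This automates the manual contamination screen up to flagging; nothing
    is removed automatically.
    """
    by_id = {p.protein_id: p for p in proteins}
    rows = []
    for pid in sorted(architectures):
        arch = architectures[pid]
        if arch.mce_count == 0:
            continue
        rec = by_id.get(pid)
        if rec is None or rec.superkingdom.lower() == "bacteria":
            continue
        rows.append(
            {
                "protein_id": pid,
                "superkingdom": rec.superkingdom,
                "phylum": rec.phylum,
                "species_id": rec.species_id,
                "type_label": arch.type_label,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["protein_id", "superkingdom", "phylum", "species_id", "type_label"],
    )
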