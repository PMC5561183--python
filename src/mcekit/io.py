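"""Readers and writers for the tabular formats the pipeline consumes.

Three external dialects are supported, closely enough that files produced by
the real tools also parse:

* HMMER per-domain tabular output (``hmmsearch --domtblout``).  Envelope
  coordinates, the domain independent e-value and the domain bit score are
  used.  A Pfam clan id, which real domtblout lacks, may be carried as a
  ``clan=CLxxxx`` token inside the free-text description column.
* GFF3 gene annotation (selected feature types only).
* BLAST tabular, ``-outfmt 6`` (12 columns).

All coordinates are 1-based inclusive, for both residues and base pairs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

PathLike = Union[str, Path]

__all__ = [
    "ParseError",
    "DomainHit",
    "ProteinRecord",
    "GeneLocus",
    "AlignmentEdge",
    "read_domain_hits",
    "write_domain_hits",
    "read_gff",
    "write_gff",
    "read_alignments",
    "write_alignments",
    "read_proteins",
    "write_proteins",
]


class ParseError(ValueError):
    """A malformed line in an input file; the message names the line number."""


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DomainHit:
    """One significance-scored domain match on one protein."""

    protein_id: str
    domain_name: str
    clan_id: Optional[str]
    start: int  # 1-based inclusive envelope start (residues)
    end: int  # 1-based inclusive envelope end
    bit_score: float
    e_value: float
    is_mce: bool = False

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid coordinates {self.start}..{self.end} for "
                f"{self.protein_id}/{self.domain_name}: need 1 <= start <= end"
            )
        if self.e_value < 0:
            raise ValueError(f"negative e-value {self.e_value}")

    def overlaps(self, other: "DomainHit") -> bool:
        """True if the two closed residue intervals share >= 1 residue."""
        return self.start <= other.end and other.start <= self.end


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    genome_id: str
    species_id: str
    phylum: str
    superkingdom: str
    length: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"protein {self.protein_id}: length must be > 0")


@dataclass(frozen=True)
class GeneLocus:
    gene_id: str
    genome_id: str
    contig: str
    start: int  # 1-based inclusive bp
    end: int
    strand: str  # '+' or '-'
    protein_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass(frozen=True)
class AlignmentEdge:
    query_id: str
    subject_id: str
    pct_identity: float
    e_value: float
    bit_score: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.pct_identity <= 100.0):
            raise ValueError(f"pct_identity {self.pct_identity} outside [0, 100]")
        if self.e_value < 0:
            raise ValueError(f"negative e-value {self.e_value}")


# ---------------------------------------------------------------------------
# HMMER domtblout dialect
# ---------------------------------------------------------------------------

# Column indices in hmmsearch --domtblout (0-based, whitespace-split with the
# description absorbing everything after column 22):
_DT_TARGET = 0
_DT_QUERY_NAME = 3
_DT_I_EVALUE = 12
_DT_DOM_SCORE = 13
_DT_ENV_FROM = 19
_DT_ENV_TO = 20
_DT_MIN_FIELDS = 22  # before the optional description


def _parse_clan(description: str) -> Optional[str]:
    for token in description.split():
        if token.startswith("clan="):
            value = token[len("clan="):]
            if value and value != "-":
                return value
    return None


def read_domain_hits(path: PathLike, mce_family: str = "MCE") -> list[DomainHit]:
    """Parse a per-domain tabular file into :class:`DomainHit` records.

    Lines starting with ``#`` are comments.  ``is_mce`` is set by exact
    match of the domain name against *mce_family*.
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split(None, _DT_MIN_FIELDS)
            if len(parts) < _DT_MIN_FIELDS:
                raise ParseError(
                    f"{path}: line {lineno}: expected >= {_DT_MIN_FIELDS} "
                    f"whitespace-delimited fields, got {len(parts)}"
                )
            description = parts[_DT_MIN_FIELDS] if len(parts) > _DT_MIN_FIELDS else ""
            try:
                start = int(parts[_DT_ENV_FROM])
                end = int(parts[_DT_ENV_TO])
                e_value = float(parts[_DT_I_EVALUE])
                bit_score = float(parts[_DT_DOM_SCORE])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            domain_name = parts[_DT_QUERY_NAME]
            try:
                hit = DomainHit(
                    protein_id=parts[_DT_TARGET],
                    domain_name=domain_name,
                    clan_id=_parse_clan(description),
                    start=start,
                    end=end,
                    bit_score=bit_score,
                    e_value=e_value,
                    is_mce=(domain_name == mce_family),
                )
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            hits.append(hit)
    return hits


def write_domain_hits(hits: Iterable[DomainHit], path: PathLike) -> None:
    """Write hits in the domtblout dialect (clan id in the description)."""
    header = (
        "#                                                               "
        "--- full sequence --- -------------- this domain --------------\n"
        "# target name        accession   tlen query name           "
        "accession   qlen   E-value  score  bias   #  of  c-Evalue  "
        "i-Evalue  score  bias  from    to  from    to  from    to  acc "
        "description of target\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for h in hits:
            desc = f"clan={h.clan_id}" if h.clan_id else "-"
            length = h.end + 10  # placeholder target length
            fh.write(
                f"{h.protein_id} - {length} {h.domain_name} - {h.end - h.start + 1} "
                f"{h.e_value:.17g} {h.bit_score:.17g} 0.0 1 1 "
                f"{h.e_value:.17g} {h.e_value:.17g} {h.bit_score:.17g} 0.0 "
                f"1 {h.end - h.start + 1} {h.start} {h.end} {h.start} {h.end} "
                f"0.99 {desc}\n"
            )


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def _parse_gff_attributes(field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in field.split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" in item:
            key, value = item.split("=", 1)
            attrs[key.strip()] = value.strip()
    return attrs


def read_gff(
    path: PathLike,
    feature_types: Sequence[str] = ("gene",),
    protein_id_attr: str = "protein_id",
    genome_id_attr: str = "genome_id",
    default_genome_id: Optional[str] = None,
) -> list[GeneLocus]:
    """Parse GFF3, keeping only rows of the configured feature types.

    The protein id is read from *protein_id_attr* in column 9; the genome id
    from *genome_id_attr*, falling back to *default_genome_id* and finally
    the file stem.  Output is sorted by (genome_id, contig, start).
    """
    fallback_genome = default_genome_id or Path(path).stem
    wanted = set(feature_types)
    loci: list[GeneLocus] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise ParseError(
                    f"{path}: line {lineno}: GFF3 needs 9 tab-separated "
                    f"columns, got {len(cols)}"
                )
            if cols[2] not in wanted:
                continue
            strand = cols[6]
            if strand not in ("+", "-"):
                raise ParseError(
                    f"{path}: line {lineno}: strand required for "
                    f"neighbourhood orientation (got {strand!r})"
                )
            attrs = _parse_gff_attributes(cols[8])
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            try:
                locus = GeneLocus(
                    gene_id=attrs.get("ID", f"{cols[0]}:{start}-{end}"),
                    genome_id=attrs.get(genome_id_attr, fallback_genome),
                    contig=cols[0],
                    start=start,
                    end=end,
                    strand=strand,
                    protein_id=attrs.get(protein_id_attr),
                )
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            loci.append(locus)
    loci.sort(key=lambda g: (g.genome_id, g.contig, g.start, g.gene_id))
    return loci


def write_gff(
    loci: Iterable[GeneLocus],
    path: PathLike,
    feature_type: str = "gene",
    source: str = "mcekit",
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in loci:
            attrs = [f"ID={g.gene_id}", f"genome_id={g.genome_id}"]
            if g.protein_id is not None:
                attrs.append(f"protein_id={g.protein_id}")
            fh.write(
                f"{g.contig}\t{source}\t{feature_type}\t{g.start}\t{g.end}"
                f"\t.\t{g.strand}\t.\t{';'.join(attrs)}\n"
            )


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6)
# ---------------------------------------------------------------------------


def read_alignments(path: PathLike, drop_self: bool = True) -> list[AlignmentEdge]:
    """Parse 12-column BLAST tabular output.

    Self-hits are removed when *drop_self*.  Duplicate (query, subject)
    pairs collapse to the lowest e-value (ties: highest bit score).
    """
    best: dict[tuple[str, str], AlignmentEdge] = {}
    order: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ParseError(
                    f"{path}: line {lineno}: expected 12 tab-separated "
                    f"columns, got {len(cols)}"
                )
            try:
                edge = AlignmentEdge(
                    query_id=cols[0],
                    subject_id=cols[1],
                    pct_identity=float(cols[2]),
                    e_value=float(cols[10]),
                    bit_score=float(cols[11]),
                )
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            if drop_self and edge.query_id == edge.subject_id:
                continue
            key = (edge.query_id, edge.subject_id)
            kept = best.get(key)
            if kept is None:
                best[key] = edge
                order.append(key)
            elif (edge.e_value, -edge.bit_score) < (kept.e_value, -kept.bit_score):
                best[key] = edge
    return [best[k] for k in order]


def write_alignments(edges: Iterable[AlignmentEdge], path: PathLike) -> None:
    """Write edges as 12-column BLAST tabular (placeholder mid-columns)."""
    with open(path, "w") as fh:
        for e in edges:
            fh.write(
                f"{e.query_id}\t{e.subject_id}\t{e.pct_identity:.17g}"
                f"\t100\t0\t0\t1\t100\t1\t100"
                f"\t{e.e_value:.17g}\t{e.bit_score:.17g}\n"
            )


# ---------------------------------------------------------------------------
# protein metadata TSV
# ---------------------------------------------------------------------------

_PROTEIN_COLUMNS = (
    "protein_id",
    "genome_id",
    "species_id",
    "phylum",
    "superkingdom",
    "length",
)


def read_proteins(path: PathLike) -> list[ProteinRecord]:
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(_PROTEIN_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ParseError(f"{path}: missing columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                rec = ProteinRecord(
                    protein_id=row["protein_id"],
                    genome_id=row["genome_id"],
                    species_id=row["species_id"],
                    phylum=row["phylum"],
                    superkingdom=row["superkingdom"],
                    length=int(row["length"]),
                )
            except (ValueError, TypeError) as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            if rec.protein_id in seen:
                raise ParseError(
                    f"{path}: line {lineno}: duplicate protein_id {rec.protein_id}"
                )
            seen.add(rec.protein_id)
            records.append(rec)
    return records


def write_proteins(records: Iterable[ProteinRecord], path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_PROTEIN_COLUMNS)
        for r in records:
            writer.writerow(
                [r.protein_id, r.genome_id, r.species_id, r.phylum,
                 r.superkingdom, r.length]
            )
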