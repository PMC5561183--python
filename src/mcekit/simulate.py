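"""Synthetic dataset generator with planted ground truth.

Emits the four input tables the pipeline consumes — domain hits
(domtblout dialect), protein metadata, GFF3 gene tables and BLAST-tabular
alignments — for an invented taxonomy in which every quantity of interest
is planted and recorded:

* per-species presence of architecture types I-IV (identical across all
  genomes of a species, so representative choice cannot change prevalence);
* per-protein architectures, with optional sub-threshold decoy hits and
  planted same-clan overlap conflicts on dedicated proteins;
* protein families whose within-family alignment e-values sit strictly
  below the network threshold and between-family e-values strictly above;
* operonic gene contexts around type I / III / IV genes, mirroring the
  mla / pqi / yeb operon layouts, at randomized intergenic spacings.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import io as mio
from .architecture import TYPE_I, TYPE_II, TYPE_III, TYPE_IV, TYPE_NONE
from .io import AlignmentEdge, DomainHit, GeneLocus, ProteinRecord

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedDataset",
    "simulate_dataset",
    "ecoli_fixture",
]

MCE = "MCE"
DUF3407 = "DUF3407"

TYPE_ARCHS: dict[str, tuple[str, ...]] = {
    TYPE_I: (MCE,),
    TYPE_II: (MCE, DUF3407),
    TYPE_III: (MCE,) * 3,
    TYPE_IV: (MCE,) * 7,
}

# Operon-style planted contexts (slot -> architecture string).
DEFAULT_CONTEXT_TEMPLATES: dict[str, dict[int, str]] = {
    TYPE_I: {-2: "ABC_tran", -1: "MlaE", +1: "DUF330"},
    TYPE_III: {-2: "PqiA", -1: "PqiA", +1: "DUF330"},
    TYPE_IV: {-1: "PqiA"},
}

# Fictional sub-threshold noise families, disjoint from every planted name.
DECOY_VOCAB = ("ZetaBox", "QuuxDom", "GremlinD", "WobbleC", "FizzDom")

CONFLICT_CLAN = "CL9001"
CONFLICT_NAMES = ("ConfA", "ConfB")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_phyla: int = 4
    species_per_phylum: int = 5
    genomes_per_species: int = 1
    # phylum -> {type: probability}; phyla absent here use default_type_probs
    type_profile: Optional[Mapping[str, Mapping[str, float]]] = None
    default_type_probs: Mapping[str, float] = field(
        default_factory=lambda: {TYPE_I: 0.7, TYPE_II: 0.3, TYPE_III: 0.5, TYPE_IV: 0.25}
    )
    decoy_hit_rate: float = 0.0
    overlap_conflict_rate: float = 0.0
    family_size: int = 20
    within_family_evalue_band: tuple[float, float] = (1e-40, 1e-18)
    between_family_evalue_band: tuple[float, float] = (1e-8, 1e-2)
    within_identity_band: tuple[float, float] = (60.0, 95.0)
    between_identity_band: tuple[float, float] = (5.0, 30.0)
    between_pair_fraction: float = 0.02
    spacing_bp: tuple[int, int] = (50, 500)
    far_gene_fraction: float = 0.0
    gathering_threshold: float = 25.0
    context_templates: Mapping[str, Mapping[int, str]] = field(
        default_factory=lambda: DEFAULT_CONTEXT_TEMPLATES
    )

    def validate(self) -> None:
        if self.within_family_evalue_band[1] > 1e-15:
            raise ValueError(
                "within-family e-value ceiling must be <= 1e-15, got "
                f"{self.within_family_evalue_band[1]}"
            )
        if self.between_family_evalue_band[0] <= 1e-15:
            raise ValueError(
                "between-family e-value floor must be > 1e-15, got "
                f"{self.between_family_evalue_band[0]}"
            )
        for band in (self.within_family_evalue_band, self.between_family_evalue_band):
            if band[0] > band[1]:
                raise ValueError(f"e-value band {band} has floor > ceiling")
        for probs in [self.default_type_probs, *(self.type_profile or {}).values()]:
            for t, p in probs.items():
                if not (0.0 <= p <= 1.0):
                    raise ValueError(f"planting probability for {t} outside [0,1]: {p}")
        if not (0.0 <= self.decoy_hit_rate):
            raise ValueError("decoy_hit_rate must be >= 0")
        if not (0.0 <= self.overlap_conflict_rate <= 1.0):
            raise ValueError("overlap_conflict_rate must be in [0, 1]")


@dataclass
class GroundTruth:
    """Planted truth, self-consistent with every emitted table."""

    protein_truth: pd.DataFrame  # protein_id, architecture, type_label, family_id
    species_presence: pd.DataFrame  # species_id, phylum, I..IV booleans
    context_truth: pd.DataFrame  # gene_id, protein_id, focal_type, template
    conflict_truth: pd.DataFrame  # protein_id, survivor

    def write(self, out_dir: Path) -> None:
        out_dir.mkdir(parents=True, exist_ok=True)
        self.protein_truth.to_csv(out_dir / "protein_truth.tsv", sep="\t", index=False)
        self.species_presence.to_csv(
            out_dir / "species_presence.tsv", sep="\t", index=False
        )
        self.context_truth.to_csv(out_dir / "context_truth.tsv", sep="\t", index=False)
        self.conflict_truth.to_csv(
            out_dir / "conflict_truth.tsv", sep="\t", index=False
        )


@dataclass
class SimulatedDataset:
    config: Optional[SimulationConfig]
    hits: list[DomainHit]
    proteins: list[ProteinRecord]
    loci: list[GeneLocus]
    alignments: list[AlignmentEdge]
    truth: GroundTruth

    def write(self, out_dir) -> dict[str, str]:
        """Write the full bundle (tables, ground truth, manifest) to a directory."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "hits": out / "hits.domtbl",
            "proteins": out / "proteins.tsv",
            "genes": out / "genes.gff3",
            "alignments": out / "alignments.tsv",
        }
        mio.write_domain_hits(self.hits, paths["hits"])
        mio.write_proteins(self.proteins, paths["proteins"])
        mio.write_gff(self.loci, paths["genes"])
        mio.write_alignments(self.alignments, paths["alignments"])
        self.truth.write(out / "ground_truth")
        digests = {
            name: hashlib.sha256(p.read_bytes()).hexdigest()
            for name, p in paths.items()
        }
        manifest = {
            "seed": self.config.seed if self.config else None,
            "config": _config_echo(self.config) if self.config else None,
            "row_counts": {
                "hits": len(self.hits),
                "proteins": len(self.proteins),
                "genes": len(self.loci),
                "alignments": len(self.alignments),
            },
            "sha256": digests,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return {k: str(v) for k, v in paths.items()}


def _config_echo(config: SimulationConfig) -> dict:
    echo = asdict(config)
    echo["context_templates"] = {
        t: {str(k): v for k, v in tmpl.items()}
        for t, tmpl in config.context_templates.items()
    }
    return echo


def _log_uniform(rng: np.random.Generator, low: float, high: float) -> float:
    return float(10 ** rng.uniform(np.log10(low), np.log10(high)))


def _arch_hits(
    protein_id: str,
    domains: Sequence[str],
    rng: np.random.Generator,
    threshold: float,
    mce_family: str = MCE,
) -> list[DomainHit]:
    """Above-threshold, non-overlapping hits realizing a planted architecture."""
    hits = []
    pos = 10
    for name in domains:
        length = int(rng.integers(70, 120))
        hits.append(
            DomainHit(
                protein_id=protein_id,
                domain_name=name,
                clan_id=None,
                start=pos,
                end=pos + length,
                bit_score=float(np.round(rng.uniform(threshold + 10, threshold + 80), 1)),
                e_value=_log_uniform(rng, 1e-30, 1e-6),
                is_mce=(name == mce_family),
            )
        )
        pos += length + int(rng.integers(5, 40))
    return hits


def simulate_dataset(
    config: SimulationConfig, out_dir=None
) -> SimulatedDataset:
    """Generate a full synthetic bundle; optionally write it to *out_dir*."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    threshold = config.gathering_threshold
    templates = {t: dict(v) for t, v in config.context_templates.items()}

    hits: list[DomainHit] = []
    proteins: list[ProteinRecord] = []
    loci: list[GeneLocus] = []
    protein_truth_rows: list[dict] = []
    presence_rows: list[dict] = []
    context_rows: list[dict] = []
    conflict_rows: list[dict] = []
    mce_protein_ids: list[str] = []

    def add_protein(pid, genome, species, phylum, length, kingdom="Bacteria"):
        proteins.append(
            ProteinRecord(
                protein_id=pid,
                genome_id=genome,
                species_id=species,
                phylum=phylum,
                superkingdom=kingdom,
                length=int(length),
            )
        )

    def add_truth(pid, domains, type_label, family=""):
        protein_truth_rows.append(
            {
                "protein_id": pid,
                "architecture": ", ".join(domains) if domains else "NONE",
                "type_label": type_label,
                "family_id": family,
            }
        )

    for pi in range(config.n_phyla):
        phylum = f"Phylum{pi:02d}"
        probs = dict(config.default_type_probs)
        if config.type_profile and phylum in config.type_profile:
            probs.update(config.type_profile[phylum])
        for si in range(config.species_per_phylum):
            species = f"{phylum}_sp{si:02d}"
            presence = {
                t: bool(rng.random() < probs.get(t, 0.0))
                for t in (TYPE_I, TYPE_II, TYPE_III, TYPE_IV)
            }
            presence_rows.append({"species_id": species, "phylum": phylum, **presence})
            for gi in range(config.genomes_per_species):
                genome = f"{species}_g{gi:02d}"
                hk = f"{genome}|hk"
                add_protein(hk, genome, species, phylum, rng.integers(200, 500))
                add_truth(hk, (), TYPE_NONE)
                for t in (TYPE_I, TYPE_II, TYPE_III, TYPE_IV):
                    if not presence[t]:
                        continue
                    focal_pid = f"{genome}|{t}"
                    domains = TYPE_ARCHS[t]
                    focal_hits = _arch_hits(focal_pid, domains, rng, threshold)
                    hits.extend(focal_hits)
                    add_protein(
                        focal_pid, genome, species, phylum,
                        focal_hits[-1].end + int(rng.integers(10, 60)),
                    )
                    add_truth(focal_pid, domains, t)
                    mce_protein_ids.append(focal_pid)
                    _plant_operon(
                        config, rng, genome, species, phylum, t, focal_pid,
                        templates.get(t, {}), hits, proteins, loci,
                        protein_truth_rows, context_rows, threshold,
                    )

    # sub-threshold decoy hits never change an architecture
    if config.decoy_hit_rate > 0:
        for rec in list(proteins):
            for _ in range(rng.poisson(config.decoy_hit_rate)):
                name = DECOY_VOCAB[int(rng.integers(len(DECOY_VOCAB)))]
                start = int(rng.integers(1, max(2, rec.length - 30)))
                hits.append(
                    DomainHit(
                        protein_id=rec.protein_id,
                        domain_name=name,
                        clan_id=None,
                        start=start,
                        end=start + int(rng.integers(20, 60)),
                        bit_score=float(np.round(rng.uniform(2.0, threshold - 1.0), 1)),
                        e_value=_log_uniform(rng, 1e-4, 10.0),
                        is_mce=False,
                    )
                )

    # planted same-clan overlap conflicts on dedicated non-MCE proteins
    n_conflicts = int(round(config.overlap_conflict_rate * len(mce_protein_ids)))
    genome_cycle = sorted({p.genome_id for p in proteins})
    for ci in range(n_conflicts):
        genome = genome_cycle[ci % len(genome_cycle)]
        rec = next(p for p in proteins if p.genome_id == genome)
        pid = f"{genome}|conflict{ci:04d}"
        bits = rng.uniform(threshold + 5, threshold + 60, size=2)
        while abs(bits[0] - bits[1]) < 0.5:  # distinct scores keep resolution unique
            bits = rng.uniform(threshold + 5, threshold + 60, size=2)
        pair = []
        for j, name in enumerate(CONFLICT_NAMES):
            pair.append(
                DomainHit(
                    protein_id=pid,
                    domain_name=name,
                    clan_id=CONFLICT_CLAN,
                    start=10 + j * 50,
                    end=110 + j * 50,
                    bit_score=float(np.round(bits[j], 2)),
                    e_value=_log_uniform(rng, 1e-20, 1e-8),
                    is_mce=False,
                )
            )
        survivor = max(pair, key=lambda h: h.bit_score)
        hits.extend(pair)
        add_protein(pid, genome, rec.species_id, rec.phylum, 300)
        add_truth(pid, (survivor.domain_name,), TYPE_NONE)
        conflict_rows.append({"protein_id": pid, "survivor": survivor.domain_name})

    # planted families and the alignment table
    alignments = _plant_alignments(config, rng, sorted(mce_protein_ids), protein_truth_rows)

    truth = GroundTruth(
        protein_truth=pd.DataFrame(
            protein_truth_rows,
            columns=["protein_id", "architecture", "type_label", "family_id"],
        ),
        species_presence=pd.DataFrame(
            presence_rows,
            columns=["species_id", "phylum", TYPE_I, TYPE_II, TYPE_III, TYPE_IV],
        ),
        context_truth=pd.DataFrame(
            context_rows, columns=["gene_id", "protein_id", "focal_type", "template"]
        ),
        conflict_truth=pd.DataFrame(conflict_rows, columns=["protein_id", "survivor"]),
    )
    loci.sort(key=lambda g: (g.genome_id, g.contig, g.start, g.gene_id))
    dataset = SimulatedDataset(
        config=config,
        hits=hits,
        proteins=proteins,
        loci=loci,
        alignments=alignments,
        truth=truth,
    )
    if out_dir is not None:
        dataset.write(out_dir)
    return dataset


def _plant_operon(
    config, rng, genome, species, phylum, type_label, focal_pid, template,
    hits, proteins, loci, protein_truth_rows, context_rows, threshold,
):
    """Lay the focal gene and its planted context on a dedicated contig."""
    contig = f"{genome}|ctg_{type_label}"
    lo, hi = config.spacing_bp
    entries = []  # (slot, arch_string) in contig order assuming '+' focal
    for slot in sorted(template):
        entries.append((slot, template[slot]))
    # build '+'-orientation layout: negative slots left of focal
    genes: list[tuple[str, Optional[str], int, int, Optional[str]]] = []
    pos = 1000
    upstream = [e for e in entries if e[0] < 0]
    downstream = [e for e in entries if e[0] > 0]
    ordered = upstream + [(0, None)] + downstream
    for slot, arch in ordered:
        if slot == 0:
            length = 300 * len(TYPE_ARCHS[type_label]) + 300
            gene_id = f"{focal_pid}|gene"
            genes.append((gene_id, focal_pid, pos, pos + length - 1, None))
        else:
            length = int(rng.integers(600, 1200))
            pid = f"{focal_pid}|nbr{slot:+d}"
            gene_id = f"{pid}|gene"
            genes.append((gene_id, pid, pos, pos + length - 1, arch))
        pos += length + int(rng.integers(lo, hi + 1))
    if config.far_gene_fraction > 0 and rng.random() < config.far_gene_fraction:
        pid = f"{focal_pid}|far"
        start = pos + 10_000 + int(rng.integers(500, 2000))
        genes.append((f"{pid}|gene", pid, start, start + 800, "FarBox"))

    strand = "+" if rng.random() < 0.5 else "-"
    if strand == "-":
        span = max(g[3] for g in genes) + 500
        genes = [
            (gid, pid, span - end + 1, span - start + 1, arch)
            for gid, pid, start, end, arch in genes
        ]

    focal_gene_id = f"{focal_pid}|gene"
    for gid, pid, start, end, arch in genes:
        loci.append(
            GeneLocus(
                gene_id=gid, genome_id=genome, contig=contig,
                start=start, end=end, strand=strand, protein_id=pid,
            )
        )
        if pid == focal_pid:
            continue
        domains = tuple(arch.split(", ")) if arch else ()
        proteins.append(
            ProteinRecord(
                protein_id=pid, genome_id=genome, species_id=species,
                phylum=phylum, superkingdom="Bacteria",
                length=max(100, (end - start + 1) // 3),
            )
        )
        hits.extend(_arch_hits(pid, domains, rng, threshold))
        protein_truth_rows.append(
            {
                "protein_id": pid,
                "architecture": ", ".join(domains) if domains else "NONE",
                "type_label": TYPE_NONE,
                "family_id": "",
            }
        )
    if type_label in (TYPE_I, TYPE_III, TYPE_IV):
        context_rows.append(
            {
                "gene_id": focal_gene_id,
                "protein_id": focal_pid,
                "focal_type": type_label,
                "template": "|".join(
                    f"{s:+d}:{a}" for s, a in sorted(template.items())
                ),
            }
        )


def _plant_alignments(config, rng, mce_ids, protein_truth_rows):
    """All within-family pairs below threshold, sampled between-family pairs above."""
    families: dict[str, int] = {}
    for idx, pid in enumerate(mce_ids):
        families[pid] = idx // config.family_size
    fam_of = dict(families)
    for row in protein_truth_rows:
        if row["protein_id"] in fam_of:
            row["family_id"] = f"fam{fam_of[row['protein_id']]:03d}"

    edges: list[AlignmentEdge] = []
    w_lo, w_hi = config.within_family_evalue_band
    b_lo, b_hi = config.between_family_evalue_band
    wi_lo, wi_hi = config.within_identity_band
    bi_lo, bi_hi = config.between_identity_band
    n = len(mce_ids)
    between_pairs: list[tuple[int, int]] = []
    for i in range(n):
        for j in range(i + 1, n):
            if fam_of[mce_ids[i]] == fam_of[mce_ids[j]]:
                edges.append(
                    AlignmentEdge(
                        query_id=mce_ids[i],
                        subject_id=mce_ids[j],
                        pct_identity=float(np.round(rng.uniform(wi_lo, wi_hi), 1)),
                        e_value=_log_uniform(rng, w_lo, w_hi),
                        bit_score=float(np.round(rng.uniform(200, 600), 1)),
                    )
                )
            else:
                between_pairs.append((i, j))
    if between_pairs and config.between_pair_fraction > 0:
        k = min(len(between_pairs), max(1, int(config.between_pair_fraction * len(between_pairs))))
        chosen = rng.choice(len(between_pairs), size=k, replace=False)
        for idx in sorted(chosen):
            i, j = between_pairs[idx]
            edges.append(
                AlignmentEdge(
                    query_id=mce_ids[i],
                    subject_id=mce_ids[j],
                    pct_identity=float(np.round(rng.uniform(bi_lo, bi_hi), 1)),
                    e_value=_log_uniform(rng, b_lo, b_hi),
                    bit_score=float(np.round(rng.uniform(20, 45), 1)),
                )
            )
    return edges


# ---------------------------------------------------------------------------
# worked example: a miniature E. coli-like genome
# ---------------------------------------------------------------------------


def ecoli_fixture(out_dir=None) -> SimulatedDataset:
    """Hand-written miniature genome with the mla / pqi / yeb operon layouts.

    Three focal proteins: a single-MCE MlaD-like (type I), a 3-MCE PqiB-like
    (type III, pqiA upstream and a DUF330 gene downstream) and a 7-MCE
    YebT-like (type IV, pqiA-like gene upstream, no DUF330).
    """
    genome, species, phylum = "ECOLI_g1", "Escherichia_coli", "Proteobacteria"
    hits: list[DomainHit] = []
    proteins: list[ProteinRecord] = []
    loci: list[GeneLocus] = []
    truth_rows: list[dict] = []

    def protein(pid, domains, length=350):
        proteins.append(
            ProteinRecord(pid, genome, species, phylum, "Bacteria", length)
        )
        pos = 10
        for name in domains:
            hits.append(
                DomainHit(
                    protein_id=pid, domain_name=name, clan_id=None,
                    start=pos, end=pos + 80, bit_score=60.0, e_value=1e-20,
                    is_mce=(name == MCE),
                )
            )
            pos += 100
        truth_rows.append(
            {
                "protein_id": pid,
                "architecture": ", ".join(domains) if domains else "NONE",
                "type_label": "",
                "family_id": "",
            }
        )

    def gene(contig, gid, pid, start, end, strand="+"):
        loci.append(GeneLocus(gid, genome, contig, start, end, strand, pid))

    # mlaFEDCB operon: mlaF (ATPase) - mlaE (permease) - mlaD (MCE) - mlaC - mlaB
    protein("mlaF", ("ABC_tran",))
    protein("mlaE", ("MlaE",))
    protein("mlaD", (MCE,))
    protein("mlaC", ())
    protein("mlaB", ("STAS",))
    gene("chr", "mlaF_g", "mlaF", 1000, 1800)
    gene("chr", "mlaE_g", "mlaE", 1900, 2700)
    gene("chr", "mlaD_g", "mlaD", 2800, 3400)
    gene("chr", "mlaC_g", "mlaC", 3500, 4100)
    gene("chr", "mlaB_g", "mlaB", 4200, 4500)

    # pqiA - pqiB - ymbA operon (ymbA carries DUF330)
    protein("pqiA", ("PqiA",))
    protein("pqiB", (MCE,) * 3, length=550)
    protein("ymbA", ("DUF330",))
    gene("chr", "pqiA_g", "pqiA", 100000, 101200)
    gene("chr", "pqiB_g", "pqiB", 101300, 103000)
    gene("chr", "ymbA_g", "ymbA", 103100, 103700)

    # yebS - yebT operon (no DUF330 gene)
    protein("yebS", ("PqiA",))
    protein("yebT", (MCE,) * 7, length=880)
    gene("chr", "yebS_g", "yebS", 200000, 201300)
    gene("chr", "yebT_g", "yebT", 201400, 204100)

    truth = GroundTruth(
        protein_truth=pd.DataFrame(
            truth_rows, columns=["protein_id", "architecture", "type_label", "family_id"]
        ),
        species_presence=pd.DataFrame(
            [{"species_id": species, "phylum": phylum,
              TYPE_I: True, TYPE_II: False, TYPE_III: True, TYPE_IV: True}],
            columns=["species_id", "phylum", TYPE_I, TYPE_II, TYPE_III, TYPE_IV],
        ),
        context_truth=pd.DataFrame(
            [
                {"gene_id": "mlaD_g", "protein_id": "mlaD", "focal_type": TYPE_I,
                 "template": "-2:ABC_tran|-1:MlaE|+1:NONE|+2:STAS"},
                {"gene_id": "pqiB_g", "protein_id": "pqiB", "focal_type": TYPE_III,
                 "template": "-1:PqiA|+1:DUF330"},
                {"gene_id": "yebT_g", "protein_id": "yebT", "focal_type": TYPE_IV,
                 "template": "-1:PqiA"},
            ],
            columns=["gene_id", "protein_id", "focal_type", "template"],
        ),
        conflict_truth=pd.DataFrame(columns=["protein_id", "survivor"]),
    )
    dataset = SimulatedDataset(
        config=None, hits=hits, proteins=proteins, loci=loci,
        alignments=[], truth=truth,
    )
    if out_dir is not None:
        dataset.write(out_dir)
    return dataset
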