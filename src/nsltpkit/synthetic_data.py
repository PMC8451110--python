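"""Synthetic nsLTP cohorts with full ground truth.

The generator emits everything the pipeline consumes — candidate
proteins, a genome with gene models, promoters with planted cis-elements
and expression tables with known fold changes — together with a
:class:`TruthManifest` recording every planted feature, so each stage
can be tested for exact recovery without any external download.

The default cohort mirrors the published barley catalog's structure:
16/5/11/8 genes of types 1/2/D/G distributed over seven chromosomes
(maximum 11 genes on chromosome 2, a single gene on chromosome 6, one
unplaced gene), six tandem clusters, one segmental-candidate pair,
type-specific intron counts (1 for type 1, 0 for type 2, 0-1 for type D,
2 for type G, all placed within -9..104 bp of the 8th-Cys codon), and a
decoy set of 107 cysteine-deficient, 11 signal-less and 2 proline-rich
proteins on top of the 40 genuine members.

Biological realism is deliberately limited: coding sequences are
back-translated with a fixed codon table and the genomic background is
i.i.d. uniform ACGT.  That is adequate for coordinate arithmetic,
scanning and recovery tests, but carries no codon-usage or GC signal.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .classify import default_profiles
from .promoter_scan import IUPAC, CisElement, default_catalog, reverse_complement
from .records import GeneModel, ProteinRecord

__all__ = [
    "CohortConfig",
    "TruthManifest",
    "Bundle",
    "generate_proteins",
    "generate_cohort",
    "mutate_cohort",
]

NON_CYS = "ADEFGHIKLMNPQRSTVWY"
HYDROPHOBIC_CORE = "LVIF"
HYDROPHILIC = "DEKNQRSTH"
CXC_HYDROPHILIC = "STNQGKRDEH"
CXC_HYDROPHOBIC = "LIVFA"

#: fixed most-frequent-codon back-translation table
CODON = {
    "A": "GCC", "C": "TGC", "D": "GAC", "E": "GAG", "F": "TTC", "G": "GGC",
    "H": "CAC", "I": "ATC", "K": "AAG", "L": "CTG", "M": "ATG", "N": "AAC",
    "P": "CCC", "Q": "CAG", "R": "AGG", "S": "AGC", "T": "ACC", "V": "GTG",
    "W": "TGG", "Y": "TAC", "*": "TAA",
}

TISSUES = ("EMB", "ROO1", "LEA", "INF1", "INF2", "NOD", "CAR5", "CAR15",
           "ETI", "LEM", "LOD", "PAL", "EPI", "RAC", "ROO2", "SEN")
SILENT_TISSUE = "INF1"


@dataclass(frozen=True)
class GenePlan:
    """Placement and structure plan for one true nsLTP gene."""

    name: str
    type_label: str
    chromosome: Optional[str]
    strand: str
    intron_offsets: tuple[int, ...] = ()
    cluster: Optional[str] = None
    segmental: Optional[str] = None


def default_plan() -> list[GenePlan]:
    """The barley-catalog-shaped default: 16/5/11/8 genes of types 1/2/D/G."""
    t1 = [30]
    tg = [-9, 60]
    entries = [
        # type 1
        ("LTP1.1", "1", "2", t1, "T1", None), ("LTP1.2", "1", "2", t1, "T1", None),
        ("LTP1.3", "1", "2", t1, "T1", None), ("LTP1.4", "1", "3", t1, None, None),
        ("LTP1.5", "1", "3", t1, "T2", None), ("LTP1.6", "1", "3", t1, "T3", None),
        ("LTP1.7", "1", "3", t1, "T2", None), ("LTP1.8", "1", "3", t1, "T2", None),
        ("LTP1.9", "1", "3", t1, "T3", None), ("LTP1.10", "1", "3", t1, None, None),
        ("LTP1.11", "1", "4", t1, None, None), ("LTP1.12", "1", "4", t1, None, "S1"),
        ("LTP1.13", "1", "5", t1, None, "S1"), ("LTP1.14", "1", "5", t1, None, None),
        ("LTP1.15", "1", "7", t1, None, None), ("LTP1.16", "1", "5", t1, None, None),
        # type 2 (intronless)
        ("LTP2.1", "2", "1", [], "T4", None), ("LTP2.2", "2", "1", [], "T4", None),
        ("LTP2.3", "2", "2", [], None, None), ("LTP2.4", "2", "4", [], "T5", None),
        ("LTP2.5", "2", "4", [], "T5", None),
        # type D (three intron carriers)
        ("LTPd1", "D", "1", [15], None, None), ("LTPd2", "D", "2", [], "T6", None),
        ("LTPd3", "D", "2", [], None, None), ("LTPd4", "D", "2", [], None, None),
        ("LTPd5", "D", "2", [], "T6", None), ("LTPd6", "D", "2", [], "T6", None),
        ("LTPd7", "D", "2", [15], None, None), ("LTPd8", "D", "4", [], None, None),
        ("LTPd9", "D", "7", [15], None, None), ("LTPd10", "D", "5", [], None, None),
        ("LTPd11", "D", "7", [], None, None),
        # type G (GPI-anchored, two introns)
        ("LTPg1", "G", "1", tg, None, None), ("LTPg2", "G", "2", tg, None, None),
        ("LTPg3", "G", "4", tg, None, None), ("LTPg4", "G", "5", tg, None, None),
        ("LTPg5", "G", "5", tg, None, None), ("LTPg6", "G", "5", tg, None, None),
        ("LTPg7", "G", None, tg, None, None), ("LTPg8", "G", "6", tg, None, None),
    ]
    plan = []
    for i, (name, label, chrom, introns, cluster, segmental) in enumerate(entries):
        plan.append(
            GenePlan(
                name=name,
                type_label=label,
                chromosome=chrom,
                strand="+" if i % 3 else "-",
                intron_offsets=tuple(introns),
                cluster=cluster,
                segmental=segmental,
            )
        )
    return plan


def compact_plan(type_counts: dict[str, int]) -> list[GenePlan]:
    """A minimal plan without duplication structure, for quick cohorts."""
    intron_plan = {"1": (30,), "2": (), "C": (30,), "D": (), "E": (30,), "F": (30,),
                   "G": (-9, 60)}
    plan = []
    i = 0
    for label, count in type_counts.items():
        for k in range(count):
            plan.append(
                GenePlan(
                    name=f"LTP{label}.{k + 1}",
                    type_label=label,
                    chromosome=str(i % 7 + 1),
                    strand="+" if i % 2 else "-",
                    intron_offsets=intron_plan.get(label, ()),
                )
            )
            i += 1
    return plan


@dataclass
class CohortConfig:
    """Study-condition knobs of the synthetic cohort."""

    plan: list[GenePlan] = field(default_factory=default_plan)
    decoy_counts: dict[str, int] = field(
        default_factory=lambda: {
            "cys_deficient": 107, "nss_lacking": 11, "proline_rich": 2, "storage_like": 0,
        }
    )
    #: per-type (g1..g5) sampling ranges; defaults to the shipped type profiles
    spacing_ranges: dict[str, tuple[tuple[int, int], ...]] = field(default_factory=dict)
    #: per-residue divergence of each member from its type's ancestral
    #: sequence.  Members of one type share an ancestor (so types form
    #: clades, as in real families) but sit well below the duplication
    #: identity cutoff; duplicate copies diverge only by copy_mutation_rate.
    within_type_divergence: float = 0.5
    copy_mutation_rate: float = 0.08
    gene_spacing_bp: int = 120_000
    cluster_spacing_bp: int = 20_000
    promoter_length: int = 1500
    promoter_elements: tuple[str, ...] = (
        "TATA-box", "CAAT-box", "ARE", "MBS", "LTR", "ABRE", "G-box", "A-box",
    )
    promoter_plants_per_gene: tuple[int, int] = (3, 6)
    conditions: tuple[str, ...] = ("control", "cold", "drought", "salt")
    calibrator: str = "control"
    fold_changes: dict[str, float] = field(
        default_factory=lambda: {"cold": 0.25, "drought": 4.0, "salt": 2.0}
    )
    ct_noise_sd: float = 0.1
    n_bio_reps: int = 3
    n_tech_reps: int = 3
    qpcr_types: tuple[str, ...] = ("1",)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.spacing_ranges:
            self.spacing_ranges = {
                p.label: p.gap_ranges for p in default_profiles() if not p.label == "X"
            }
        if any(v < 0 for v in self.decoy_counts.values()):
            raise ValueError("decoy counts must be non-negative")
        for plan in self.plan:
            for off in plan.intron_offsets:
                if not -9 <= off <= 104:
                    raise ValueError(
                        f"{plan.name}: intron offset {off} outside the catalogued -9..104 bp band"
                    )


@dataclass
class ProteinTruth:
    kind: str  # type label or decoy class
    nss_cleavage: Optional[int] = None
    gpi_omega: Optional[int] = None
    cys_positions: tuple[int, ...] = ()
    gaps: tuple[int, ...] = ()


@dataclass
class TruthManifest:
    proteins: dict[str, ProteinTruth] = field(default_factory=dict)
    genes: dict[str, dict] = field(default_factory=dict)
    promoters: dict[str, list[tuple[str, int, str]]] = field(default_factory=dict)
    fold_changes: dict[str, dict[str, float]] = field(default_factory=dict)
    specific_tissue: dict[str, str] = field(default_factory=dict)

    def to_yaml(self) -> str:
        doc = {
            "proteins": {
                name: {
                    "kind": t.kind,
                    "nss_cleavage": t.nss_cleavage,
                    "gpi_omega": t.gpi_omega,
                    "cys_positions": list(t.cys_positions),
                    "gaps": list(t.gaps),
                }
                for name, t in sorted(self.proteins.items())
            },
            "genes": {name: info for name, info in sorted(self.genes.items())},
            "promoters": {
                name: [list(p) for p in plants] for name, plants in sorted(self.promoters.items())
            },
            "fold_changes": {g: dict(sorted(fc.items())) for g, fc in sorted(self.fold_changes.items())},
            "specific_tissue": dict(sorted(self.specific_tissue.items())),
        }
        return yaml.safe_dump(doc, sort_keys=True)


@dataclass
class Bundle:
    """In-memory synthetic cohort; ``write`` emits the on-disk file set."""

    proteins: list[ProteinRecord]
    genes: dict[str, GeneModel]
    genome: dict[str, str]
    promoters: dict[str, str]
    fpkm: pd.DataFrame
    qpcr: pd.DataFrame
    manifest: TruthManifest

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        from .io import write_fasta, write_gff3

        write_fasta(out / "proteins.faa", [(p.id, p.sequence, p.description) for p in self.proteins])
        write_fasta(out / "genome.fa", sorted(self.genome.items()))
        write_fasta(out / "promoters.fa", sorted(self.promoters.items()))
        write_gff3(out / "genes.gff3", self.genes.values())
        self.fpkm.to_csv(out / "fpkm.tsv", sep="\t")
        self.qpcr.to_csv(out / "qpcr.tsv", sep="\t", index=False)
        (out / "manifest.yaml").write_text(self.manifest.to_yaml())


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(zlib.crc32(stream.encode()),))
    )


def _choice(rng: np.random.Generator, alphabet: str, k: int) -> str:
    if k == 0:
        return ""
    codes = np.frombuffer(alphabet.encode(), dtype=np.uint8)
    return codes[rng.integers(0, len(codes), size=k)].tobytes().decode()


@dataclass
class _Parts:
    """Construction-kit view of a true nsLTP precursor."""

    signal: str       # Met + hydrophobic core
    cleavage_res: str  # A/G/S at the cleavage position
    nreg: str         # between cleavage and C1
    gaps: tuple[str, str, str, str, str]
    cxc_x: str
    tail: str         # after C8 (hydrophilic)
    gpi_tail: str = ""  # "" for non-G; "S" + 24 hydrophobic for type G

    def sequence(self) -> str:
        g1, g2, g3, g4, g5 = self.gaps
        motif = f"C{g1}C{g2}CC{g3}C{self.cxc_x}C{g4}C{g5}C"
        return self.signal + self.cleavage_res + self.nreg + motif + self.tail + self.gpi_tail

    def truth(self, kind: str) -> ProteinTruth:
        cleavage = len(self.signal) + 1
        c1 = cleavage + len(self.nreg) + 1
        g = [len(x) for x in self.gaps]
        cys = (
            c1,
            c1 + g[0] + 1,
            c1 + g[0] + g[1] + 2,
            c1 + g[0] + g[1] + 3,
            c1 + g[0] + g[1] + g[2] + 4,
            c1 + g[0] + g[1] + g[2] + 6,
            c1 + g[0] + g[1] + g[2] + g[3] + 7,
            c1 + g[0] + g[1] + g[2] + g[3] + g[4] + 8,
        )
        seq_len = len(self.sequence())
        omega = seq_len - 24 if self.gpi_tail else None
        return ProteinTruth(
            kind=kind, nss_cleavage=cleavage, gpi_omega=omega,
            cys_positions=cys, gaps=tuple(g),
        )


_TAIL_LENGTH = {"G": (20, 29)}
_DEFAULT_TAIL_LENGTH = (36, 45)


def _make_parts(type_label: str, ranges, rng: np.random.Generator,
                full_width: bool = False) -> _Parts:
    """One independent precursor; ``full_width`` maximizes gap/tail lengths
    (used for type ancestors from which members are derived)."""
    signal = "M" + _choice(rng, HYDROPHOBIC_CORE, int(rng.integers(9, 13)))
    gaps = tuple(
        _choice(rng, NON_CYS, hi if full_width else int(rng.integers(lo, hi + 1)))
        for lo, hi in ranges
    )
    tail_lo, tail_hi = _TAIL_LENGTH.get(type_label, _DEFAULT_TAIL_LENGTH)
    cxc_pool = CXC_HYDROPHILIC if type_label == "1" else CXC_HYDROPHOBIC
    parts = _Parts(
        signal=signal,
        cleavage_res="AGS"[int(rng.integers(0, 3))],
        nreg=_choice(rng, HYDROPHILIC, int(rng.integers(4, 9))),
        gaps=gaps,  # type: ignore[arg-type]
        cxc_x=cxc_pool[int(rng.integers(0, len(cxc_pool)))],
        tail=_choice(rng, HYDROPHILIC, tail_hi - 1 if full_width else int(rng.integers(tail_lo, tail_hi))),
    )
    if type_label == "G":
        parts = replace(parts, gpi_tail="S" + _choice(rng, HYDROPHOBIC_CORE, 24))
    return parts


def _member_from_ancestor(ancestor: _Parts, type_label: str, ranges,
                          divergence: float, rng: np.random.Generator) -> _Parts:
    """A type member: resampled gap/tail lengths, ancestor-derived content."""
    gaps = tuple(
        _mutate_string(ancestor.gaps[i][: int(rng.integers(lo, hi + 1))],
                       divergence, rng, NON_CYS)
        for i, (lo, hi) in enumerate(ranges)
    )
    tail_lo, tail_hi = _TAIL_LENGTH.get(type_label, _DEFAULT_TAIL_LENGTH)
    tail = _mutate_string(ancestor.tail[: int(rng.integers(tail_lo, tail_hi))],
                          divergence, rng, HYDROPHILIC)
    cxc_pool = CXC_HYDROPHILIC if type_label == "1" else CXC_HYDROPHOBIC
    parts = _Parts(
        signal="M" + _choice(rng, HYDROPHOBIC_CORE, int(rng.integers(9, 13))),
        cleavage_res="AGS"[int(rng.integers(0, 3))],
        nreg=_choice(rng, HYDROPHILIC, int(rng.integers(4, 9))),
        gaps=gaps,  # type: ignore[arg-type]
        cxc_x=cxc_pool[int(rng.integers(0, len(cxc_pool)))],
        tail=tail,
        gpi_tail="S" + _choice(rng, HYDROPHOBIC_CORE, 24) if type_label == "G" else "",
    )
    return parts


def _mutate_string(text: str, rate: float, rng: np.random.Generator, alphabet: str) -> str:
    out = list(text)
    for i, res in enumerate(out):
        if res != "C" and rng.random() < rate:
            out[i] = alphabet[int(rng.integers(0, len(alphabet)))]
    return "".join(out)


def _copy_parts(base: _Parts, rate: float, rng: np.random.Generator) -> _Parts:
    # mutate only motif gaps and the hydrophilic tail so signal/GPI calls survive
    return replace(
        base,
        gaps=tuple(_mutate_string(g, rate, rng, NON_CYS) for g in base.gaps),  # type: ignore[arg-type]
        tail=_mutate_string(base.tail, rate, rng, HYDROPHILIC),
    )


def _decoy_sequence(kind: str, ranges_by_type: dict, rng: np.random.Generator) -> str:
    if kind == "cys_deficient":
        signal = "M" + _choice(rng, HYDROPHOBIC_CORE, int(rng.integers(9, 13)))
        return signal + "A" + _choice(rng, NON_CYS, int(rng.integers(60, 101)))
    labels = sorted(ranges_by_type)
    label = labels[int(rng.integers(0, len(labels)))]
    ranges = ranges_by_type[label]
    g = [_choice(rng, NON_CYS, int(rng.integers(lo, hi + 1))) for lo, hi in ranges]
    motif = f"C{g[0]}C{g[1]}CC{g[2]}C{CXC_HYDROPHOBIC[int(rng.integers(0, 5))]}C{g[3]}C{g[4]}C"
    if kind == "nss_lacking":
        return "M" + _choice(rng, "DEKNQRT", 17) + motif + _choice(rng, HYDROPHILIC, 20)
    if kind == "proline_rich":
        signal = "M" + _choice(rng, HYDROPHOBIC_CORE, int(rng.integers(9, 13)))
        linker = _choice(rng, "PHG", int(rng.integers(16, 21)))
        return signal + "A" + linker + motif + _choice(rng, HYDROPHILIC, 20)
    raise ValueError(f"unknown decoy class {kind!r}")


def generate_proteins(config: CohortConfig) -> tuple[list[ProteinRecord], TruthManifest]:
    """True nsLTP proteins plus decoys, with per-protein ground truth."""
    rng = _rng(config.seed, "proteins")
    manifest = TruthManifest()
    proteins: list[ProteinRecord] = []

    group_base: dict[str, _Parts] = {}
    type_ancestor: dict[str, _Parts] = {}
    for plan in config.plan:
        ranges = config.spacing_ranges[plan.type_label]
        group = plan.cluster or plan.segmental
        if group is not None and group in group_base:
            parts = _copy_parts(group_base[group], config.copy_mutation_rate, rng)
        else:
            if plan.type_label not in type_ancestor:
                type_ancestor[plan.type_label] = _make_parts(
                    plan.type_label, ranges, rng, full_width=True
                )
            parts = _member_from_ancestor(
                type_ancestor[plan.type_label], plan.type_label, ranges,
                config.within_type_divergence, rng,
            )
            if group is not None:
                group_base[group] = parts
        proteins.append(
            ProteinRecord(id=plan.name, sequence=parts.sequence(), source="synthetic",
                          description=f"synthetic type {plan.type_label} nsLTP")
        )
        manifest.proteins[plan.name] = parts.truth(plan.type_label)

    decoy_rng = _rng(config.seed, "decoys")
    for kind in sorted(config.decoy_counts):
        for i in range(config.decoy_counts[kind]):
            name = f"DECOY_{kind}_{i + 1:03d}"
            if kind == "storage_like":
                base = _make_parts("1", config.spacing_ranges["1"], decoy_rng)
                seq = base.sequence()
                manifest.proteins[name] = base.truth(kind)
            else:
                seq = _decoy_sequence(kind, config.spacing_ranges, decoy_rng)
                manifest.proteins[name] = ProteinTruth(kind=kind)
            proteins.append(
                ProteinRecord(id=name, sequence=seq, source="synthetic",
                              description=f"synthetic decoy ({kind})")
            )
    return proteins, manifest


def _plant_elements(
    window: str,
    elements: Sequence[CisElement],
    rng: np.random.Generator,
    n_plants: int,
) -> tuple[str, list[tuple[str, int, str]]]:
    chars = list(window)
    taken: list[tuple[int, int]] = []
    plants: list[tuple[str, int, str]] = []
    for _ in range(n_plants):
        element = elements[int(rng.integers(0, len(elements)))]
        concrete = "".join(
            IUPAC[code][int(rng.integers(0, len(IUPAC[code])))] for code in element.consensus
        )
        strand = "+" if rng.random() < 0.7 else "-"
        if strand == "-":
            concrete = reverse_complement(concrete)
        width = len(concrete)
        for _attempt in range(50):
            start = int(rng.integers(0, len(chars) - width + 1))
            if all(end <= start or begin >= start + width for begin, end in taken):
                taken.append((start, start + width))
                chars[start : start + width] = concrete
                plants.append((element.name, start + 1, strand))
                break
    plants.sort(key=lambda p: p[1])
    return "".join(chars), plants


def _spliced_gene_unit(
    protein: str,
    cys8: int,
    intron_offsets: Sequence[int],
    promoter: str,
    rng: np.random.Generator,
) -> tuple[str, list[tuple[int, int]]]:
    """Forward-orientation gene unit (promoter + gene body) and local CDS intervals."""
    cds_nt = "".join(CODON[res] for res in protein) + CODON["*"]
    codon_start = 3 * (cys8 - 1)
    cuts = sorted(codon_start + off for off in intron_offsets)
    for cut in cuts:
        if not 0 < cut < len(cds_nt):
            raise ValueError(f"intron insertion point {cut} outside CDS of {len(cds_nt)} bp")
    segments = []
    prev = 0
    for cut in cuts:
        segments.append(cds_nt[prev:cut])
        prev = cut
    segments.append(cds_nt[prev:])
    body = ""
    local_cds: list[tuple[int, int]] = []
    cursor = len(promoter)
    for i, segment in enumerate(segments):
        local_cds.append((cursor, cursor + len(segment)))
        body += segment
        cursor += len(segment)
        if i < len(segments) - 1:
            intron = "GT" + _choice(rng, "ACGT", 86) + "AG"
            body += intron
            cursor += len(intron)
    unit = promoter + body + _choice(rng, "ACGT", 200)
    return unit, local_cds


def generate_cohort(config: Optional[CohortConfig] = None,
                    out_dir: Optional[str | Path] = None) -> Bundle:
    """Full synthetic bundle: proteins, genome+GFF3, promoters, expression."""
    config = config or CohortConfig()
    proteins, manifest = generate_proteins(config)

    genome_rng = _rng(config.seed, "genome")
    promoter_rng = _rng(config.seed, "promoters")
    catalog = {e.name: e for e in default_catalog()}
    plant_pool = [catalog[name] for name in config.promoter_elements]

    # cluster members are placed contiguously along their chromosome
    by_chrom: dict[Optional[str], list[GenePlan]] = {}
    for plan in config.plan:
        by_chrom.setdefault(plan.chromosome, []).append(plan)
    placement: dict[Optional[str], list[GenePlan]] = {}
    for chrom, members in by_chrom.items():
        ordered, placed = [], set()
        for plan in members:
            if plan.name in placed:
                continue
            if plan.cluster:
                mates = [m for m in members if m.cluster == plan.cluster]
            else:
                mates = [plan]
            for mate in mates:
                ordered.append(mate)
                placed.add(mate.name)
        placement[chrom] = ordered

    genome: dict[str, str] = {}
    promoters: dict[str, str] = {}
    genes: dict[str, GeneModel] = {}
    sequences = {p.id: p.sequence for p in proteins}

    for chrom in sorted(placement, key=lambda c: (c is None, c)):
        pieces: list[str] = [_choice(genome_rng, "ACGT", 2000)]
        position = 2000
        previous_cluster: Optional[str] = None
        for plan in placement[chrom]:
            truth = manifest.proteins[plan.name]
            window = _choice(promoter_rng, "ACGT", config.promoter_length)
            lo, hi = config.promoter_plants_per_gene
            window, plants = _plant_elements(
                window, plant_pool, promoter_rng, int(promoter_rng.integers(lo, hi + 1))
            )
            promoters[plan.name] = window
            manifest.promoters[plan.name] = plants

            unit, local_cds = _spliced_gene_unit(
                sequences[plan.name], truth.cys_positions[7], plan.intron_offsets,
                window, genome_rng,
            )
            if previous_cluster is not None and plan.cluster == previous_cluster:
                gap = config.cluster_spacing_bp
            else:
                gap = config.gene_spacing_bp if len(pieces) > 1 else 0
            previous_cluster = plan.cluster
            if gap:
                pieces.append(_choice(genome_rng, "ACGT", gap))
                position += gap
            if plan.strand == "+":
                pieces.append(unit)
                cds = [(position + s, position + e) for s, e in local_cds]
            else:
                pieces.append(reverse_complement(unit))
                total = len(unit)
                cds = sorted((position + total - e, position + total - s) for s, e in local_cds)
            gene_id = plan.name + ".g"
            genes[gene_id] = GeneModel(
                gene_id=gene_id,
                chromosome=chrom,
                strand=plan.strand,
                exons=list(cds),
                cds=list(cds),
                protein_id=plan.name,
            )
            manifest.genes[gene_id] = {
                "chromosome": chrom,
                "strand": plan.strand,
                "cluster": plan.cluster,
                "segmental": plan.segmental,
                "intron_offsets": list(plan.intron_offsets),
                "type": plan.type_label,
            }
            position += len(unit)
        if chrom is not None:
            pieces.append(_choice(genome_rng, "ACGT", 1000))
            genome[chrom] = "".join(pieces)
        else:
            # unplaced genes live on an unanchored scaffold
            pieces.append(_choice(genome_rng, "ACGT", 1000))
            genome["scaffold_un"] = "".join(pieces)
            for plan in placement[chrom]:
                genes[plan.name + ".g"].chromosome = None

    expr_rng = _rng(config.seed, "expression")
    fpkm = _fpkm_matrix(config, manifest, expr_rng)
    qpcr = _qpcr_table(config, manifest, expr_rng)

    bundle = Bundle(
        proteins=proteins, genes=genes, genome=genome, promoters=promoters,
        fpkm=fpkm, qpcr=qpcr, manifest=manifest,
    )
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle


def _fpkm_matrix(config: CohortConfig, manifest: TruthManifest,
                 rng: np.random.Generator) -> pd.DataFrame:
    names = [p.name for p in config.plan]
    rows = []
    candidate_tissues = [t for t in TISSUES if t != SILENT_TISSUE]
    for plan in config.plan:
        row = {}
        if plan.type_label in ("1", "2"):
            specific = candidate_tissues[int(rng.integers(0, len(candidate_tissues)))]
            manifest.specific_tissue[plan.name] = specific
            for tissue in TISSUES:
                if tissue == SILENT_TISSUE:
                    row[tissue] = 0.0
                elif tissue == specific:
                    row[tissue] = float(np.round(rng.uniform(50, 200), 2))
                else:
                    row[tissue] = float(np.round(rng.uniform(0, 3), 2))
        else:
            for tissue in TISSUES:
                row[tissue] = 0.0 if tissue == SILENT_TISSUE else float(
                    np.round(rng.uniform(1, 10), 2)
                )
        rows.append(row)
    return pd.DataFrame(rows, index=names, columns=list(TISSUES))


def _qpcr_table(config: CohortConfig, manifest: TruthManifest,
                rng: np.random.Generator) -> pd.DataFrame:
    records = []
    for plan in config.plan:
        if plan.type_label not in config.qpcr_types:
            continue
        base_dct = float(rng.uniform(4.0, 6.0))
        manifest.fold_changes[plan.name] = dict(config.fold_changes)
        for condition in config.conditions:
            fold = config.fold_changes.get(condition, 1.0)
            true_dct = base_dct - float(np.log2(fold))
            for bio in range(1, config.n_bio_reps + 1):
                for tech in range(1, config.n_tech_reps + 1):
                    ct_ref = 20.0 + rng.normal(0.0, config.ct_noise_sd)
                    ct_tgt = 20.0 + true_dct + rng.normal(0.0, config.ct_noise_sd)
                    records.append(
                        {
                            "gene": plan.name, "condition": condition,
                            "bio_rep": bio, "tech_rep": tech,
                            "ct_target": round(ct_tgt, 4), "ct_reference": round(ct_ref, 4),
                        }
                    )
    return pd.DataFrame.from_records(
        records, columns=["gene", "condition", "bio_rep", "tech_rep", "ct_target", "ct_reference"]
    )


def mutate_cohort(
    proteins: Sequence[ProteinRecord],
    rate: float,
    seed: int,
) -> list[ProteinRecord]:
    """Point-mutate non-cysteine residues at the given per-residue rate.

    Cysteines are never touched, so planted 8CMs survive; substitutions
    are drawn uniformly from the 19 non-Cys standard residues.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("mutation rate must lie in [0, 1)")
    rng = _rng(seed, "mutate")
    mutated = []
    for protein in proteins:
        mutated.append(
            ProteinRecord(
                id=protein.id,
                sequence=_mutate_string(protein.sequence, rate, rng, NON_CYS),
                source=protein.source,
                description=protein.description,
            )
        )
    return mutated
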