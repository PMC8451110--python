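"""Gene-model context: intron geometry, chromosome maps, duplications.

Intron positions are reported relative to the first base of the codon
encoding the eighth motif cysteine, measured along the spliced transcript
(negative = upstream of that codon).  Tandem duplication follows the
usual gene-family convention: a pair of family genes on the same
chromosome, within a genomic window and with few intervening family
members, whose proteins exceed an identity cutoff.  High-identity pairs
failing the tandem geometry are reported as *segmental candidates* —
confirming true segmental events needs synteny blocks, which is out of
scope here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .align import IdentityMatrix
from .records import EightCMMatch, GeneModel

__all__ = [
    "IntronReport",
    "DuplicationEvent",
    "DuplicationConfig",
    "intron_stats",
    "find_duplications",
    "chromosome_map",
]

UNPLACED = "chrUn"


@dataclass(frozen=True)
class IntronReport:
    gene_id: str
    intron_count: int
    #: bp offsets of each intron's insertion point from the first base of
    #: the 8th-Cys codon, in transcript orientation (negative = upstream).
    offsets_from_c8: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.intron_count != len(self.offsets_from_c8):
            raise ValueError("intron count must equal number of offsets")


def _cds_in_transcript_order(gene: GeneModel) -> list[tuple[int, int]]:
    return list(gene.cds) if gene.strand == "+" else list(reversed(gene.cds))


def intron_stats(
    gene: GeneModel,
    match: EightCMMatch,
    protein_length: Optional[int] = None,
) -> IntronReport:
    """Intron count and offsets relative to the 8th-Cys codon start.

    The offsets are computed in spliced-CDS coordinates, which makes them
    invariant under reflection of the locus onto the opposite strand.
    ``protein_length`` (when given) cross-checks the CDS against the
    protein carrying the motif.
    """
    cds_len = gene.cds_length
    if protein_length is not None and cds_len not in (3 * protein_length, 3 * protein_length + 3):
        raise ValueError(
            f"{gene.gene_id}: CDS length {cds_len} does not match "
            f"protein of {protein_length} residues"
        )
    codon_start = 3 * (match.cys_positions[7] - 1)  # 0-based bp within spliced CDS
    if codon_start + 3 > cds_len:
        raise ValueError(f"{gene.gene_id}: 8th-Cys codon lies beyond the CDS")
    segments = _cds_in_transcript_order(gene)
    offsets = []
    consumed = 0
    for seg_start, seg_end in segments[:-1]:
        consumed += seg_end - seg_start
        offsets.append(consumed - codon_start)
    return IntronReport(gene_id=gene.gene_id, intron_count=len(segments) - 1,
                        offsets_from_c8=tuple(offsets))


@dataclass(frozen=True)
class DuplicationEvent:
    gene_a: str
    gene_b: str
    kind: str  # tandem | segmental_candidate
    identity: float
    separation_bp: Optional[int] = None
    intervening_genes: Optional[int] = None


@dataclass
class DuplicationConfig:
    identity_cutoff: float = 50.0
    max_separation_bp: int = 100_000
    max_intervening: int = 5


@dataclass
class DuplicationCalls:
    events: list[DuplicationEvent] = field(default_factory=list)
    clusters: list[set[str]] = field(default_factory=list)

    @property
    def tandem(self) -> list[DuplicationEvent]:
        return [e for e in self.events if e.kind == "tandem"]

    @property
    def segmental_candidates(self) -> list[DuplicationEvent]:
        return [e for e in self.events if e.kind == "segmental_candidate"]


def find_duplications(
    genes: Sequence[GeneModel],
    identity: IdentityMatrix,
    config: Optional[DuplicationConfig] = None,
) -> DuplicationCalls:
    """Call tandem pairs and segmental candidates; cluster tandem genes.

    The identity matrix is indexed by the genes' linked protein ids.
    Clusters are the connected components of the tandem relation.
    """
    config = config or DuplicationConfig()
    for gene in genes:
        if (gene.protein_id or gene.gene_id) not in identity:
            raise ValueError(f"{gene.gene_id}: no identity row for its protein")

    by_chrom: dict[Optional[str], list[GeneModel]] = {}
    for gene in genes:
        by_chrom.setdefault(gene.chromosome, []).append(gene)
    for members in by_chrom.values():
        members.sort(key=lambda g: g.start)
    order = {g.gene_id: i for members in by_chrom.values() for i, g in enumerate(members)}

    calls = DuplicationCalls()
    adjacency: dict[str, set[str]] = {}
    n = len(genes)
    genes = list(genes)
    for i in range(n):
        for j in range(i + 1, n):
            ga, gb = genes[i], genes[j]
            ident = identity[ga.protein_id or ga.gene_id, gb.protein_id or gb.gene_id]
            if ident < config.identity_cutoff:
                continue
            tandem = False
            separation = intervening = None
            if ga.chromosome is not None and ga.chromosome == gb.chromosome:
                separation = max(0, max(ga.start, gb.start) - min(ga.end, gb.end))
                intervening = abs(order[ga.gene_id] - order[gb.gene_id]) - 1
                tandem = (
                    separation <= config.max_separation_bp
                    and intervening <= config.max_intervening
                )
            kind = "tandem" if tandem else "segmental_candidate"
            calls.events.append(
                DuplicationEvent(ga.gene_id, gb.gene_id, kind, ident, separation, intervening)
            )
            if tandem:
                adjacency.setdefault(ga.gene_id, set()).add(gb.gene_id)
                adjacency.setdefault(gb.gene_id, set()).add(ga.gene_id)

    seen: set[str] = set()
    for gene_id in sorted(adjacency):
        if gene_id in seen:
            continue
        stack, component = [gene_id], set()
        while stack:
            current = stack.pop()
            if current in component:
                continue
            component.add(current)
            stack.extend(adjacency[current] - component)
        seen |= component
        calls.clusters.append(component)
    return calls


def chromosome_map(genes: Sequence[GeneModel]) -> tuple[dict[str, list[str]], dict[str, int]]:
    """Genes grouped and ordered by chromosome, plus per-chromosome counts.

    Unplaced genes are listed under "chrUn" and excluded from the counts.
    """
    grouped: dict[str, list[GeneModel]] = {}
    for gene in genes:
        key = gene.chromosome if gene.chromosome is not None else UNPLACED
        grouped.setdefault(key, []).append(gene)
    ordered = {
        chrom: [g.gene_id for g in sorted(members, key=lambda g: (g.start, g.gene_id))]
        for chrom, members in sorted(grouped.items())
    }
    counts = {chrom: len(names) for chrom, names in ordered.items() if chrom != UNPLACED}
    return ordered, counts
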