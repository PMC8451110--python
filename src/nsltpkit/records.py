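"""Core record types shared across the pipeline.

Coordinates follow the convention used throughout the package: every
position reported to a user (cysteine positions, signal-peptide cleavage
sites, GPI omega-sites, motif spans) is 1-based and inclusive.  Genomic
intervals are stored internally 0-based half-open on the forward strand
and converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
#: 'X' is tolerated as an unknown residue; every scale table documents its fallback.
VALID_RESIDUES = AMINO_ACIDS | {"X"}


@dataclass(frozen=True)
class ProteinRecord:
    """A candidate protein sequence with provenance."""

    id: str
    sequence: str
    source: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise ValueError(
                f"{self.id}: illegal residue(s) {sorted(bad)}; "
                "only the 20 standard letters plus X are accepted"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class EightCMMatch:
    """One placement of the eight-cysteine motif C-Xn-C-Xn-CC-Xn-CXC-Xn-C-Xn-C.

    ``cys_positions`` are the eight cysteines, 1-based.  ``gaps`` holds the
    five free inter-cysteine gap lengths (g1: C1..C2, g2: C2..C3,
    g3: C4..C5, g4: C6..C7, g5: C7..C8); the CC adjacency and the single
    CXC residue are structural, not free gaps.
    """

    cys_positions: tuple[int, int, int, int, int, int, int, int]
    gaps: tuple[int, int, int, int, int]
    cxc_x: str
    span: tuple[int, int]

    def __post_init__(self) -> None:
        p = self.cys_positions
        if len(p) != 8 or any(b <= a for a, b in zip(p, p[1:])):
            raise ValueError("cys_positions must be 8 strictly increasing integers")
        if p[3] != p[2] + 1:
            raise ValueError("C3 and C4 must be adjacent (the CC block)")
        if p[5] != p[4] + 2:
            raise ValueError("exactly one residue must separate C5 and C6 (the CXC block)")
        if self.span != (p[0], p[7]):
            raise ValueError("span must be [C1, C8], 1-based inclusive")

    @property
    def spacing(self) -> tuple[int, int, int, int, int]:
        return self.gaps


@dataclass
class CandidateRecord:
    """A protein together with its screening outcome."""

    protein: ProteinRecord
    match: Optional[EightCMMatch] = None
    nss_cleavage: Optional[int] = None
    gpi_omega: Optional[int] = None
    mature_sequence: str = ""
    status: str = "excluded"  # accepted | excluded
    exclusion_stage: str = "none"

    STAGES = ("no_8cm", "no_nss", "proline_rich", "storage_like", "too_long", "none")

    def __post_init__(self) -> None:
        if self.exclusion_stage not in self.STAGES:
            raise ValueError(f"unknown exclusion stage {self.exclusion_stage!r}")

    @property
    def accepted(self) -> bool:
        return self.status == "accepted"

    @property
    def gpi_positive(self) -> bool:
        return self.gpi_omega is not None


@dataclass
class ScreenReport:
    """Per-stage accounting of the screening funnel."""

    input_count: int = 0
    excluded: dict[str, int] = field(default_factory=dict)
    accepted_count: int = 0

    def check_conservation(self) -> None:
        total = self.accepted_count + sum(self.excluded.values())
        if total != self.input_count:
            raise AssertionError(
                f"funnel accounting broken: {self.input_count} in, "
                f"{self.accepted_count} accepted + {sum(self.excluded.values())} excluded"
            )


@dataclass
class GeneModel:
    """A protein-coding gene model on a genome assembly.

    ``exons`` and ``cds`` are 0-based half-open intervals on the forward
    strand, sorted by start.  ``chromosome`` may be None for unplaced
    genes (reported under "chrUn").
    """

    gene_id: str
    chromosome: Optional[str]
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    protein_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        for name, ivs in (("exons", self.exons), ("cds", self.cds)):
            for (s, e) in ivs:
                if e <= s:
                    raise ValueError(f"{self.gene_id}: empty/inverted {name} interval {(s, e)}")
            if any(b[0] < a[1] for a, b in zip(ivs, ivs[1:])):
                raise ValueError(f"{self.gene_id}: {name} overlap or are unsorted")
        if self.cds_length % 3 != 0:
            raise ValueError(f"{self.gene_id}: CDS length {self.cds_length} not divisible by 3")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def intron_count(self) -> int:
        return len(self.cds) - 1
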