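"""Promoter extraction and IUPAC cis-element scanning.

The promoter window is the ~1.5 kb immediately upstream of the
*translation* start (the ATG of the CDS), extracted strand-aware so the
returned sequence always reads 5'->3' toward the gene.  Scanning matches
IUPAC-degenerate consensus strings on both strands; an 'N' in the
*genome* matches nothing, so assembly gaps never produce hits.
Palindromic consensus hits with identical footprints collapse to a
single strand "±" record.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Optional, Sequence

import yaml

from .records import GeneModel

__all__ = [
    "CisElement",
    "PromoterHit",
    "load_catalog",
    "default_catalog",
    "extract_upstream",
    "scan",
    "compare_organization",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

CATEGORIES = ("stress", "hormone", "light", "development", "core")


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CisElement:
    name: str
    consensus: str
    category: str = "core"

    def __post_init__(self) -> None:
        if not self.consensus:
            raise ValueError(f"{self.name}: empty consensus")
        bad = set(self.consensus.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"{self.name}: non-IUPAC letters {sorted(bad)} in consensus")
        if self.category not in CATEGORIES:
            raise ValueError(f"{self.name}: unknown category {self.category!r}")


@dataclass(frozen=True)
class PromoterHit:
    gene_id: str
    element: str
    start: int  # 1-based within the scanned window
    end: int    # 1-based inclusive
    strand: str  # + | - | ±
    matched: str


def load_catalog(path) -> list[CisElement]:
    with open(path) as handle:
        raw = yaml.safe_load(handle)
    return [CisElement(name=e["name"], consensus=e["consensus"].upper(),
                       category=e.get("category", "core")) for e in raw]


def default_catalog() -> list[CisElement]:
    with resources.as_file(resources.files("nsltpkit.data") / "plantcare.yaml") as path:
        return load_catalog(path)


def extract_upstream(
    genome: Mapping[str, str],
    gene: GeneModel,
    length: int = 1500,
) -> str:
    """The upstream window of a gene, 5'->3' toward the translation start.

    For + genes this is ``[ATG - length, ATG)`` on the forward strand;
    for - genes it is the reverse complement of the ``length`` bases
    following the (forward-strand) end of the CDS.  Windows truncated by
    the contig edge are returned shorter, with a warning.
    """
    if gene.chromosome is None or gene.chromosome not in genome:
        raise KeyError(f"{gene.gene_id}: chromosome {gene.chromosome!r} not in genome")
    contig = genome[gene.chromosome]
    if gene.end > len(contig):
        raise ValueError(f"{gene.gene_id}: gene extends beyond contig end")
    if gene.strand == "+":
        tss = gene.cds[0][0]
        lo = tss - length
        if lo < 0:
            warnings.warn(f"{gene.gene_id}: promoter window truncated at contig start",
                          stacklevel=2)
            lo = 0
        return contig[lo:tss]
    tss = gene.cds[-1][1]
    hi = tss + length
    if hi > len(contig):
        warnings.warn(f"{gene.gene_id}: promoter window truncated at contig end", stacklevel=2)
        hi = len(contig)
    return reverse_complement(contig[tss:hi])


def _matches_at(sequence: str, consensus: str, start: int) -> bool:
    for offset, code in enumerate(consensus):
        if sequence[start + offset] not in IUPAC[code]:
            return False
    return True


def scan(
    sequence: str,
    catalog: Sequence[CisElement],
    gene_id: str = "",
) -> list[PromoterHit]:
    """All matches of every catalog element on both strands.

    Hits are reported in forward-window coordinates (1-based inclusive),
    sorted by start then element name.  A consensus matching both strands
    over the same footprint yields one hit with strand "±".
    """
    sequence = sequence.upper()
    n = len(sequence)
    found: dict[tuple[str, int, int], set[str]] = {}
    for element in catalog:
        consensus = element.consensus
        rc_consensus = reverse_complement(consensus)
        width = len(consensus)
        for start in range(n - width + 1):
            if _matches_at(sequence, consensus, start):
                found.setdefault((element.name, start, start + width), set()).add("+")
            if _matches_at(sequence, rc_consensus, start):
                found.setdefault((element.name, start, start + width), set()).add("-")
    hits = []
    for (name, start, end), strands in found.items():
        strand = "±" if strands == {"+", "-"} else next(iter(strands))
        hits.append(
            PromoterHit(
                gene_id=gene_id,
                element=name,
                start=start + 1,
                end=end,
                strand=strand,
                matched=sequence[start:end],
            )
        )
    hits.sort(key=lambda h: (h.start, h.element))
    return hits


@dataclass(frozen=True)
class OrganizationComparison:
    shared_elements: frozenset[str]
    unique_to_a: tuple[tuple[str, int, str], ...]
    unique_to_b: tuple[tuple[str, int, str], ...]
    identical_organization: bool


def compare_organization(
    hits_a: Sequence[PromoterHit],
    hits_b: Sequence[PromoterHit],
) -> OrganizationComparison:
    """Compare two promoters' element organization as (element, start, strand) multisets."""
    from collections import Counter

    def multiset(hits: Sequence[PromoterHit]) -> Counter:
        return Counter((h.element, h.start, h.strand) for h in hits)

    ma, mb = multiset(hits_a), multiset(hits_b)
    only_a = tuple(sorted((ma - mb).elements()))
    only_b = tuple(sorted((mb - ma).elements()))
    shared = frozenset(h.element for h in hits_a) & frozenset(h.element for h in hits_b)
    return OrganizationComparison(
        shared_elements=shared,
        unique_to_a=only_a,
        unique_to_b=only_b,
        identical_organization=(ma == mb),
    )
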