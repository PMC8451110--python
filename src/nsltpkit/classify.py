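"""Type assignment and 8CM alignment for accepted nsLTPs.

Plant nsLTPs fall into four major and several minor types (1, 2, C, D,
E, F, G, plus the unassigned bucket X).  Type is decided by a rule
cascade: a GPI anchor forces type G; otherwise the inter-cysteine
spacing vector must fall inside a type profile's gap ranges, the
intron count of the linked gene model (when available) must match the
profile's expectation, and remaining ties are broken by mean global
identity to the profile's exemplar sequences, then by the smallest type
label.  A candidate matching no profile, or whose best exemplar identity
falls below the threshold when exemplars decide, is labelled X.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from statistics import fmean
from typing import Optional, Sequence

import yaml

from .align import IdentityMatrix, identity_matrix, pairwise_identity  # noqa: F401 (re-export)
from .records import CandidateRecord, EightCMMatch
from .scales import KYTE_DOOLITTLE

__all__ = [
    "TypeProfile",
    "AnchoredAlignment",
    "load_profiles",
    "default_profiles",
    "build_anchored_alignment",
    "cxc_polarity",
    "assign_type",
    "assign_types",
]


@dataclass(frozen=True)
class TypeProfile:
    """Spacing/intron/GPI expectations for one nsLTP type."""

    label: str
    gap_ranges: tuple[tuple[int, int], ...]
    introns: Optional[tuple[int, ...]] = None  # None = no expectation
    gpi: bool = False
    exemplars: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.gap_ranges) != 5:
            raise ValueError(f"type {self.label}: five gap ranges required")
        for lo, hi in self.gap_ranges:
            if hi < lo:
                raise ValueError(f"type {self.label}: empty gap range ({lo}, {hi})")

    def admits_spacing(self, gaps: Sequence[int]) -> bool:
        return all(lo <= g <= hi for g, (lo, hi) in zip(gaps, self.gap_ranges))

    def admits_introns(self, count: Optional[int]) -> bool:
        return count is None or self.introns is None or count in self.introns


def load_profiles(path) -> list[TypeProfile]:
    """Load type profiles from YAML (mapping label -> gaps/introns/gpi/exemplars)."""
    with open(path) as handle:
        raw = yaml.safe_load(handle)
    profiles = []
    for label, spec in raw.items():
        profiles.append(
            TypeProfile(
                label=str(label),
                gap_ranges=tuple(tuple(pair) for pair in spec["gaps"]),
                introns=tuple(spec["introns"]) if spec.get("introns") is not None else None,
                gpi=bool(spec.get("gpi", False)),
                exemplars=tuple(spec.get("exemplars", ())),
            )
        )
    labels = [p.label for p in profiles]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate type labels in profile file")
    return profiles


def default_profiles() -> list[TypeProfile]:
    with resources.as_file(resources.files("nsltpkit.data") / "type_profiles.yaml") as path:
        return load_profiles(path)


# ---------------------------------------------------------------------------
# Cysteine-anchored 8CM alignment
# ---------------------------------------------------------------------------

#: Block layout of the anchored alignment, in order.
BLOCKS = ("C1", "g1", "C2", "g2", "C3C4", "g3", "CXC", "g4", "C7", "g5", "C8")
_FIXED_WIDTH = {"C1": 1, "C2": 1, "C3C4": 2, "CXC": 3, "C7": 1, "C8": 1}


@dataclass
class AnchoredAlignment:
    """8CM alignment in which the eight cysteines are fixed columns.

    Each free gap block is right-padded with '-' to the block's maximum
    width across rows, so cysteine columns are perfectly conserved by
    construction.  ``column_blocks`` maps every column to (block,
    offset-within-block).
    """

    ids: list[str]
    rows: list[str]
    column_blocks: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        widths = {len(row) for row in self.rows}
        if len(widths) > 1:
            raise ValueError("aligned rows must have equal length")

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def cysteine_columns(self) -> list[int]:
        cols = []
        for i, (block, offset) in enumerate(self.column_blocks):
            if block in ("C1", "C2", "C3C4", "C7", "C8"):
                cols.append(i)
            elif block == "CXC" and offset != 1:  # skip the X column
                cols.append(i)
        return cols


def _segments(match: EightCMMatch, sequence: str) -> dict[str, str]:
    p = [pos - 1 for pos in match.cys_positions]  # 0-based
    return {
        "C1": sequence[p[0]],
        "g1": sequence[p[0] + 1 : p[1]],
        "C2": sequence[p[1]],
        "g2": sequence[p[1] + 1 : p[2]],
        "C3C4": sequence[p[2] : p[3] + 1],
        "g3": sequence[p[3] + 1 : p[4]],
        "CXC": sequence[p[4] : p[5] + 1],
        "g4": sequence[p[5] + 1 : p[6]],
        "C7": sequence[p[6]],
        "g5": sequence[p[6] + 1 : p[7]],
        "C8": sequence[p[7]],
    }


def build_anchored_alignment(
    matches: Sequence[tuple[str, EightCMMatch, str]],
) -> AnchoredAlignment:
    """Anchor the eight cysteines and right-pad each gap block with '-'."""
    per_row = [(name, _segments(match, seq)) for name, match, seq in matches]
    widths = {
        block: _FIXED_WIDTH.get(block) or max((len(segs[block]) for _, segs in per_row), default=0)
        for block in BLOCKS
    }
    ids, rows = [], []
    for name, segs in per_row:
        ids.append(name)
        rows.append("".join(segs[block].ljust(widths[block], "-") for block in BLOCKS))
    column_blocks = [
        (block, offset) for block in BLOCKS for offset in range(widths[block])
    ]
    return AnchoredAlignment(ids=ids, rows=rows, column_blocks=column_blocks)


def cxc_polarity(match: EightCMMatch, sequence: str) -> str:
    """Polarity class of the CXC middle residue: hydrophobic iff KD > 0."""
    x = sequence[match.cys_positions[4]]  # residue after C5, 0-based index = pos5
    return "hydrophobic" if KYTE_DOOLITTLE.get(x, 0.0) > 0 else "hydrophilic"


# ---------------------------------------------------------------------------
# Type assignment
# ---------------------------------------------------------------------------


def assign_type(
    candidate: CandidateRecord,
    profiles: Sequence[TypeProfile],
    intron_count: Optional[int] = None,
    identity_threshold: float = 30.0,
) -> tuple[str, float]:
    """Assign an nsLTP type and a confidence to one accepted candidate.

    Returns ``(label, confidence)`` where confidence is the mean global
    identity (percent) of the mature sequence to the winning profile's
    exemplars, or 0.0 when the type is decided by rules alone.
    """
    if not candidate.accepted:
        raise ValueError(f"{candidate.protein.id}: only accepted candidates can be typed")
    if candidate.match is None:
        raise ValueError(f"{candidate.protein.id}: accepted candidate without an 8CM")

    if candidate.gpi_positive:
        gpi_profiles = [p for p in profiles if p.gpi]
        if not gpi_profiles:
            raise ValueError("no GPI-anchored type profile configured")
        return gpi_profiles[0].label, _exemplar_identity(candidate, gpi_profiles[0])

    gaps = candidate.match.gaps
    admissible = [
        p for p in profiles if p.admits_spacing(gaps) and p.admits_introns(intron_count)
    ]
    if not admissible:
        return "X", 0.0

    scored = [(p, _exemplar_identity(candidate, p)) for p in admissible]
    scored.sort(key=lambda item: (-item[1], item[0].label))
    best, confidence = scored[0]
    if best.exemplars and confidence < identity_threshold:
        return "X", confidence
    return best.label, confidence


def _exemplar_identity(candidate: CandidateRecord, prof: TypeProfile) -> float:
    if not prof.exemplars or not candidate.mature_sequence:
        return 0.0
    return fmean(
        pairwise_identity(candidate.mature_sequence, exemplar) for exemplar in prof.exemplars
    )


def assign_types(
    candidates: Sequence[CandidateRecord],
    profiles: Optional[Sequence[TypeProfile]] = None,
    intron_counts: Optional[dict[str, int]] = None,
    identity_threshold: float = 30.0,
) -> dict[str, tuple[str, float]]:
    """Type every accepted candidate; returns id -> (type, confidence)."""
    profiles = list(profiles) if profiles is not None else default_profiles()
    intron_counts = intron_counts or {}
    result = {}
    for cand in candidates:
        if not cand.accepted:
            continue
        result[cand.protein.id] = assign_type(
            cand, profiles, intron_counts.get(cand.protein.id), identity_threshold
        )
    return result
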