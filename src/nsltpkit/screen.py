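"""Candidate screening funnel: from putative proteins to accepted nsLTPs.

The screen applies, in order:

1. eight-cysteine motif (8CM) presence,
2. N-terminal signal sequence (NSS) presence,
3. GPI-anchor detection (GPI-positive candidates are *retained* and
   flagged; they become type G downstream),
4. proline/histidine/glycine-rich exclusion of the segment between the
   signal cleavage site and the first motif cysteine,
5. similarity to storage-protein/inhibitor exemplars,
6. optional mature-length cap.

Each protein is charged to the first stage it fails, so per-stage counts
plus the accepted count always sum to the input count.

The NSS and GPI calls are deliberately simple hydrophobicity heuristics:
dedicated neural predictors (SignalP-class tools) make these calls in
production annotation pipelines, and their output can be injected
verbatim through the ``annotations`` override table.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .align import pairwise_identity
from .records import CandidateRecord, EightCMMatch, ProteinRecord, ScreenReport
from .scales import KYTE_DOOLITTLE

__all__ = [
    "ScreenConfig",
    "find_8cm",
    "canonical_8cm",
    "detect_nss",
    "detect_gpi",
    "is_proline_rich",
    "run_screen",
]

#: Residues accepted as a signal-peptidase P1' cleavage position.
CLEAVAGE_RESIDUES = frozenset("AGSC")
#: Residues accepted as a GPI omega-site.
OMEGA_RESIDUES = frozenset("SGANDC")
#: Latest 1-based start (0-based index 11) for the NSS hydrophobic run.
NSS_RUN_START_MAX = 12
#: Allowed distance (residues from the C-terminus, inclusive) of the omega-site.
OMEGA_DISTANCE = (20, 30)


@dataclass
class ScreenConfig:
    """Thresholds of the screening funnel.

    The gap bounds are generous by default so that every spacing
    architecture observed across the barley/Qingke catalog is accepted;
    type discrimination happens later, in classification.
    """

    gap_bounds: tuple[tuple[int, int], ...] = ((2, 40), (2, 50), (2, 60), (2, 50), (2, 40))
    max_span: int = 160
    nss_window: int = 45
    nss_min_hydrophobic_run: int = 8
    nss_kd_threshold: float = 1.5
    gpi_tail_length: int = 25
    gpi_kd_threshold: float = 1.0
    prolinerich_min_len: int = 15
    prolinerich_phg_fraction: float = 0.35
    exclusion_exemplars: dict[str, str] = field(default_factory=dict)
    exclusion_identity_cutoff: float = 30.0
    # Mature-length cap. Disabled by default: the reported mature lengths
    # reach 200 aa, so a hard 120-aa cap would reject catalogued members.
    max_mature_length: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.gap_bounds) != 5:
            raise ValueError("gap_bounds must give (min, max) for the five free gaps")
        for lo, hi in self.gap_bounds:
            if lo < 0 or hi < lo:
                raise ValueError(f"invalid gap bound ({lo}, {hi})")
        if not 0.0 <= self.prolinerich_phg_fraction <= 1.0:
            raise ValueError("prolinerich_phg_fraction must be in [0, 1]")


def _mean_kd(segment: str) -> float:
    return sum(KYTE_DOOLITTLE.get(res, 0.0) for res in segment) / len(segment)


def find_8cm(protein: ProteinRecord, config: ScreenConfig) -> list[EightCMMatch]:
    """Every placement of the 8CM compatible with the configured gap bounds.

    Returns all cysteine 8-tuples satisfying the CC adjacency, the single
    CXC residue, the five gap bounds and the maximum span, ordered by
    start position then span.  The search walks the (sparse) cysteine
    positions with bound pruning, so it is equivalent to exhaustive
    enumeration of all 8-subsets of cysteine positions.
    """
    seq = protein.sequence
    if len(seq) < 15:
        return []
    cys = [i for i, res in enumerate(seq) if res == "C"]  # 0-based
    cys_set = set(cys)
    (g1lo, g1hi), (g2lo, g2hi), (g3lo, g3hi), (g4lo, g4hi), (g5lo, g5hi) = config.gap_bounds
    matches: list[EightCMMatch] = []

    def cands(after: int, lo: int, hi: int) -> Iterable[int]:
        # cysteines whose gap to `after` lies within [lo, hi]
        left = bisect_left(cys, after + 1 + lo)
        right = bisect_right(cys, after + 1 + hi)
        return cys[left:right]

    for p1 in cys:
        for p2 in cands(p1, g1lo, g1hi):
            for p3 in cands(p2, g2lo, g2hi):
                p4 = p3 + 1
                if p4 not in cys_set:
                    continue
                for p5 in cands(p4, g3lo, g3hi):
                    p6 = p5 + 2
                    if p6 not in cys_set:
                        continue
                    for p7 in cands(p6, g4lo, g4hi):
                        for p8 in cands(p7, g5lo, g5hi):
                            if p8 - p1 + 1 > config.max_span:
                                break
                            positions = tuple(p + 1 for p in (p1, p2, p3, p4, p5, p6, p7, p8))
                            matches.append(
                                EightCMMatch(
                                    cys_positions=positions,  # type: ignore[arg-type]
                                    gaps=(p2 - p1 - 1, p3 - p2 - 1, p5 - p4 - 1,
                                          p7 - p6 - 1, p8 - p7 - 1),
                                    cxc_x=seq[p5 + 1],
                                    span=(p1 + 1, p8 + 1),
                                )
                            )
    matches.sort(key=lambda m: (m.span[0], m.span[1] - m.span[0]))
    return matches


def canonical_8cm(protein: ProteinRecord, config: ScreenConfig) -> Optional[EightCMMatch]:
    """The canonical motif placement: leftmost start, then smallest span."""
    matches = find_8cm(protein, config)
    return matches[0] if matches else None


def detect_nss(
    protein: ProteinRecord,
    config: ScreenConfig,
    override: Optional[int] = None,
) -> Optional[int]:
    """Signal-peptide cleavage position (1-based; mature sequence starts after it).

    Heuristic: the first window of ``nss_min_hydrophobic_run`` residues
    with mean Kyte-Doolittle hydropathy >= ``nss_kd_threshold``, starting
    within the first 12 residues and contained in the first
    ``nss_window`` residues, is taken as the signal's hydrophobic core.
    The cleavage site is the first small residue (A/G/S/C) after it.
    """
    seq = protein.sequence
    if override is not None:
        if not 1 <= override <= len(seq):
            raise ValueError(
                f"{protein.id}: NSS override {override} outside sequence of length {len(seq)}"
            )
        return override
    run = config.nss_min_hydrophobic_run
    run_end = None
    for start in range(min(NSS_RUN_START_MAX, len(seq) - run + 1)):
        if start + run > config.nss_window:
            break
        if _mean_kd(seq[start : start + run]) >= config.nss_kd_threshold:
            run_end = start + run
            break
    if run_end is None:
        return None
    for i in range(run_end, len(seq)):
        if seq[i] in CLEAVAGE_RESIDUES:
            return i + 1
    return None


def detect_gpi(
    protein: ProteinRecord,
    config: ScreenConfig,
    override: Optional[int] = None,
) -> Optional[int]:
    """GPI-anchor omega-site position (1-based), or None.

    Heuristic: the C-terminal ``gpi_tail_length`` residues must be
    hydrophobic on average (mean KD >= ``gpi_kd_threshold``) and an
    omega-site candidate (S/G/A/N/D/C) must sit 20-30 residues from the
    C-terminus; the candidate closest to the C-terminus wins.
    """
    seq = protein.sequence
    if override is not None:
        if not 1 <= override <= len(seq):
            raise ValueError(
                f"{protein.id}: GPI override {override} outside sequence of length {len(seq)}"
            )
        return override
    n = len(seq)
    if n < config.gpi_tail_length:
        return None
    if _mean_kd(seq[n - config.gpi_tail_length :]) < config.gpi_kd_threshold:
        return None
    lo_dist, hi_dist = OMEGA_DISTANCE
    for pos in range(n - lo_dist + 1, n - hi_dist, -1):  # 1-based, distance 20 -> 30
        if pos < 1:
            break
        if seq[pos - 1] in OMEGA_RESIDUES:
            return pos
    return None


def is_proline_rich(candidate: CandidateRecord, config: ScreenConfig) -> bool:
    """Whether the segment between the NSS cleavage and C1 is P/H/G-rich."""
    if candidate.match is None or candidate.nss_cleavage is None:
        raise ValueError("proline-rich test requires both an 8CM and an NSS call")
    c1 = candidate.match.cys_positions[0]
    segment = candidate.protein.sequence[candidate.nss_cleavage : c1 - 1]
    if len(segment) < config.prolinerich_min_len:
        return False
    fraction = sum(res in "PHG" for res in segment) / len(segment)
    return fraction >= config.prolinerich_phg_fraction


def _storage_like(mature: str, config: ScreenConfig) -> bool:
    return any(
        pairwise_identity(mature, exemplar) >= config.exclusion_identity_cutoff
        for exemplar in config.exclusion_exemplars.values()
    )


def run_screen(
    proteins: Sequence[ProteinRecord],
    config: Optional[ScreenConfig] = None,
    annotations: Optional[Mapping[str, Mapping[str, Optional[int]]]] = None,
) -> tuple[list[CandidateRecord], ScreenReport]:
    """Run the full screening funnel.

    ``annotations`` maps protein ids to ``{"nss_cleavage": int|None,
    "gpi_omega": int|None}`` overrides from external predictors; keys
    that are present override the heuristic entirely for that protein.
    """
    config = config or ScreenConfig()
    annotations = annotations or {}
    ids = [p.id for p in proteins]
    if len(set(ids)) != len(ids):
        seen, dupes = set(), set()
        for name in ids:
            (dupes if name in seen else seen).add(name)
        raise ValueError(f"duplicate protein ids: {sorted(dupes)}")

    candidates: list[CandidateRecord] = []
    report = ScreenReport(input_count=len(proteins),
                          excluded={stage: 0 for stage in CandidateRecord.STAGES if stage != "none"})

    for protein in proteins:
        overrides = annotations.get(protein.id, {})
        cand = CandidateRecord(protein=protein)

        cand.match = canonical_8cm(protein, config)
        if cand.match is None:
            cand.exclusion_stage = "no_8cm"
            report.excluded["no_8cm"] += 1
            candidates.append(cand)
            continue

        cand.nss_cleavage = detect_nss(protein, config, overrides.get("nss_cleavage"))
        if cand.nss_cleavage is None:
            cand.exclusion_stage = "no_nss"
            report.excluded["no_nss"] += 1
            candidates.append(cand)
            continue

        # GPI-positive candidates are retained and flagged (they are the
        # type G members); the mature chain is truncated at omega-1.
        cand.gpi_omega = detect_gpi(protein, config, overrides.get("gpi_omega"))
        if cand.gpi_omega is not None:
            mature = protein.sequence[cand.nss_cleavage : cand.gpi_omega - 1]
        else:
            mature = protein.sequence[cand.nss_cleavage :]
        cand.mature_sequence = mature

        if is_proline_rich(cand, config):
            cand.exclusion_stage = "proline_rich"
            report.excluded["proline_rich"] += 1
            candidates.append(cand)
            continue

        if mature and _storage_like(mature, config):
            cand.exclusion_stage = "storage_like"
            report.excluded["storage_like"] += 1
            candidates.append(cand)
            continue

        if config.max_mature_length is not None and len(mature) > config.max_mature_length:
            cand.exclusion_stage = "too_long"
            report.excluded["too_long"] += 1
            candidates.append(cand)
            continue

        cand.status = "accepted"
        cand.exclusion_stage = "none"
        report.accepted_count += 1
        candidates.append(cand)

    report.check_conservation()
    return candidates, report
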