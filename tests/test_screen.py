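"""Screening funnel: motif detection, NSS/GPI heuristics, staged exclusion."""

import numpy as np
import pytest

from nsltpkit.records import CandidateRecord, EightCMMatch, ProteinRecord
from nsltpkit.screen import (
    ScreenConfig,
    canonical_8cm,
    detect_gpi,
    detect_nss,
    find_8cm,
    is_proline_rich,
    run_screen,
)
from nsltpkit import synthetic_data as sd

from conftest import brute_force_8cm, random_protein


class TestFind8CM:
    def test_planted_motif(self, config, make_protein):
        protein = make_protein("CAACAACCAACACAACAAC")
        matches = find_8cm(protein, config)
        assert len(matches) == 1
        match = matches[0]
        assert match.cys_positions == (1, 4, 7, 8, 11, 13, 16, 19)
        assert match.gaps == (2, 2, 2, 2, 2)
        assert match.cxc_x == "A"
        assert match.span == (1, 19)

    def test_no_cysteines(self, config, make_protein):
        assert find_8cm(make_protein("A" * 20), config) == []

    def test_too_short_sequence(self, config, make_protein):
        assert find_8cm(make_protein("CCCCCCCC"), config) == []

    def test_nine_cysteines_equals_enumeration(self, config):
        rng = np.random.default_rng(7)
        # sequences dense in cysteines stress the multi-placement logic
        for _ in range(20):
            seq = random_protein(rng, 60, cys_prob=0.18)
            protein = ProteinRecord(id="x", sequence=seq)
            assert find_8cm(protein, config) == brute_force_8cm(seq, config)

    def test_matches_oracle_on_random_sequences(self, config):
        rng = np.random.default_rng(11)
        for _ in range(100):
            seq = random_protein(rng, int(rng.integers(15, 201)))
            protein = ProteinRecord(id="x", sequence=seq)
            assert find_8cm(protein, config) == brute_force_8cm(seq, config)

    def test_canonical_is_leftmost_then_smallest_span(self, config):
        rng = np.random.default_rng(3)
        for _ in range(50):
            seq = random_protein(rng, 120, cys_prob=0.15)
            matches = find_8cm(ProteinRecord(id="x", sequence=seq), config)
            if matches:
                canonical = canonical_8cm(ProteinRecord(id="x", sequence=seq), config)
                starts = [(m.span[0], m.span[1] - m.span[0]) for m in matches]
                assert (canonical.span[0], canonical.span[1] - canonical.span[0]) == min(starts)


class TestDetectNSS:
    def test_worked_signal_peptide(self, config, make_protein):
        protein = make_protein("M" + "L" * 8 + "A" + "K" * 40)
        assert detect_nss(protein, config) == 10

    def test_hydrophilic_sequence_has_no_signal(self, config, make_protein):
        assert detect_nss(make_protein("K" * 50), config) is None

    def test_override_wins(self, config, make_protein):
        protein = make_protein("K" * 120)
        assert detect_nss(protein, config, override=24) == 24

    def test_override_beyond_length_rejected(self, config, make_protein):
        with pytest.raises(ValueError):
            detect_nss(make_protein("MKKL"), config, override=10)

    def test_run_must_start_within_first_12_residues(self, config, make_protein):
        # hydrophobic run buried at position 20: not a signal peptide
        protein = make_protein("M" + "K" * 19 + "L" * 10 + "A" + "K" * 20)
        assert detect_nss(protein, config) is None


class TestDetectGPI:
    def test_omega_site_in_hydrophobic_tail(self, config, make_protein):
        protein = make_protein("M" + "K" * 60 + "S" + "L" * 24)
        omega = detect_gpi(protein, config)
        assert omega == len(protein.sequence) - 24
        assert protein.sequence[omega - 1] == "S"

    def test_hydrophilic_tail_is_negative(self, config, make_protein):
        assert detect_gpi(make_protein("M" + "L" * 40 + "E" * 25), config) is None

    def test_override_wins(self, config, make_protein):
        assert detect_gpi(make_protein("K" * 80), config, override=55) == 55


class TestProlineRich:
    @staticmethod
    def _candidate(segment: str) -> CandidateRecord:
        # cleavage at 10, C1 at 11 + len(segment); motif geometry is synthetic
        c1 = 11 + len(segment)
        positions = (c1, c1 + 3, c1 + 6, c1 + 7, c1 + 10, c1 + 12, c1 + 15, c1 + 18)
        seq = "M" + "L" * 8 + "A" + segment + "C" * (c1 + 18 - 10 - len(segment))
        match = EightCMMatch(cys_positions=positions, gaps=(2, 2, 2, 2, 2),
                             cxc_x="A", span=(positions[0], positions[-1]))
        return CandidateRecord(
            protein=ProteinRecord(id="x", sequence=seq), match=match, nss_cleavage=10
        )

    def test_all_phg_segment(self, config):
        assert is_proline_rich(self._candidate("PPPHHHGGGPPPHHH"), config)

    def test_no_phg_segment(self, config):
        assert not is_proline_rich(self._candidate("A" * 15), config)

    def test_threshold_boundary(self, config):
        segment = "PHGPHGP" + "A" * 13  # 7 of 20 = 0.35
        assert is_proline_rich(self._candidate(segment), config)
        strict = ScreenConfig(prolinerich_phg_fraction=0.36)
        assert not is_proline_rich(self._candidate(segment), strict)


class TestRunScreen:
    def test_empty_input(self):
        candidates, report = run_screen([])
        assert candidates == []
        assert report.input_count == 0
        assert report.accepted_count == 0

    def test_duplicate_ids_rejected(self, make_protein):
        proteins = [make_protein("A" * 20, "a"), make_protein("C" * 20, "a")]
        with pytest.raises(ValueError, match="duplicate"):
            run_screen(proteins)

    def test_single_synthetic_type1_accepted(self):
        cfg = sd.CohortConfig(
            plan=sd.compact_plan({"1": 1}),
            decoy_counts={"cys_deficient": 0, "nss_lacking": 0,
                          "proline_rich": 0, "storage_like": 0},
            seed=5,
        )
        proteins, manifest = sd.generate_proteins(cfg)
        candidates, report = run_screen(proteins)
        (cand,) = candidates
        truth = manifest.proteins[cand.protein.id]
        assert cand.accepted and cand.exclusion_stage == "none"
        assert cand.nss_cleavage == truth.nss_cleavage
        assert cand.match.cys_positions == truth.cys_positions

    def test_funnel_counts_on_default_cohort(self):
        proteins, _ = sd.generate_proteins(sd.CohortConfig(seed=2))
        _, report = run_screen(proteins)
        assert report.accepted_count == 40
        assert report.excluded["no_8cm"] == 107
        assert report.excluded["no_nss"] == 11
        assert report.excluded["proline_rich"] == 2
        report.check_conservation()

    def test_first_failing_stage_is_charged(self, make_protein):
        # lacks cysteines AND a signal: must be charged to the 8CM stage only
        protein = make_protein("K" * 60)
        candidates, report = run_screen([protein])
        assert candidates[0].exclusion_stage == "no_8cm"
        assert report.excluded["no_nss"] == 0

    def test_rescreening_accepted_proteins_is_idempotent(self):
        proteins, _ = sd.generate_proteins(sd.CohortConfig(seed=4))
        candidates, _ = run_screen(proteins)
        accepted = [c.protein for c in candidates if c.accepted]
        again, report = run_screen(accepted)
        assert report.accepted_count == len(accepted)
        assert all(c.accepted for c in again)

    def test_storage_like_exclusion_against_exemplar(self):
        cfg = sd.CohortConfig(
            plan=sd.compact_plan({"1": 2}),
            decoy_counts={"cys_deficient": 0, "nss_lacking": 0,
                          "proline_rich": 0, "storage_like": 0},
            seed=9,
        )
        proteins, _ = sd.generate_proteins(cfg)
        candidates, _ = run_screen(proteins)
        target = next(c for c in candidates if c.accepted)
        screen_cfg = ScreenConfig(
            exclusion_exemplars={"inhibitor": target.mature_sequence}
        )
        rescreened, report = run_screen([c.protein for c in candidates], screen_cfg)
        by_id = {c.protein.id: c for c in rescreened}
        assert by_id[target.protein.id].exclusion_stage == "storage_like"
        report.check_conservation()

    def test_mature_length_cap(self):
        proteins, _ = sd.generate_proteins(
            sd.CohortConfig(plan=sd.compact_plan({"1": 3}),
                            decoy_counts={"cys_deficient": 0, "nss_lacking": 0,
                                          "proline_rich": 0, "storage_like": 0},
                            seed=6)
        )
        _, report = run_screen(proteins, ScreenConfig(max_mature_length=50))
        assert report.excluded["too_long"] == 3

    def test_gpi_positive_candidates_are_retained_and_truncated(self):
        cfg = sd.CohortConfig(
            plan=sd.compact_plan({"G": 3}),
            decoy_counts={"cys_deficient": 0, "nss_lacking": 0,
                          "proline_rich": 0, "storage_like": 0},
            seed=8,
        )
        proteins, manifest = sd.generate_proteins(cfg)
        candidates, report = run_screen(proteins)
        assert report.accepted_count == 3
        for cand in candidates:
            truth = manifest.proteins[cand.protein.id]
            assert cand.gpi_omega == truth.gpi_omega
            # mature chain stops right before the omega-site
            expected = cand.protein.sequence[cand.nss_cleavage : cand.gpi_omega - 1]
            assert cand.mature_sequence == expected
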